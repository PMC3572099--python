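"""Identifier normalization, table readers and network round trips."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paralognet.io import (
    SchemaError,
    read_annotation_tables,
    read_interactions,
    read_network,
    read_ptm_table,
    write_network,
)
from paralognet.model import (
    AnnotatedNetwork,
    DisorderSegment,
    DomainAnnotation,
    Interaction,
    MalformedIdentifierError,
    ProteinRecord,
    PTMSite,
    merge_segments,
    normalize_accession,
)


class TestNormalizeAccession:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("p62258-2", "P62258"),
            ("P31946", "P31946"),
            ("  q04917 ", "Q04917"),
            ("P63104-10", "P63104"),
        ],
    )
    def test_known_cases(self, raw, expected):
        assert normalize_accession(raw) == expected

    def test_empty_rejected(self):
        with pytest.raises(MalformedIdentifierError):
            normalize_accession("")
        with pytest.raises(MalformedIdentifierError):
            normalize_accession("   ")

    @given(st.text(alphabet=st.characters(codec="ascii"), min_size=1).filter(lambda s: s.strip()))
    @settings(max_examples=200, deadline=None)
    def test_idempotent(self, raw):
        once = normalize_accession(raw)
        assert normalize_accession(once) == once


class TestReadInteractions:
    def test_undirected_dedup(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("id_a\tid_b\tsource\nA1\tB1\tx\nB1\tA1\ty\n")
        res = read_interactions(p)
        assert len(res.items) == 1

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("id_a\tid_b\n")
        assert len(read_interactions(p).items) == 0

    def test_short_row_goes_to_rejects(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("id_a\tid_b\nA1\tB1\nA1\n")
        res = read_interactions(p)
        assert len(res.items) == 1
        assert len(res.rejects) == 1

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("id_a\tpartner\nA\tB\n")
        with pytest.raises(SchemaError, match="id_b"):
            read_interactions(p)

    def test_self_interaction_dropped(self, tmp_path):
        p = tmp_path / "i.tsv"
        p.write_text("id_a\tid_b\nA1\tA1\nA1\tB1\n")
        res = read_interactions(p)
        assert len(res.items) == 1
        assert res.rejects[0][1] == "self-interaction"

    def test_row_order_invariance(self, tmp_path):
        rows = ["A\tB", "C\tD", "B\tC"]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text("id_a\tid_b\n" + "\n".join(rows) + "\n")
        p2.write_text("id_a\tid_b\n" + "\n".join(reversed(rows)) + "\n")
        key = lambda res: sorted((e.a, e.b) for e in res.items)
        assert key(read_interactions(p1)) == key(read_interactions(p2))


class TestReadPTMTable:
    def test_basic_row_and_duplicates_collapse(self, tmp_path):
        p = tmp_path / "ptm.tsv"
        p.write_text(
            "protein_id\tposition\tresidue\tmodification\n"
            "P1\t15\tS\tphosphorylation\nP1\t15\tS\tphosphorylation\n"
        )
        res = read_ptm_table(p)
        assert res.items == [PTMSite("P1", 15, "S", "phosphorylation")]

    def test_non_integer_position_rejected_with_reason(self, tmp_path):
        p = tmp_path / "ptm.tsv"
        p.write_text("protein_id\tposition\tresidue\tmodification\nP1\tx\tS\tphosphorylation\n")
        res = read_ptm_table(p)
        assert not res.items and "position" in res.rejects[0][1]

    @pytest.mark.parametrize(
        "residue,mod", [("K", "phosphorylation"), ("S", "acetylation")]
    )
    def test_residue_modification_mismatch_rejected(self, tmp_path, residue, mod):
        p = tmp_path / "ptm.tsv"
        p.write_text(f"protein_id\tposition\tresidue\tmodification\nP1\t10\t{residue}\t{mod}\n")
        res = read_ptm_table(p)
        assert not res.items and len(res.rejects) == 1

    def test_other_modifications_pass_through(self, tmp_path):
        p = tmp_path / "ptm.tsv"
        p.write_text("protein_id\tposition\tresidue\tmodification\nP1\t10\tN\tglycosylation\n")
        assert len(read_ptm_table(p).items) == 1


class TestAnnotationTables:
    def test_disorder_overlap_merged(self, tmp_path):
        p = tmp_path / "dis.tsv"
        p.write_text("protein_id\tstart\tend\nP1\t1\t10\nP1\t5\t20\n")
        bundle = read_annotation_tables(disorder_path=p)
        assert bundle.disorder["P1"] == [DisorderSegment("P1", 1, 20)]
        assert bundle.warnings

    def test_absent_files_leave_empty_annotations(self):
        bundle = read_annotation_tables()
        assert not bundle.localization and not bundle.domains

    def test_domain_row_parsed(self, tmp_path):
        p = tmp_path / "dom.tsv"
        p.write_text("protein_id\tdomain_name\tstart\tend\nP1\tPDZ\t10\t80\n")
        bundle = read_annotation_tables(domain_path=p)
        assert bundle.domains["P1"] == [DomainAnnotation("P1", "PDZ", 10, 80)]

    def test_clade_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "clades.tsv"
        p.write_text("protein_id\tclade_id\nP1\t1300\nP2\t42\n")
        bundle = read_annotation_tables(clade_path=p)
        assert bundle.clades == {"P2": 42}
        assert len(bundle.rejects) == 1

    def test_domain_clipped_to_length(self, tmp_path):
        dom = tmp_path / "dom.tsv"
        dom.write_text("protein_id\tdomain_name\tstart\tend\nP1\tPDZ\t10\t500\n")
        lengths = tmp_path / "len.tsv"
        lengths.write_text("protein_id\tlength\nP1\t100\n")
        bundle = read_annotation_tables(domain_path=dom, length_path=lengths)
        rec = bundle.apply(ProteinRecord("P1"))
        assert rec.domains[0].end == 100 and bundle.warnings


def _random_network(rng) -> AnnotatedNetwork:
    n = int(rng.integers(2, 9))
    pids = [f"P{i:03d}" for i in range(n)]
    net = AnnotatedNetwork(isoform_ids=pids[:1])
    for pid in pids:
        length = int(rng.integers(50, 400))
        rec = ProteinRecord(pid, length=length)
        if rng.random() < 0.7:
            s = int(rng.integers(1, length - 20))
            rec.domains = [DomainAnnotation(pid, "PDZ", s, s + 19)]
        if rng.random() < 0.7:
            s = int(rng.integers(1, length - 10))
            rec.disorder = [DisorderSegment(pid, s, s + 9)]
        if rng.random() < 0.8:
            rec.ptms = [PTMSite(pid, int(rng.integers(1, length)), "S", "phosphorylation")]
        rec.go_terms = {"GO:0000001"} if rng.random() < 0.5 else set()
        rec.localization = {"nuclear"} if rng.random() < 0.5 else set()
        rec.has_nls = bool(rng.random() < 0.3)
        net.add_protein(rec)
    for _ in range(int(rng.integers(1, 2 * n))):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            a, b = sorted((pids[i], pids[j]))
            post = float(rng.random()) if rng.random() < 0.5 else None
            net.add_edge(
                Interaction(a, b, provenance="sim", source=a if post is not None else None,
                            posterior=round(post, 6) if post is not None else None)
            )
    return net


class TestNetworkRoundTrip:
    def test_graphml_round_trip_exact(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(3)
        for i in range(10):
            net = _random_network(rng)
            path = tmp_path / f"net{i}.graphml"
            write_network(net, path)
            back = read_network(path)
            assert set(back.proteins) == set(net.proteins)
            assert {e.key for e in back.edges} == {e.key for e in net.edges}
            for pid, rec in net.proteins.items():
                b = back.proteins[pid]
                assert (b.length, b.domains, b.disorder, b.ptms) == (
                    rec.length, rec.domains, rec.disorder, rec.ptms
                )
                assert (b.go_terms, b.localization, b.has_nls) == (
                    rec.go_terms, rec.localization, rec.has_nls
                )
            for e in net.edges:
                be = back.edge_between(e.a, e.b)
                assert be.source == e.source
                if e.posterior is not None:
                    assert be.posterior == pytest.approx(e.posterior, abs=1e-6)

    def test_empty_network_round_trip(self, tmp_path):
        net = AnnotatedNetwork()
        path = tmp_path / "empty.graphml"
        write_network(net, path)
        back = read_network(path)
        assert back.n_nodes == 0 and back.n_edges == 0

    def test_tsv_round_trip_edge_set(self, tmp_path):
        import numpy as np

        net = _random_network(np.random.default_rng(4))
        path = tmp_path / "net.tsv"
        write_network(net, path, fmt="tsv")
        back = read_network(path, fmt="tsv")
        assert {e.key for e in back.edges} == {e.key for e in net.edges}


def test_merge_segments_is_idempotent_and_sorted():
    segs = [DisorderSegment("P", 30, 40), DisorderSegment("P", 1, 10), DisorderSegment("P", 8, 25)]
    merged = merge_segments(segs)
    assert merged == [DisorderSegment("P", 1, 25), DisorderSegment("P", 30, 40)]
    assert merge_segments(merged) == merged


def test_summary_counts_match_cardinalities(full_net):
    s = full_net.summary()
    assert s["n_nodes"] == len(full_net.proteins)
    assert s["n_edges"] == len(full_net.edges)
    union = set()
    for iso in full_net.isoform_ids:
        union |= full_net.neighbors(iso)
    assert s["n_clients"] == len(union - set(full_net.isoform_ids))
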