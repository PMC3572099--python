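"""Readers and writers for the tabular and GraphML formats the pipeline touches.

All tables are tab-separated with a header row; coordinates are 1-based
inclusive.  Schemas:

* ``interactions.tsv``: ``id_a  id_b  [source]``
* ``ptm.tsv``:          ``protein_id  position  residue  modification``
* ``domains.tsv``:      ``protein_id  domain_name  start  end``
* ``disorder.tsv``:     ``protein_id  start  end``
* ``go.tsv``:           ``protein_id  term_id``
* ``localization.tsv``: ``protein_id  label``  (label ``NLS`` sets the NLS flag)
* ``kinase_groups.tsv``:``protein_id  group``
* ``clades.tsv``:       ``protein_id  clade_id``

Malformed rows are never dropped silently: every reader returns a
:class:`LoadResult` whose ``rejects`` lists ``(row, reason)`` pairs.
Network export uses GraphML; each node carries its full annotation record as
a JSON attribute so that a write/read round trip is lossless.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from .model import (
    AnnotatedNetwork,
    DisorderSegment,
    DomainAnnotation,
    Interaction,
    KINASE_GROUPS,
    MalformedIdentifierError,
    ProteinRecord,
    PTMSite,
    merge_segments,
    normalize_accession,
)

__all__ = [
    "LoadResult",
    "SchemaError",
    "AnnotationBundle",
    "read_interactions",
    "read_ptm_table",
    "read_annotation_tables",
    "write_network",
    "read_network",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


@dataclass
class LoadResult:
    """Parsed items plus a rejects report (row, reason) and warnings."""

    items: list
    rejects: list[tuple[list[str], str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)


def _read_rows(path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if not rows:
        raise SchemaError(f"{path}: empty file, expected a header row")
    return [c.strip() for c in rows[0]], rows[1:]


def _require(header: list[str], columns: list[str], path) -> dict[str, int]:
    idx = {}
    for col in columns:
        if col not in header:
            raise SchemaError(f"{path}: missing required column {col!r}")
        idx[col] = header.index(col)
    return idx


def read_interactions(path, fmt: str = "tsv") -> LoadResult:
    """Read undirected interactions, deduplicating unordered pairs.

    Self-interactions are rejected (homodimerization is not material to the
    cross-paralog comparisons).  Row order never affects the edge set.
    """
    if fmt == "graphml":
        net = read_network(path, fmt="graphml")
        return LoadResult(items=net.edges)
    header, rows = _read_rows(path)
    idx = _require(header, ["id_a", "id_b"], path)
    src_idx = header.index("source") if "source" in header else None
    seen: dict[frozenset, Interaction] = {}
    rejects: list[tuple[list[str], str]] = []
    for row in rows:
        if len(row) <= max(idx.values()):
            rejects.append((row, "too few columns"))
            continue
        try:
            a = normalize_accession(row[idx["id_a"]])
            b = normalize_accession(row[idx["id_b"]])
        except MalformedIdentifierError as exc:
            rejects.append((row, str(exc)))
            continue
        if a == b:
            rejects.append((row, "self-interaction"))
            continue
        provenance = row[src_idx].strip() if src_idx is not None and len(row) > src_idx else ""
        key = frozenset((a, b))
        if key not in seen:
            seen[key] = Interaction(a=min(a, b), b=max(a, b), provenance=provenance)
    return LoadResult(items=list(seen.values()), rejects=rejects)


def read_ptm_table(path) -> LoadResult:
    """Read PTM sites; duplicate (protein, position, modification) rows collapse.

    Residue/modification mismatches (phospho off S/T/Y, acetyl off K) are
    rejected with a reason, since the analysis pivots on residue identity.
    """
    header, rows = _read_rows(path)
    idx = _require(header, ["protein_id", "position", "residue", "modification"], path)
    seen: dict[tuple, PTMSite] = {}
    rejects: list[tuple[list[str], str]] = []
    for row in rows:
        if len(row) <= max(idx.values()):
            rejects.append((row, "too few columns"))
            continue
        try:
            pid = normalize_accession(row[idx["protein_id"]])
        except MalformedIdentifierError as exc:
            rejects.append((row, str(exc)))
            continue
        pos_raw = row[idx["position"]].strip()
        try:
            pos = int(pos_raw)
        except ValueError:
            rejects.append((row, f"non-integer position {pos_raw!r}"))
            continue
        site = PTMSite(
            protein_id=pid,
            position=pos,
            residue=row[idx["residue"]].strip().upper(),
            modification=row[idx["modification"]].strip().lower(),
        )
        reason = site.validate()
        if reason is not None:
            rejects.append((row, reason))
            continue
        seen.setdefault((pid, pos, site.modification), site)
    return LoadResult(items=list(seen.values()), rejects=rejects)


@dataclass
class AnnotationBundle:
    """Per-protein annotations keyed by normalized accession."""

    lengths: dict[str, int] = field(default_factory=dict)
    domains: dict[str, list[DomainAnnotation]] = field(default_factory=dict)
    disorder: dict[str, list[DisorderSegment]] = field(default_factory=dict)
    ptms: dict[str, list[PTMSite]] = field(default_factory=dict)
    go_terms: dict[str, set] = field(default_factory=dict)
    localization: dict[str, set] = field(default_factory=dict)
    nls: set = field(default_factory=set)
    kinase_groups: dict[str, str] = field(default_factory=dict)
    clades: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    rejects: list[tuple[list[str], str]] = field(default_factory=list)

    def apply(self, record: ProteinRecord) -> ProteinRecord:
        """Merge this bundle's annotations into a protein record (in place)."""
        pid = record.protein_id
        if pid in self.lengths:
            record.length = self.lengths[pid]
        record.domains = sorted(self.domains.get(pid, []))
        record.disorder = merge_segments(self.disorder.get(pid, []))
        record.ptms = sorted(self.ptms.get(pid, []))
        record.go_terms = set(self.go_terms.get(pid, set()))
        record.localization = set(self.localization.get(pid, set()))
        record.has_nls = pid in self.nls
        record.kinase_group = self.kinase_groups.get(pid)
        if record.length <= 0:
            record.length = record.effective_length()
        # clip spans to the known length rather than dropping annotations
        if record.length > 0:
            clipped = []
            for d in record.domains:
                if d.start > record.length:
                    self.warnings.append(f"{pid}: domain {d.domain_name} outside length, dropped")
                    continue
                if d.end > record.length:
                    self.warnings.append(f"{pid}: domain {d.domain_name} clipped to length")
                    d = DomainAnnotation(pid, d.domain_name, d.start, record.length)
                clipped.append(d)
            record.domains = clipped
        return record


def read_annotation_tables(
    domain_path=None,
    disorder_path=None,
    go_path=None,
    localization_path=None,
    kinase_group_path=None,
    ptm_path=None,
    length_path=None,
    clade_path=None,
) -> AnnotationBundle:
    """Read every optional annotation table into one bundle.

    Absent files simply leave the corresponding annotation empty.  Overlapping
    disorder segments are merged (logged in ``warnings``); clade identifiers
    outside 1-1250 are rejected rows.
    """
    bundle = AnnotationBundle()

    if length_path is not None:
        header, rows = _read_rows(length_path)
        idx = _require(header, ["protein_id", "length"], length_path)
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
                bundle.lengths[pid] = int(row[idx["length"]])
            except (MalformedIdentifierError, ValueError) as exc:
                bundle.rejects.append((row, str(exc)))

    if domain_path is not None:
        header, rows = _read_rows(domain_path)
        idx = _require(header, ["protein_id", "domain_name", "start", "end"], domain_path)
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
                dom = DomainAnnotation(
                    pid, row[idx["domain_name"]].strip(), int(row[idx["start"]]), int(row[idx["end"]])
                )
            except (MalformedIdentifierError, ValueError) as exc:
                bundle.rejects.append((row, str(exc)))
                continue
            bundle.domains.setdefault(pid, []).append(dom)

    if disorder_path is not None:
        header, rows = _read_rows(disorder_path)
        idx = _require(header, ["protein_id", "start", "end"], disorder_path)
        raw: dict[str, list[DisorderSegment]] = {}
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
                seg = DisorderSegment(pid, int(row[idx["start"]]), int(row[idx["end"]]))
            except (MalformedIdentifierError, ValueError) as exc:
                bundle.rejects.append((row, str(exc)))
                continue
            raw.setdefault(pid, []).append(seg)
        for pid, segs in raw.items():
            merged = merge_segments(segs)
            if len(merged) < len(segs):
                bundle.warnings.append(f"{pid}: merged {len(segs)} disorder segments into {len(merged)}")
            bundle.disorder[pid] = merged

    if ptm_path is not None:
        result = read_ptm_table(ptm_path)
        bundle.rejects.extend(result.rejects)
        for site in result.items:
            bundle.ptms.setdefault(site.protein_id, []).append(site)

    if go_path is not None:
        header, rows = _read_rows(go_path)
        idx = _require(header, ["protein_id", "term_id"], go_path)
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
            except MalformedIdentifierError as exc:
                bundle.rejects.append((row, str(exc)))
                continue
            bundle.go_terms.setdefault(pid, set()).add(row[idx["term_id"]].strip())

    if localization_path is not None:
        header, rows = _read_rows(localization_path)
        idx = _require(header, ["protein_id", "label"], localization_path)
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
            except MalformedIdentifierError as exc:
                bundle.rejects.append((row, str(exc)))
                continue
            label = row[idx["label"]].strip()
            if label.upper() == "NLS":
                bundle.nls.add(pid)
            else:
                bundle.localization.setdefault(pid, set()).add(label.lower())

    if kinase_group_path is not None:
        header, rows = _read_rows(kinase_group_path)
        idx = _require(header, ["protein_id", "group"], kinase_group_path)
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
            except MalformedIdentifierError as exc:
                bundle.rejects.append((row, str(exc)))
                continue
            group = row[idx["group"]].strip()
            if group not in KINASE_GROUPS:
                bundle.warnings.append(f"{pid}: unknown kinase group {group!r}, mapped to 'other'")
                group = "other"
            bundle.kinase_groups[pid] = group

    if clade_path is not None:
        header, rows = _read_rows(clade_path)
        idx = _require(header, ["protein_id", "clade_id"], clade_path)
        for row in rows:
            try:
                pid = normalize_accession(row[idx["protein_id"]])
                clade = int(row[idx["clade_id"]])
            except (MalformedIdentifierError, ValueError) as exc:
                bundle.rejects.append((row, str(exc)))
                continue
            if not (1 <= clade <= 1250):
                bundle.rejects.append((row, f"clade id {clade} outside 1-1250"))
                continue
            bundle.clades[pid] = clade

    return bundle


# ---------------------------------------------------------------------------
# network serialization
# ---------------------------------------------------------------------------

def _record_to_json(rec: ProteinRecord) -> str:
    return json.dumps(
        {
            "length": rec.length,
            "domains": [[d.domain_name, d.start, d.end] for d in sorted(rec.domains)],
            "disorder": [[s.start, s.end] for s in sorted(rec.disorder)],
            "ptms": [[p.position, p.residue, p.modification] for p in sorted(rec.ptms)],
            "go_terms": sorted(rec.go_terms),
            "localization": sorted(rec.localization),
            "has_nls": rec.has_nls,
            "kinase_group": rec.kinase_group,
        },
        sort_keys=True,
    )


def _record_from_json(pid: str, payload: str) -> ProteinRecord:
    d = json.loads(payload)
    return ProteinRecord(
        protein_id=pid,
        length=d["length"],
        domains=[DomainAnnotation(pid, n, s, e) for n, s, e in d["domains"]],
        disorder=[DisorderSegment(pid, s, e) for s, e in d["disorder"]],
        ptms=[PTMSite(pid, pos, res, mod) for pos, res, mod in d["ptms"]],
        go_terms=set(d["go_terms"]),
        localization=set(d["localization"]),
        has_nls=d["has_nls"],
        kinase_group=d["kinase_group"],
    )


def to_networkx(net: AnnotatedNetwork) -> nx.Graph:
    """Undirected networkx view with full annotation payloads as attributes."""
    g = nx.Graph()
    for pid, rec in net.proteins.items():
        g.add_node(
            pid,
            record=_record_to_json(rec),
            is_isoform=pid in net.isoform_ids,
            n_phospho=len(rec.phospho_sites()),
            n_acetyl=len(rec.acetyl_sites()),
            is_kinase=rec.is_kinase,
        )
    for e in net.edges:
        attrs = {"provenance": e.provenance}
        if e.source is not None:
            attrs["direction_source"] = e.source
            attrs["posterior"] = round(float(e.posterior), 6)
        g.add_edge(e.a, e.b, **attrs)
    g.graph["isoform_ids"] = ",".join(net.isoform_ids)
    return g


def from_networkx(g: nx.Graph) -> AnnotatedNetwork:
    isoforms = [s for s in g.graph.get("isoform_ids", "").split(",") if s]
    net = AnnotatedNetwork(isoform_ids=isoforms)
    for pid, data in g.nodes(data=True):
        if "record" in data:
            net.add_protein(_record_from_json(pid, data["record"]))
        else:
            net.ensure_protein(pid)
    for a, b, data in g.edges(data=True):
        src = data.get("direction_source")
        post = data.get("posterior")
        net.add_edge(
            Interaction(
                a=min(a, b),
                b=max(a, b),
                provenance=data.get("provenance", ""),
                source=src if src else None,
                posterior=float(post) if post is not None else None,
            )
        )
    return net


def write_network(net: AnnotatedNetwork, path, fmt: str = "graphml") -> None:
    """Write a network; GraphML round trips node set, edge set and node
    annotations exactly, the TSV form is an edge list for spreadsheet use."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif fmt == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id_a", "id_b", "source", "direction_source", "posterior"])
            for e in sorted(net.edges, key=lambda e: (e.a, e.b)):
                w.writerow(
                    [
                        e.a,
                        e.b,
                        e.provenance,
                        e.source or "",
                        "" if e.posterior is None else f"{e.posterior:.6f}",
                    ]
                )
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "graphml") -> AnnotatedNetwork:
    if fmt == "graphml":
        return from_networkx(nx.read_graphml(path))
    if fmt == "tsv":
        header, rows = _read_rows(path)
        idx = _require(header, ["id_a", "id_b"], path)
        net = AnnotatedNetwork()
        for row in rows:
            a, b = normalize_accession(row[idx["id_a"]]), normalize_accession(row[idx["id_b"]])
            prov = row[header.index("source")] if "source" in header and len(row) > header.index("source") else ""
            src = None
            post = None
            if "direction_source" in header and len(row) > header.index("direction_source"):
                src = row[header.index("direction_source")].strip() or None
            if "posterior" in header and len(row) > header.index("posterior"):
                raw = row[header.index("posterior")].strip()
                post = float(raw) if raw else None
            net.add_edge(Interaction(a=min(a, b), b=max(a, b), provenance=prov, source=src, posterior=post))
        return net
    raise ValueError(f"unknown network format {fmt!r}")
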