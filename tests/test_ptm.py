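"""Region classification, composition tables, cross-network Fisher
comparisons, crosstalk, OLS proportionality and kinase/localization stats."""

from __future__ import annotations

import numpy as np
import pytest

from paralognet.model import (
    AnnotatedNetwork,
    DisorderSegment,
    DomainAnnotation,
    Interaction,
    ProteinRecord,
    PTMSite,
)
from paralognet.netbuild import ParalogNetwork
from paralognet.ptm import (
    acetylation_burden,
    classify_position,
    compare_fraction,
    composition_table,
    crosstalk_association,
    crosstalk_table,
    disorder_comparison,
    kinase_group_profile,
    localization_stats,
    proportionality_fit,
)


def _rec(pid="P1", length=200, domains=(), disorder=(), ptms=(), **kw):
    return ProteinRecord(
        pid,
        length=length,
        domains=[DomainAnnotation(pid, n, s, e) for n, s, e in domains],
        disorder=[DisorderSegment(pid, s, e) for s, e in disorder],
        ptms=[PTMSite(pid, p, r, m) for p, r, m in ptms],
        **kw,
    )


def _pnet(isoform, records):
    net = AnnotatedNetwork()
    hub = f"HUB_{isoform}"
    net.ensure_protein(hub)
    for rec in records:
        net.add_protein(rec)
        net.add_edge(Interaction(*sorted((hub, rec.protein_id))))
    return ParalogNetwork(isoform, hub, {r.protein_id for r in records},
                          {r.protein_id for r in records},
                          net.edges, net)


class TestClassifyPosition:
    def test_three_regions_and_precedence(self):
        rec = _rec(domains=[("PDZ", 10, 50)], disorder=[(40, 90)])
        assert classify_position(rec, 20) == "domain"
        assert classify_position(rec, 60) == "disordered"
        assert classify_position(rec, 45) == "domain"  # overlap -> domain wins
        assert classify_position(rec, 45, domain_precedence=False) == "disordered"
        assert classify_position(rec, 150) == "other"

    def test_out_of_range_rejected(self):
        rec = _rec(length=100)
        with pytest.raises(ValueError):
            classify_position(rec, 0)
        with pytest.raises(ValueError):
            classify_position(rec, 101)


class TestCompositionTable:
    def test_small_hand_built_network(self):
        rec = _rec(
            domains=[("SH2", 100, 150)],
            disorder=[(1, 50)],
            ptms=[(10, "S", "phosphorylation"), (20, "S", "phosphorylation"),
                  (30, "S", "phosphorylation"), (120, "Y", "phosphorylation")],
        )
        ct = composition_table(_pnet("beta", [rec]))
        assert ct.counts.loc["pS", "disordered"] == 3
        assert ct.counts.loc["pY", "domain"] == 1
        assert ct.percentages.loc["pS", "disordered"] == pytest.approx(100.0)
        assert ct.percentages.loc["pY", "domain"] == pytest.approx(100.0)

    def test_no_phospho_flags_undefined(self):
        ct = composition_table(_pnet("beta", [_rec()]))
        assert ct.percentages.isna().all().all()

    def test_every_site_in_exactly_one_cell(self, pnets, bundle):
        total_truth = 0
        for pnet in pnets.values():
            ct = composition_table(pnet)
            n_truth = sum(
                len(bundle.truth["site_regions"].get(pid, [])) for pid in pnet.partner_ids
            )
            assert ct.total_sites == n_truth
            total_truth += n_truth
        assert total_truth > 0

    def test_region_assignment_matches_generator_truth(self, pnets, bundle):
        pnet = pnets["beta"]
        for pid in sorted(pnet.partner_ids)[:40]:
            rec = pnet.protein(pid)
            truth = {(pos, cls): reg for pos, cls, reg in bundle.truth["site_regions"].get(pid, [])}
            for site in rec.ptms:
                cls = ("p" + site.residue) if site.is_phospho else "acK"
                assert classify_position(rec, site.position) == truth[(site.position, cls)]

    def test_percentages_sum_to_100_per_region(self, pnets):
        ct = composition_table(pnets["zeta"])
        sums = ct.percentages.sum(axis=0, skipna=True)
        for region, s in sums.items():
            if not ct.percentages[region].isna().any():
                assert s == pytest.approx(100.0, abs=0.5)


class TestCompareFraction:
    def test_identical_networks_p_one(self):
        recs = [_rec(f"P{i}", ptms=[(10, "Y", "phosphorylation")]) for i in range(5)]
        a, b = _pnet("beta", recs), _pnet("gamma", recs)
        _, p = compare_fraction(
            a, b,
            numerator=lambda r, s: s.residue == "Y",
            denominator=lambda r, s: s.is_phospho,
        )
        assert p == 1.0

    def test_zero_denominator_rejected(self):
        a = _pnet("beta", [_rec("P1")])
        b = _pnet("gamma", [_rec("P2")])
        with pytest.raises(ValueError):
            compare_fraction(a, b, numerator=lambda r, s: True, denominator=lambda r, s: s.is_phospho)

    def test_protein_unit(self):
        recs_a = [_rec(f"A{i}", ptms=[(10, "K", "acetylation")]) for i in range(8)]
        recs_b = [_rec(f"B{i}") for i in range(8)]
        t, p = compare_fraction(
            _pnet("beta", recs_a), _pnet("gamma", recs_b),
            numerator=lambda r: bool(r.acetyl_sites()),
            denominator=lambda r: True,
            unit="proteins",
        )
        assert (t.a, t.b, t.c, t.d) == (8, 0, 0, 8)
        assert p < 0.001


class TestBurdenAndCrosstalk:
    def test_identical_networks_all_p_one(self):
        recs = [_rec(f"P{i}", ptms=[(10, "K", "acetylation")] if i % 2 else []) for i in range(6)]
        out = acetylation_burden([_pnet("beta", recs), _pnet("gamma", recs)])
        assert float(out["p_matrix"].loc["beta", "gamma"]) == 1.0
        assert float(out["site_p_matrix"].loc["beta", "gamma"]) == 1.0

    def test_containment_acK_in_domain(self, pnets):
        out = acetylation_burden(list(pnets.values()))
        c = out["counts"]
        assert (c["acK_in_domain"] <= c["acK_sites"]).all()
        assert (c["acetylated_partners"] <= c["n_partners"]).all()

    def test_crosstalk_perfect_association(self):
        both = [_rec(f"A{i}", ptms=[(10, "Y", "phosphorylation"), (20, "K", "acetylation")])
                for i in range(6)]
        neither = [_rec(f"B{i}") for i in range(6)]
        t, p, degen = crosstalk_association(_pnet("beta", both + neither), "Y")
        assert (t.a, t.d) == (6, 6) and not degen
        # oracle: hypergeometric point mass of the extreme table
        from tests.test_stats import fisher_two_sided_oracle

        assert p == pytest.approx(fisher_two_sided_oracle(6, 0, 0, 6), abs=1e-9)

    def test_crosstalk_no_acetylation_degenerate(self):
        recs = [_rec(f"P{i}", ptms=[(10, "Y", "phosphorylation")]) for i in range(4)]
        t, p, degen = crosstalk_association(_pnet("beta", recs), "Y")
        assert degen and p == 1.0

    def test_crosstalk_table_consistency(self, pnets):
        df = crosstalk_table(pnets["beta"])
        pnet = pnets["beta"]
        assert len(df) == len(pnet.partner_ids)
        row = df.iloc[0]
        rec = pnet.protein(row.protein_id)
        assert row.n_acK == len(rec.acetyl_sites())
        assert row.n_pS == len(rec.phospho_sites("S"))

    def test_crosstalk_independent_placement_calibrated(self):
        """Under independent site placement the Y/acK association p-value is
        conservative: rejection rate at alpha stays near or below alpha."""
        rng = np.random.default_rng(0)
        alpha, n_sim = 0.1, 200
        rejections = 0
        for _ in range(n_sim):
            recs = []
            for i in range(60):
                ptms = []
                if rng.random() < 0.4:
                    ptms.append((10, "Y", "phosphorylation"))
                if rng.random() < 0.4:
                    ptms.append((20, "K", "acetylation"))
                recs.append(_rec(f"P{i}", ptms=ptms))
            _, p, _ = crosstalk_association(_pnet("beta", recs), "Y")
            rejections += p < alpha
        rate = rejections / n_sim
        se = np.sqrt(alpha * (1 - alpha) / n_sim)
        assert rate <= alpha + 2 * se


class TestProportionalityFit:
    def test_exact_line(self):
        slope, intercept, r2 = proportionality_fit([1, 2, 3, 4], [2, 4, 6, 8])
        assert (slope, intercept, r2) == (pytest.approx(2.0), pytest.approx(0.0), pytest.approx(1.0))

    def test_constant_y(self):
        _, _, r2 = proportionality_fit([1, 2, 3], [5, 5, 5])
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 3.0, 5.0, 9.0])
        # closed-form OLS by hand
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope_h = sxy / sxx
        inter_h = y.mean() - slope_h * x.mean()
        slope, intercept, r2 = proportionality_fit(x, y)
        assert slope == pytest.approx(slope_h, abs=1e-9)
        assert intercept == pytest.approx(inter_h, abs=1e-9)
        resid = y - (slope_h * x + inter_h)
        r2_h = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(r2_h, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            proportionality_fit([1, 1, 1], [1, 2, 3])


class TestKinaseGroups:
    def test_all_agc_row(self):
        recs = [_rec(f"K{i}", kinase_group="AGC") for i in range(3)]
        mat = kinase_group_profile([_pnet("beta", recs)])
        assert mat.loc["beta", "AGC"] == 1.0 and mat.loc["beta"].sum() == 1.0

    def test_no_kinases_zero_row(self):
        mat = kinase_group_profile([_pnet("beta", [_rec("P1")])])
        assert mat.loc["beta"].sum() == 0.0

    def test_rows_match_direct_recount(self, pnets):
        mat = kinase_group_profile(list(pnets.values()))
        for pnet in pnets.values():
            kins = [pnet.protein(p).kinase_group for p in pnet.partner_ids
                    if pnet.protein(p).is_kinase]
            if not kins:
                continue
            for g in set(kins):
                assert mat.loc[pnet.isoform, g] == pytest.approx(kins.count(g) / len(kins))

    def test_generator_weights_recovered_at_bundle_level(self, default_bundle):
        # sampled kinase groups follow the configured weights (chi-square GOF)
        from collections import Counter
        from scipy.stats import chisquare

        groups = sorted(default_bundle.config.kinase_group_weights)
        w = np.array([default_bundle.config.kinase_group_weights[g] for g in groups])
        w = w / w.sum()
        obs = Counter(default_bundle.annotations.kinase_groups.values())
        counts = np.array([obs.get(g, 0) for g in groups])
        _, p = chisquare(counts, f_exp=w * counts.sum())
        assert p > 1e-3


class TestLocalization:
    def test_full_subset_trivial(self):
        recs = [_rec(f"P{i}", localization={"nuclear"}, has_nls=(i < 2)) for i in range(4)]
        out = localization_stats(_pnet("beta", recs), lambda r: True)
        assert out["subset_fraction"] == 1.0 and out["nls_share"] == 1.0

    def test_empty_subset_degenerate(self):
        recs = [_rec("P1", localization={"nuclear"})]
        out = localization_stats(_pnet("beta", recs), lambda r: False)
        assert out["degenerate"]

    def test_missing_annotations_instructive_error(self):
        with pytest.raises(ValueError, match="localization"):
            localization_stats(_pnet("beta", [_rec("P1")]), lambda r: True)

    def test_acetylation_nuclear_coupling_detected(self, pnets):
        # the generator couples acetylation to nuclear localization + NLS
        out = localization_stats(pnets["zeta"], lambda r: bool(r.acetyl_sites()))
        assert out["p_nls"] < 0.05
        assert out["nls_share"] > out["subset_fraction"]


class TestDisorderComparison:
    def test_outputs_complete_and_symmetric(self, pnets):
        out = disorder_comparison(list(pnets.values()))
        assert 0 <= out["kruskal_p"] <= 1
        w = out["wilcoxon_p"]
        assert np.allclose(w.to_numpy(), w.to_numpy().T)
        assert ((w.to_numpy() > 0) & (w.to_numpy() <= 1)).all()
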