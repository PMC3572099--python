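"""Region-stratified PTM composition and phospho/acetyl crosstalk statistics.

Each modified residue of a partner protein is assigned to exactly one
structural region -- ``domain``, ``disordered`` or ``other`` -- with domain
taking precedence when a curated domain overlaps a predicted disorder
segment.  Composition tables, pairwise Fisher comparisons across paralog
networks, acetylation burden, protein-level phospho/acetyl co-occurrence and
kinase-group profiles are all computed per paralog subnetwork.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import KINASE_GROUPS, ProteinRecord, PTMSite
from .netbuild import ParalogNetwork
from .stats import (
    ContingencyTable,
    benjamini_hochberg,
    fisher_exact,
    kruskal_wallis,
    wilcoxon_rank_sum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "classify_position",
    "CompositionTable",
    "composition_table",
    "compare_fraction",
    "acetylation_burden",
    "crosstalk_association",
    "crosstalk_table",
    "proportionality_fit",
    "kinase_group_profile",
    "localization_stats",
    "disorder_comparison",
]

REGIONS = ("domain", "disordered", "other")
_SITE_CLASSES = ("pS", "pT", "pY", "acK")


def classify_position(protein: ProteinRecord, position: int, domain_precedence: bool = True) -> str:
    """Region label of one residue; domains win over disorder on overlap."""
    length = protein.effective_length()
    if not (1 <= position <= length):
        raise ValueError(f"{protein.protein_id}: position {position} outside [1, {length}]")
    in_domain = any(d.contains(position) for d in protein.domains)
    in_disorder = any(s.contains(position) for s in protein.disorder)
    if in_domain and in_disorder:
        return "domain" if domain_precedence else "disordered"
    if in_domain:
        return "domain"
    if in_disorder:
        return "disordered"
    return "other"


def _site_class(site: PTMSite) -> str | None:
    if site.is_phospho and site.residue in "STY":
        return "p" + site.residue
    if site.is_acetyl:
        return "acK"
    return None


@dataclass
class CompositionTable:
    """Counts of modified residues by site class x region for one network.

    ``percentages`` expresses each phospho class as percent of all phospho
    sites in that region (one shared denominator per region); regions without
    phospho sites are flagged undefined (NaN).
    """

    isoform: str
    counts: pd.DataFrame       # index pS/pT/pY/acK, columns domain/disordered/other/total
    percentages: pd.DataFrame  # index pS/pT/pY, same columns; NaN where undefined

    @property
    def total_sites(self) -> int:
        return int(self.counts.loc[:, list(REGIONS)].to_numpy().sum())


def composition_table(pnet: ParalogNetwork, domain_precedence: bool = True) -> CompositionTable:
    counts = pd.DataFrame(0, index=list(_SITE_CLASSES), columns=list(REGIONS), dtype=int)
    for pid in sorted(pnet.partner_ids):
        rec = pnet.protein(pid)
        for site in rec.ptms:
            cls = _site_class(site)
            if cls is None:
                continue
            region = classify_position(rec, site.position, domain_precedence)
            counts.loc[cls, region] += 1
    counts["total"] = counts.sum(axis=1)
    phospho = counts.loc[["pS", "pT", "pY"]]
    denom = phospho.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * phospho / denom.replace(0, np.nan)
    return CompositionTable(isoform=pnet.isoform, counts=counts, percentages=pct)


def compare_fraction(
    netA: ParalogNetwork,
    netB: ParalogNetwork,
    numerator,
    denominator,
    unit: str = "sites",
) -> tuple[ContingencyTable, float]:
    """Two-network 2x2 Fisher comparison of a fraction.

    ``denominator`` selects the eligible units (sites or proteins) of each
    network, ``numerator`` the subset satisfying the property.  Returns the
    table [[hitA, missA], [hitB, missB]] and the two-sided exact p.
    """

    def tally(pnet):
        hits = misses = 0
        for pid in pnet.partner_ids:
            rec = pnet.protein(pid)
            if unit == "proteins":
                if denominator(rec):
                    if numerator(rec):
                        hits += 1
                    else:
                        misses += 1
            else:
                for site in rec.ptms:
                    if denominator(rec, site):
                        if numerator(rec, site):
                            hits += 1
                        else:
                            misses += 1
        return hits, misses

    a, b = tally(netA)
    c, d = tally(netB)
    if a + b == 0 or c + d == 0:
        raise ValueError("zero denominator in one of the networks")
    table = ContingencyTable(a, b, c, d)
    return table, fisher_exact(table)


def pY_in_domain_fraction_test(netA: ParalogNetwork, netB: ParalogNetwork):
    """Convenience: share of pTyr among phospho sites inside domains, A vs B."""
    return compare_fraction(
        netA,
        netB,
        numerator=lambda rec, s: s.residue == "Y",
        denominator=lambda rec, s: s.is_phospho and classify_position(rec, s.position) == "domain",
    )


def acetylation_burden(paralog_networks: list[ParalogNetwork], adjust: bool = False) -> dict:
    """Acetylation burden per network, compared pairwise two ways.

    ``p_matrix`` holds Fisher exact p on the fraction of partners carrying at
    least one acetyl-lysine (the partner-level view); ``site_p_matrix`` holds
    Wilcoxon rank-sum p on the per-partner acetyl-site counts (the
    modified-lysine view, which keeps its power when most partners carry at
    least one site and the binary indicator saturates).
    """
    labels = [p.isoform for p in paralog_networks]
    rows = {}
    state = {}
    site_counts = {}
    for pnet in paralog_networks:
        acetylated = {p for p in pnet.partner_ids if pnet.protein(p).acetyl_sites()}
        ack_sites = sum(len(pnet.protein(p).acetyl_sites()) for p in pnet.partner_ids)
        ack_domain = 0
        for pid in pnet.partner_ids:
            rec = pnet.protein(pid)
            ack_domain += sum(
                1 for s in rec.acetyl_sites() if classify_position(rec, s.position) == "domain"
            )
        rows[pnet.isoform] = {
            "n_partners": len(pnet.partner_ids),
            "acetylated_partners": len(acetylated),
            "acK_sites": ack_sites,
            "acK_in_domain": ack_domain,
        }
        state[pnet.isoform] = (len(acetylated), len(pnet.partner_ids) - len(acetylated))
        site_counts[pnet.isoform] = [
            len(pnet.protein(p).acetyl_sites()) for p in sorted(pnet.partner_ids)
        ]
    counts = pd.DataFrame(rows).T
    pmat = pd.DataFrame(1.0, index=labels, columns=labels)
    smat = pd.DataFrame(1.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        p = fisher_exact(ContingencyTable(*state[a], *state[b]))
        pmat.loc[a, b] = pmat.loc[b, a] = p
        _, ps = wilcoxon_rank_sum(site_counts[a], site_counts[b])
        smat.loc[a, b] = smat.loc[b, a] = ps
    out = {"counts": counts, "p_matrix": pmat, "site_p_matrix": smat}
    if adjust:
        pairs = list(itertools.combinations(labels, 2))
        q = benjamini_hochberg([pmat.loc[a, b] for a, b in pairs])
        qmat = pd.DataFrame(1.0, index=labels, columns=labels)
        for (a, b), qv in zip(pairs, q):
            qmat.loc[a, b] = qmat.loc[b, a] = qv
        out["q_matrix"] = qmat
    return out


def crosstalk_association(
    pnet: ParalogNetwork, phospho_residue: str
) -> tuple[ContingencyTable, float, bool]:
    """Protein-level 2x2 association between carrying >=1 phospho site on the
    given residue and carrying >=1 acetyl-lysine.

    Returns (table, two-sided Fisher p, degenerate flag); a degenerate table
    (an empty margin, e.g. no acetylation at all) is reported with p = 1.
    """
    if phospho_residue not in "STY":
        raise ValueError("phospho_residue must be one of S, T, Y")
    a = b = c = d = 0
    for pid in pnet.partner_ids:
        rec = pnet.protein(pid)
        has_p = bool(rec.phospho_sites(phospho_residue))
        has_ac = bool(rec.acetyl_sites())
        if has_p and has_ac:
            a += 1
        elif has_p:
            b += 1
        elif has_ac:
            c += 1
        else:
            d += 1
    table = ContingencyTable(a, b, c, d)
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        logger.warning("%s/%s crosstalk table has an empty margin", pnet.isoform, phospho_residue)
        return table, 1.0, True
    return table, fisher_exact(table), False


def crosstalk_table(pnet: ParalogNetwork) -> pd.DataFrame:
    """Per-partner site counts (n_pS, n_pT, n_pY, n_acK) for bubble plots."""
    rows = []
    for pid in sorted(pnet.partner_ids):
        rec = pnet.protein(pid)
        rows.append(
            {
                "protein_id": pid,
                "n_pS": len(rec.phospho_sites("S")),
                "n_pT": len(rec.phospho_sites("T")),
                "n_pY": len(rec.phospho_sites("Y")),
                "n_acK": len(rec.acetyl_sites()),
            }
        )
    return pd.DataFrame(rows, columns=["protein_id", "n_pS", "n_pT", "n_pY", "n_acK"])


def proportionality_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns (slope,
    intercept, R^2).  R^2 is 0 when y has no variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(slope), float(intercept), r2


def kinase_group_profile(paralog_networks: list[ParalogNetwork]) -> pd.DataFrame:
    """Isoform x kinase-group relative frequencies over kinase partners.

    Rows normalize to 1; a network without kinase partners yields a zero row
    (flagged in the log).  Kinases without a mapped group count as 'other'.
    """
    mat = pd.DataFrame(0.0, index=[p.isoform for p in paralog_networks], columns=list(KINASE_GROUPS))
    for pnet in paralog_networks:
        counts = dict.fromkeys(KINASE_GROUPS, 0)
        for pid in pnet.partner_ids:
            rec = pnet.protein(pid)
            if rec.is_kinase:
                group = rec.kinase_group if rec.kinase_group in KINASE_GROUPS else "other"
                counts[group] += 1
        total = sum(counts.values())
        if total == 0:
            logger.warning("%s: no kinase partners; zero kinase-group row", pnet.isoform)
            continue
        for g, c in counts.items():
            mat.loc[pnet.isoform, g] = c / total
    return mat


def localization_stats(pnet: ParalogNetwork, subset_predicate) -> dict:
    """Localization of a partner subset and its NLS concentration.

    Reports the subset fraction of partners, the mainly-nuclear fraction
    within the subset, the share of all partner NLS carried by the subset,
    and a Fisher test of (in subset) x (has NLS) over partners.
    """
    partners = [pnet.protein(p) for p in sorted(pnet.partner_ids)]
    if not any(rec.localization for rec in partners) and not any(rec.has_nls for rec in partners):
        raise ValueError("no localization/NLS annotations loaded; supply localization.tsv")
    subset = [rec for rec in partners if subset_predicate(rec)]
    n, ns = len(partners), len(subset)
    result = {"n_partners": n, "subset_size": ns, "subset_fraction": ns / n if n else float("nan")}
    if ns == 0:
        logger.warning("%s: empty subset; localization stats degenerate", pnet.isoform)
        result.update(nuclear_fraction=float("nan"), nls_share=float("nan"), p_nls=1.0, degenerate=True)
        return result
    nuclear = sum(1 for rec in subset if "nuclear" in rec.localization)
    nls_total = sum(1 for rec in partners if rec.has_nls)
    nls_subset = sum(1 for rec in subset if rec.has_nls)
    a = nls_subset
    b = ns - nls_subset
    c = nls_total - nls_subset
    d = (n - ns) - c
    p = fisher_exact(ContingencyTable(a, b, c, d)) if min(a + b, c + d) > 0 else 1.0
    result.update(
        nuclear_fraction=nuclear / ns,
        nls_share=nls_subset / nls_total if nls_total else float("nan"),
        p_nls=p,
        degenerate=False,
    )
    return result


def disorder_comparison(
    paralog_networks: list[ParalogNetwork], binarize_threshold: float = 0.5
) -> dict:
    """Cross-network comparison of partner disorder fractions.

    Computes the omnibus Kruskal-Wallis over all networks, pairwise Wilcoxon
    rank-sum on the disorder fractions, and pairwise Fisher on partners
    binarized at ``binarize_threshold`` disorder fraction.
    """
    labels = [p.isoform for p in paralog_networks]
    fracs = {
        p.isoform: [p.protein(pid).disorder_fraction() for pid in sorted(p.partner_ids)]
        for p in paralog_networks
    }
    h, p_kw = kruskal_wallis([fracs[lab] for lab in labels])
    wil = pd.DataFrame(1.0, index=labels, columns=labels)
    fis = pd.DataFrame(1.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        _, pw = wilcoxon_rank_sum(fracs[a], fracs[b])
        wil.loc[a, b] = wil.loc[b, a] = pw
        ha = sum(1 for f in fracs[a] if f >= binarize_threshold)
        hb = sum(1 for f in fracs[b] if f >= binarize_threshold)
        pf = fisher_exact(
            ContingencyTable(ha, len(fracs[a]) - ha, hb, len(fracs[b]) - hb)
        )
        fis.loc[a, b] = fis.loc[b, a] = pf
    return {"kruskal_H": h, "kruskal_p": p_kw, "wilcoxon_p": wil, "fisher_p": fis}
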