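"""Domain composition of paralog partner sets.

Counting unit is protein-level presence: a partner counts once for a domain
no matter how many copies it carries; relative frequency is that count over
the partner-set size.  Instance-level totals are retained for size/abundance
fits.  Coiled-coil (CC) and transmembrane (TM) annotations are excluded by
default as super-numerary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .netbuild import ParalogNetwork
from .stats import ContingencyTable, fisher_exact

__all__ = [
    "DEFAULT_EXCLUDE",
    "DomainFrequencyProfile",
    "domain_frequencies",
    "top_n_union",
    "domain_enrichment_tests",
    "DomainIsoformBipartite",
    "build_bipartite",
    "modified_domain_frequencies",
    "clade_profile",
]

DEFAULT_EXCLUDE = frozenset({"CC", "TM"})

#: clades at or above this id contain isolated (never-linked) domains
ISOLATED_CLADE_MIN = 1081


@dataclass
class DomainFrequencyProfile:
    isoform: str
    n_partners: int
    counts: dict[str, int]            # protein-level presence counts
    instance_counts: dict[str, int]   # total domain instances
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self):
        self.frequencies = {
            d: (c / self.n_partners if self.n_partners else 0.0) for d, c in self.counts.items()
        }

    def top_n(self, n: int) -> list[str]:
        """Top-n domains by frequency; ties broken by higher count then name."""
        ranked = sorted(self.counts, key=lambda d: (-self.frequencies[d], -self.counts[d], d))
        return ranked[:n]


def domain_frequencies(pnet: ParalogNetwork, exclude=DEFAULT_EXCLUDE) -> DomainFrequencyProfile:
    counts: dict[str, int] = {}
    instances: dict[str, int] = {}
    for pid in sorted(pnet.partner_ids):
        rec = pnet.protein(pid)
        present = set()
        for dom in rec.domains:
            if dom.domain_name in exclude:
                continue
            present.add(dom.domain_name)
            instances[dom.domain_name] = instances.get(dom.domain_name, 0) + 1
        for name in present:
            counts[name] = counts.get(name, 0) + 1
    return DomainFrequencyProfile(
        isoform=pnet.isoform,
        n_partners=len(pnet.partner_ids),
        counts=counts,
        instance_counts=instances,
    )


def top_n_union(profiles: list[DomainFrequencyProfile], n: int = 10) -> list[str]:
    """Union of each profile's top-n domains, in deterministic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not profiles:
        raise ValueError("need at least one profile")
    union: set[str] = set()
    for prof in profiles:
        union.update(prof.top_n(n))
    # order by maximal frequency across profiles, then name
    def key(d):
        return (-max(p.frequencies.get(d, 0.0) for p in profiles), d)

    return sorted(union, key=key)


def domain_enrichment_tests(
    profiles: list[DomainFrequencyProfile], domain: str
) -> pd.DataFrame:
    """Pairwise two-sided Fisher p on per-protein presence of one domain."""
    if not any(domain in p.counts for p in profiles):
        raise ValueError(f"domain {domain!r} absent from every profile")
    labels = [p.isoform for p in profiles]
    state = {p.isoform: (p.counts.get(domain, 0), p.n_partners - p.counts.get(domain, 0)) for p in profiles}
    pmat = pd.DataFrame(1.0, index=labels, columns=labels)
    for a, b in itertools.combinations(labels, 2):
        p = fisher_exact(ContingencyTable(*state[a], *state[b]))
        pmat.loc[a, b] = pmat.loc[b, a] = p
    return pmat


@dataclass
class DomainIsoformBipartite:
    """Isoform-domain edges where a domain's presence differs significantly
    for that isoform against at least one other; sign marks enrichment (+1)
    or depletion (-1) relative to the other isoforms' pooled frequency."""

    alpha: float
    edges: list[tuple[str, str, int]]        # (isoform, domain, sign)
    domain_degree: dict[str, int] = field(init=False)

    def __post_init__(self):
        deg: dict[str, int] = {}
        for iso, dom, _ in self.edges:
            deg[dom] = deg.get(dom, 0) + 1
        self.domain_degree = deg


def build_bipartite(
    profiles: list[DomainFrequencyProfile],
    domains: list[str] | None = None,
    alpha: float = 0.01,
    top_n: int = 10,
) -> DomainIsoformBipartite:
    """Significance network over the top-N union of domains at cutoff alpha.

    An isoform links to a domain when its presence fraction differs from some
    other isoform's at p <= alpha; sign compares its frequency to the mean of
    the others.
    """
    if domains is None:
        domains = top_n_union(profiles, top_n)
    edges = []
    for dom in domains:
        try:
            pmat = domain_enrichment_tests(profiles, dom)
        except ValueError:
            continue
        for prof in profiles:
            others = [p for p in profiles if p.isoform != prof.isoform]
            if any(pmat.loc[prof.isoform, o.isoform] <= alpha for o in others):
                mean_other = sum(p.frequencies.get(dom, 0.0) for p in others) / len(others)
                sign = 1 if prof.frequencies.get(dom, 0.0) >= mean_other else -1
                edges.append((prof.isoform, dom, sign))
    return DomainIsoformBipartite(alpha=alpha, edges=edges)


def modified_domain_frequencies(
    pnet: ParalogNetwork, modification: str, exclude=DEFAULT_EXCLUDE
) -> DomainFrequencyProfile:
    """Protein-level frequency of domains carrying >=1 matching site.

    ``modification`` is ``phospho`` or ``acetyl``; a domain instance counts as
    modified iff a site of that class falls within its span.
    """
    if modification not in ("phospho", "acetyl"):
        raise ValueError("modification must be 'phospho' or 'acetyl'")
    counts: dict[str, int] = {}
    instances: dict[str, int] = {}
    for pid in sorted(pnet.partner_ids):
        rec = pnet.protein(pid)
        sites = rec.phospho_sites() if modification == "phospho" else rec.acetyl_sites()
        positions = [s.position for s in sites]
        present = set()
        for dom in rec.domains:
            if dom.domain_name in exclude:
                continue
            if any(dom.contains(pos) for pos in positions):
                present.add(dom.domain_name)
                instances[dom.domain_name] = instances.get(dom.domain_name, 0) + 1
        for name in present:
            counts[name] = counts.get(name, 0) + 1
    return DomainFrequencyProfile(
        isoform=pnet.isoform,
        n_partners=len(pnet.partner_ids),
        counts=counts,
        instance_counts=instances,
    )


def clade_profile(
    pnet: ParalogNetwork,
    clade_map: dict[str, int],
    isolated_min: int = ISOLATED_CLADE_MIN,
) -> dict:
    """Clade ("domain club") frequency profile of a partner set.

    Clades below ``isolated_min`` hold social domains (clubs); clades at or
    above it hold isolated domains.  Unmapped partners are counted apart.
    """
    clade_counts: dict[int, int] = {}
    unmapped = 0
    for pid in sorted(pnet.partner_ids):
        clade = clade_map.get(pid)
        if clade is None:
            unmapped += 1
            continue
        if not (1 <= clade <= 1250):
            raise ValueError(f"{pid}: clade id {clade} outside 1-1250")
        clade_counts[clade] = clade_counts.get(clade, 0) + 1
    mapped = sum(clade_counts.values())
    isolated = sum(c for k, c in clade_counts.items() if k >= isolated_min)
    freq = {k: c / mapped for k, c in sorted(clade_counts.items())} if mapped else {}
    return {
        "isoform": pnet.isoform,
        "clade_counts": dict(sorted(clade_counts.items())),
        "clade_frequencies": freq,
        "n_mapped": mapped,
        "n_unmapped": unmapped,
        "isolated_fraction": (isolated / mapped) if mapped else 0.0,
    }
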