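"""Ground-truth-labelled synthetic input bundles.

The generator emits every file the pipeline reads (interactions, PTM sites,
domains, disorder segments, GO annotations plus a toy OBO ontology,
localization, kinase groups, clades, a directed training table) together
with a ground-truth record of what was planted, so each analysis stage can
be tested for effect recovery and type-I calibration without any external
download.

Statistical structure emulated:

* seven hub proteins with partner sets of tunable pairwise overlap
  (shared-core construction targeting a chosen Jaccard coefficient);
* log-normal protein lengths carrying non-overlapping domains and disorder
  segments placed in the inter-domain gaps (with a small configurable
  probability of overlapping into a domain);
* per-residue Bernoulli PTM placement with region-dependent rates --
  phosphosites concentrated in disordered segments, acetyl-lysines in
  ordered (domain) regions;
* isoform-specific effect multipliers (elevated domain phospho-tyrosine for
  one hub, elevated acetylation for another, an over-represented domain for
  a third, a boosted GO term);
* kinase flags with group labels and kinase->substrate directed edges; all
  edge directions generated from the same feature schema the edge-direction
  classifier uses;
* planted feed-forward loops in the directed layer.

``null_bundle`` resets every multiplier to 1 and plants nothing, for
calibration runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AnnotationBundle
from .model import (
    DisorderSegment,
    DomainAnnotation,
    Interaction,
    PTMSite,
)

__all__ = ["GeneratorConfig", "SyntheticBundle", "generate_bundle", "null_bundle"]

#: hub accessions of the seven paralogs (UniProt)
DEFAULT_ISOFORM_MAP = {
    "beta": "P31946",
    "gamma": "P61981",
    "epsilon": "P62258",
    "eta": "Q04917",
    "sigma": "P31947",
    "theta": "P27348",
    "zeta": "P63104",
}

_DOMAIN_VOCAB = [
    ("Pkinase", 0.10),
    ("S_T_kinase", 0.06),
    ("SH3", 0.06),
    ("SH2", 0.05),
    ("RRM", 0.04),
    ("PDZ", 0.05),
    ("LIM", 0.04),
    ("TPR", 0.05),
    ("HAT", 0.03),
    ("EF", 0.05),
    ("LRR", 0.05),
    ("WD40", 0.06),
    ("KELCH", 0.04),
    ("PH", 0.06),
    ("ANK", 0.05),
    ("ZnF_C2H2", 0.06),
    ("PDB_bromo", 0.03),
    ("FHA", 0.04),
    ("UBA", 0.04),
    ("CC", 0.05),
    ("TM", 0.05),
]

_KINASE_GROUP_WEIGHTS = {
    "AGC": 0.17,
    "CAMK": 0.14,
    "CK1": 0.03,
    "CMGC": 0.17,
    "STE": 0.09,
    "TK": 0.17,
    "TKL": 0.08,
    "atypical": 0.08,
    "other": 0.07,
}


@dataclass
class GeneratorConfig:
    """All tunables of the synthetic bundle; defaults are the study
    conditions every calibration and recovery test assumes."""

    seed: int = 0
    n_proteins: int = 800
    # protein lengths: log-normal, median 450
    length_median: float = 450.0
    length_sigma: float = 0.6
    # domains: geometric count (mean 1.6, support 0,1,2,...), uniform length
    domain_count_mean: float = 1.6
    domain_length_range: tuple[int, int] = (60, 250)
    # disorder: beta-distributed target fraction of the protein, segments in
    # inter-domain gaps; small probability of spilling into a domain edge
    disorder_beta_a: float = 1.6
    disorder_beta_b: float = 3.4
    disorder_domain_overlap_prob: float = 0.05
    # per-residue PTM rates by region
    ptm_rates: dict = field(
        default_factory=lambda: {
            "pS": {"disordered": 0.02, "domain": 0.004, "other": 0.008},
            "pT": {"disordered": 0.01, "domain": 0.002, "other": 0.004},
            "pY": {"disordered": 0.002, "domain": 0.003, "other": 0.002},
            "acK": {"disordered": 0.002, "domain": 0.006, "other": 0.003},
        }
    )
    # partner sets
    partner_set_size: int = 120
    base_jaccard: float = 0.10
    pair_jaccard: dict = field(default_factory=lambda: {("theta", "beta"): 0.273})
    # isoform-specific effects
    effect_multipliers: dict = field(
        default_factory=lambda: {
            ("epsilon", "pY_in_domain"): 2.5,
            ("zeta", "acK"): 2.0,
            ("gamma", "domain:RRM"): 8.0,
            ("gamma", "go:GO:9000030"): 5.0,
        }
    )
    # kinase layer
    kinase_fraction: float = 0.15
    kinase_group_weights: dict = field(default_factory=lambda: dict(_KINASE_GROUP_WEIGHTS))
    substrates_per_kinase: float = 3.0
    # direction-generation effect sizes (probability the rule fires)
    p_kinase_direction: float = 0.9
    p_degree_direction: float = 0.75
    # GO layer
    go_leaf_rate: float = 0.03
    go_common_rate: float = 0.10
    # localization / NLS, with acetylation coupling
    p_nuclear: float = 0.30
    p_nls_given_nuclear: float = 0.40
    p_nls_base: float = 0.05
    acetyl_nuclear_multiplier: float = 2.0
    acetyl_nls_multiplier: float = 2.5
    # planted directed-layer motifs
    planted_ffls: int = 30
    # clades
    isolated_clade_prob: float = 0.02
    zeta_isolated_clade_prob: float = 0.15

    def multiplier(self, isoform_labels: set[str], feature: str) -> float:
        m = 1.0
        for (iso, feat), mult in self.effect_multipliers.items():
            if feat == feature and iso in isoform_labels:
                m *= mult
        return m


# ---------------------------------------------------------------------------
# toy ontology
# ---------------------------------------------------------------------------

def _toy_ontology() -> tuple[str, dict]:
    """A 60-term, 3-level toy GO DAG over two namespaces.

    Returns (obo_text, {'leaves': [...], 'parents': {term: [parents]}}).
    Term GO:9000030 gets a diamond (two parents) to exercise set semantics.
    """
    terms = {}
    roots = {"GO:9000001": "biological_process", "GO:9000002": "cellular_component"}
    for tid, ns in roots.items():
        terms[tid] = {"name": f"{ns} root", "namespace": ns, "parents": []}
    mids = []
    for i in range(10):
        tid = f"GO:90000{10 + i:02d}"
        terms[tid] = {
            "name": f"toy process {10 + i}",
            "namespace": "biological_process",
            "parents": ["GO:9000001"],
        }
        mids.append(tid)
    for i in range(4):
        tid = f"GO:90000{20 + i:02d}"
        terms[tid] = {
            "name": f"toy component {20 + i}",
            "namespace": "cellular_component",
            "parents": ["GO:9000002"],
        }
        mids.append(tid)
    leaves = []
    idx = 30
    for m, mid in enumerate(mids):
        ns = terms[mid]["namespace"]
        n_children = 4 if ns == "biological_process" else 1
        for _ in range(n_children):
            tid = f"GO:90000{idx:02d}"
            parents = [mid]
            if tid == "GO:9000030":
                parents.append(mids[1])  # diamond
            terms[tid] = {"name": f"toy leaf {idx}", "namespace": ns, "parents": parents}
            leaves.append(tid)
            idx += 1
    lines = ["format-version: 1.2", "ontology: toy", ""]
    for tid in sorted(terms):
        t = terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {t['name']}")
        lines.append(f"namespace: {t['namespace']}")
        for p in t["parents"]:
            lines.append(f"is_a: {p} ! {terms[p]['name']}")
        lines.append("")
    return "\n".join(lines) + "\n", {
        "leaves": leaves,
        "parents": {tid: t["parents"] for tid, t in terms.items()},
    }


# ---------------------------------------------------------------------------
# bundle container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """In-memory bundle plus writers for the on-disk file formats."""

    config: GeneratorConfig
    isoform_map: dict[str, str]
    interactions: list[Interaction]
    annotations: AnnotationBundle
    obo_text: str
    train_rows: list[tuple[str, str, str]]  # (id_a, id_b, forward|reverse)
    truth: dict

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        def tsv(name, header, rows):
            p = outdir / name
            with open(p, "w") as fh:
                fh.write("\t".join(header) + "\n")
                for row in rows:
                    fh.write("\t".join(str(c) for c in row) + "\n")
            paths[name] = p

        tsv(
            "interactions.tsv",
            ["id_a", "id_b", "source"],
            [(e.a, e.b, e.provenance) for e in sorted(self.interactions, key=lambda e: (e.a, e.b))],
        )
        ptm_rows = []
        for pid in sorted(self.annotations.ptms):
            for s in sorted(self.annotations.ptms[pid]):
                ptm_rows.append((pid, s.position, s.residue, s.modification))
        tsv("ptm.tsv", ["protein_id", "position", "residue", "modification"], ptm_rows)
        dom_rows = []
        for pid in sorted(self.annotations.domains):
            for d in sorted(self.annotations.domains[pid]):
                dom_rows.append((pid, d.domain_name, d.start, d.end))
        tsv("domains.tsv", ["protein_id", "domain_name", "start", "end"], dom_rows)
        dis_rows = []
        for pid in sorted(self.annotations.disorder):
            for s in sorted(self.annotations.disorder[pid]):
                dis_rows.append((pid, s.start, s.end))
        tsv("disorder.tsv", ["protein_id", "start", "end"], dis_rows)
        tsv(
            "lengths.tsv",
            ["protein_id", "length"],
            sorted(self.annotations.lengths.items()),
        )
        go_rows = []
        for pid in sorted(self.annotations.go_terms):
            for t in sorted(self.annotations.go_terms[pid]):
                go_rows.append((pid, t))
        tsv("go.tsv", ["protein_id", "term_id"], go_rows)
        loc_rows = []
        for pid in sorted(self.annotations.localization):
            for lab in sorted(self.annotations.localization[pid]):
                loc_rows.append((pid, lab))
        for pid in sorted(self.annotations.nls):
            loc_rows.append((pid, "NLS"))
        tsv("localization.tsv", ["protein_id", "label"], sorted(loc_rows))
        tsv(
            "kinase_groups.tsv",
            ["protein_id", "group"],
            sorted(self.annotations.kinase_groups.items()),
        )
        tsv("clades.tsv", ["protein_id", "clade_id"], sorted(self.annotations.clades.items()))
        tsv("train.tsv", ["id_a", "id_b", "label"], sorted(self.train_rows))
        obo = outdir / "go.obo"
        obo.write_text(self.obo_text)
        paths["go.obo"] = obo
        truth_p = outdir / "truth.json"
        truth_p.write_text(json.dumps(self.truth, sort_keys=True, indent=1))
        paths["truth.json"] = truth_p
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _partner_sets(cfg: GeneratorConfig, pool: list[str], rng) -> dict[str, set]:
    """Shared-core construction hitting the configured Jaccard targets."""
    labels = sorted(DEFAULT_ISOFORM_MAP)
    n = cfg.partner_set_size
    core_size = round(2 * n * cfg.base_jaccard / (1 + cfg.base_jaccard))
    extras = {}
    for (a, b), j in cfg.pair_jaccard.items():
        s = round(2 * n * j / (1 + j))
        extra = s - core_size
        if extra < 0 or s > n:
            raise ValueError(
                f"infeasible Jaccard target {j} for pair ({a},{b}): achievable range "
                f"[{core_size / (2 * n - core_size):.3f}, 1.0] with base_jaccard={cfg.base_jaccard}"
            )
        extras[tuple(sorted((a, b)))] = extra
    demand = core_size + sum(extras.values())
    per_private = {}
    for lab in labels:
        extra_for = sum(v for k, v in extras.items() if lab in k)
        private = n - core_size - extra_for
        if private < 0:
            raise ValueError(f"partner set of {lab} over-constrained by overlap targets")
        per_private[lab] = private
        demand += private
    if demand > len(pool):
        raise ValueError(
            f"partner construction needs {demand} proteins but the pool has {len(pool)}; "
            f"raise n_proteins or lower partner_set_size/overlap"
        )
    perm = [pool[i] for i in rng.permutation(len(pool))]
    cursor = 0

    def take(k):
        nonlocal cursor
        out = perm[cursor : cursor + k]
        cursor += k
        return out

    core = take(core_size)
    pair_extra = {k: take(v) for k, v in extras.items()}
    sets = {}
    for lab in labels:
        s = set(core)
        for k, members in pair_extra.items():
            if lab in k:
                s.update(members)
        s.update(take(per_private[lab]))
        sets[lab] = s
    return sets


def _place_domains(cfg, length, n_domains, name_weights, names, rng):
    """Non-overlapping domain placement; returns list of (name, start, end)."""
    placed = []
    occupied = []  # sorted list of (start, end)
    lo, hi = cfg.domain_length_range
    for _ in range(n_domains):
        if length <= lo + 10:
            break
        dlen = int(rng.integers(lo, min(hi, length - 10) + 1))
        ok = None
        for _attempt in range(20):
            start = int(rng.integers(1, length - dlen + 2))
            end = start + dlen - 1
            if all(end < s or start > e for s, e in occupied):
                ok = (start, end)
                break
        if ok is None:
            continue
        occupied.append(ok)
        occupied.sort()
        name = names[rng.choice(len(names), p=name_weights)]
        placed.append((name, ok[0], ok[1]))
    return placed


def _place_disorder(cfg, length, domain_spans, rng):
    """Disorder segments in inter-domain gaps, targeting a beta fraction."""
    target = float(rng.beta(cfg.disorder_beta_a, cfg.disorder_beta_b)) * length
    gaps = []
    pos = 1
    for s, e in sorted(domain_spans):
        if s > pos:
            gaps.append((pos, s - 1))
        pos = max(pos, e + 1)
    if pos <= length:
        gaps.append((pos, length))
    segments = []
    covered = 0
    order = rng.permutation(len(gaps)) if gaps else []
    for gi in order:
        if covered >= target:
            break
        gs, ge = gaps[gi]
        glen = ge - gs + 1
        if glen < 8:
            continue
        seg_len = min(glen, max(8, int(rng.integers(glen // 2, glen + 1))))
        start = int(rng.integers(gs, ge - seg_len + 2))
        end = start + seg_len - 1
        if domain_spans and rng.random() < cfg.disorder_domain_overlap_prob:
            end = min(length, end + int(rng.integers(5, 21)))  # spill into a domain
        segments.append((start, end))
        covered += end - start + 1
    return segments


def generate_bundle(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Generate a complete bundle; byte-identical output for equal config."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = sorted(DEFAULT_ISOFORM_MAP)
    iso_map = dict(DEFAULT_ISOFORM_MAP)
    hubs = set(iso_map.values())

    pool = [f"S{i:05d}" for i in range(cfg.n_proteins)]
    partner_sets = _partner_sets(cfg, pool, rng)
    membership: dict[str, set] = {pid: set() for pid in pool}
    for lab, s in partner_sets.items():
        for pid in s:
            membership[pid].add(lab)
    # planted isoform-specific effects attach to *exclusive* partners only:
    # shared-core proteins belong to every network, so boosting them would
    # dilute the very contrast the effect is meant to create
    effect_membership = {
        pid: (labs if len(labs) == 1 else set()) for pid, labs in membership.items()
    }

    # kinases
    n_kin = int(round(cfg.kinase_fraction * cfg.n_proteins))
    kin_ids = sorted(pool[i] for i in rng.choice(cfg.n_proteins, size=n_kin, replace=False))
    groups = sorted(cfg.kinase_group_weights)
    gw = np.array([cfg.kinase_group_weights[g] for g in groups])
    gw = gw / gw.sum()
    kinase_groups = {
        pid: groups[gi] for pid, gi in zip(kin_ids, rng.choice(len(groups), size=n_kin, p=gw))
    }

    ann = AnnotationBundle()
    ann.kinase_groups = kinase_groups
    names = [n for n, _ in _DOMAIN_VOCAB]
    base_w = np.array([w for _, w in _DOMAIN_VOCAB])
    geom_p = 1.0 / (1.0 + cfg.domain_count_mean)  # support 0,1,2,... mean (1-p)/p

    truth_sites: dict[str, list] = {}
    lengths = {}
    for pid in pool:
        length = max(60, int(round(cfg.length_median * np.exp(rng.normal(0.0, cfg.length_sigma)))))
        lengths[pid] = length
        ann.lengths[pid] = length
        n_dom = int(rng.geometric(geom_p) - 1)
        w = base_w.copy()
        rrm_mult = cfg.multiplier(effect_membership[pid], "domain:RRM")
        if rrm_mult != 1.0:
            w[names.index("RRM")] *= rrm_mult
        w = w / w.sum()
        domains = _place_domains(cfg, length, n_dom, w, names, rng)
        ann.domains[pid] = [DomainAnnotation(pid, n, s, e) for n, s, e in sorted(domains)]
        dis = _place_disorder(cfg, length, [(s, e) for _, s, e in domains], rng)
        ann.disorder[pid] = [DisorderSegment(pid, s, e) for s, e in sorted(dis)]

        # region partition (domain precedence)
        region = np.zeros(length + 1, dtype=np.int8)  # 0 other, 1 disordered, 2 domain
        for s, e in dis:
            region[s : e + 1] = 1
        for _, s, e in domains:
            region[s : e + 1] = 2
        region_positions = {
            "other": np.flatnonzero(region[1:] == 0) + 1,
            "disordered": np.flatnonzero(region[1:] == 1) + 1,
            "domain": np.flatnonzero(region[1:] == 2) + 1,
        }
        sites = []
        truth_rows = []
        for reg, positions in region_positions.items():
            npos = positions.size
            if npos == 0:
                continue
            perm = positions[rng.permutation(npos)]
            cursor = 0
            for cls in ("pS", "pT", "pY", "acK"):
                rate = cfg.ptm_rates[cls][reg]
                if cls == "pY" and reg == "domain":
                    rate *= cfg.multiplier(effect_membership[pid], "pY_in_domain")
                if cls == "acK":
                    rate *= cfg.multiplier(effect_membership[pid], "acK")
                k = int(rng.binomial(npos, min(rate, 1.0)))
                k = min(k, npos - cursor)
                chosen = perm[cursor : cursor + k]
                cursor += k
                residue = cls[1] if cls != "acK" else "K"
                mod = "acetylation" if cls == "acK" else "phosphorylation"
                for pos in sorted(int(p) for p in chosen):
                    sites.append(PTMSite(pid, pos, residue, mod))
                    truth_rows.append([pos, cls, reg])
        ann.ptms[pid] = sorted(sites)
        if truth_rows:
            truth_sites[pid] = sorted(truth_rows)

    # localization / NLS with acetylation coupling
    for pid in pool:
        has_ack = any(s.is_acetyl for s in ann.ptms.get(pid, []))
        p_nuc = cfg.p_nuclear * (cfg.acetyl_nuclear_multiplier if has_ack else 1.0)
        nuclear = rng.random() < min(p_nuc, 0.95)
        ann.localization[pid] = {"nuclear"} if nuclear else {"cytoplasmic"}
        p_nls = cfg.p_nls_given_nuclear if nuclear else cfg.p_nls_base
        if has_ack:
            p_nls *= cfg.acetyl_nls_multiplier
        if rng.random() < min(p_nls, 0.95):
            ann.nls.add(pid)

    # clades
    for pid in pool:
        p_iso = (
            cfg.zeta_isolated_clade_prob if "zeta" in membership[pid] else cfg.isolated_clade_prob
        )
        if rng.random() < p_iso:
            ann.clades[pid] = int(rng.integers(1081, 1251))
        else:
            ann.clades[pid] = int(rng.integers(1, 1081))

    # edges: hub-partner, kinase-substrate, planted FFLs
    edges: dict[frozenset, Interaction] = {}

    def add_edge(a, b, provenance):
        key = frozenset((a, b))
        if a != b and key not in edges:
            edges[key] = Interaction(a=min(a, b), b=max(a, b), provenance=provenance)
            return True
        return False

    for lab in labels:
        hub = iso_map[lab]
        for pid in sorted(partner_sets[lab]):
            add_edge(hub, pid, "hub")
    for kin in kin_ids:
        n_sub = int(rng.poisson(cfg.substrates_per_kinase))
        if n_sub == 0:
            continue
        subs = rng.choice(cfg.n_proteins, size=min(n_sub, cfg.n_proteins), replace=False)
        for si in subs:
            sub = pool[si]
            add_edge(kin, sub, "kinase-substrate")

    planted = []
    partner_pool = sorted(set().union(*partner_sets.values()))
    for _ in range(cfg.planted_ffls):
        x, y, z = (partner_pool[i] for i in rng.choice(len(partner_pool), size=3, replace=False))
        planted.append([x, y, z])
        add_edge(x, y, "planted")
        add_edge(x, z, "planted")
        add_edge(y, z, "planted")

    # ground-truth directions from the default feature schema
    degree: dict[str, int] = {}
    for key in edges:
        for n in key:
            degree[n] = degree.get(n, 0) + 1
    is_kin = set(kin_ids)
    planted_dir = {}
    for x, y, z in planted:
        planted_dir[frozenset((x, y))] = x
        planted_dir[frozenset((x, z))] = x
        planted_dir[frozenset((y, z))] = y
    directions = {}
    for key in sorted(edges, key=lambda k: tuple(sorted(k))):
        e = edges[key]
        a, b = e.a, e.b
        if key in planted_dir:
            src = planted_dir[key]
        elif (a in is_kin) != (b in is_kin):
            kin, other = (a, b) if a in is_kin else (b, a)
            src = kin if rng.random() < cfg.p_kinase_direction else other
        elif degree.get(a, 0) != degree.get(b, 0):
            hi, lo = (a, b) if degree.get(a, 0) > degree.get(b, 0) else (b, a)
            src = hi if rng.random() < cfg.p_degree_direction else lo
        else:
            src = a if rng.random() < 0.5 else b
        directions[f"{a}--{b}"] = src

    # training table: a random half of the edges, labelled by true direction
    keys = sorted(directions)
    half = rng.choice(len(keys), size=len(keys) // 2, replace=False)
    train_rows = []
    for i in sorted(half):
        a, b = keys[i].split("--")
        train_rows.append((a, b, "forward" if directions[keys[i]] == a else "reverse"))

    # GO annotations
    obo_text, onto = _toy_ontology()
    leaves = onto["leaves"]
    common = set(leaves[:4])
    for pid in pool:
        terms = set()
        for t in leaves:
            rate = cfg.go_common_rate if t in common else cfg.go_leaf_rate
            rate *= cfg.multiplier(effect_membership[pid], f"go:{t}")
            if rng.random() < min(rate, 0.95):
                terms.add(t)
        if terms:
            ann.go_terms[pid] = terms

    node_ids = sorted({n for key in edges for n in key})
    truth = {
        "seed": cfg.seed,
        "isoform_map": iso_map,
        "partner_sets": {lab: sorted(partner_sets[lab]) for lab in labels},
        "n_nodes": len(node_ids),
        "n_edges": len(edges),
        "n_clients": len(partner_pool),
        "jaccard": {
            f"{a}|{b}": len(partner_sets[a] & partner_sets[b])
            / len(partner_sets[a] | partner_sets[b])
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
        },
        "effect_multipliers": {f"{iso}|{feat}": m for (iso, feat), m in cfg.effect_multipliers.items()},
        "directions": directions,
        "planted_ffls": planted,
        "kinases": sorted(kin_ids),
        "site_regions": truth_sites,
    }
    return SyntheticBundle(
        config=cfg,
        isoform_map=iso_map,
        interactions=[edges[k] for k in sorted(edges, key=lambda k: tuple(sorted(k)))],
        annotations=ann,
        obo_text=obo_text,
        train_rows=train_rows,
        truth=truth,
    )


def planted_ffl_network(
    n_nodes: int = 150,
    n_edges: int = 400,
    n_ffls: int = 30,
    seed=None,
):
    """A uniform random digraph background with planted feed-forward loops.

    Returns ``(DiGraph, planted_triples)``.  The sparse uniform background
    keeps the null triad spectrum flat, so planting ``n_ffls`` FFLs creates a
    clean class-7 enrichment signal for power studies -- unlike the full
    bundle's hub-star degree sequence, whose switching null is itself
    FFL-rich.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    g.add_nodes_from(range(n_nodes))
    while g.number_of_edges() < n_edges:
        u, v = rng.integers(0, n_nodes, size=2)
        if u != v and not g.has_edge(int(u), int(v)):
            g.add_edge(int(u), int(v))
    planted = []
    attempts = 0
    while len(planted) < n_ffls and attempts < 100 * n_ffls:
        attempts += 1
        x, y, z = (int(i) for i in rng.choice(n_nodes, size=3, replace=False))
        if g.has_edge(y, x) or g.has_edge(z, x) or g.has_edge(z, y):
            continue
        g.add_edge(x, y)
        g.add_edge(x, z)
        g.add_edge(y, z)
        planted.append((x, y, z))
    return g, planted


def null_bundle(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Bundle with every planted effect switched off (type-I calibration)."""
    cfg = dataclasses.replace(
        config or GeneratorConfig(),
        effect_multipliers={},
        planted_ffls=0,
        acetyl_nuclear_multiplier=1.0,
        acetyl_nls_multiplier=1.0,
        zeta_isolated_clade_prob=GeneratorConfig().isolated_clade_prob,
    )
    if config is not None:
        cfg = dataclasses.replace(cfg, isolated_clade_prob=config.isolated_clade_prob)
        cfg = dataclasses.replace(cfg, zeta_isolated_clade_prob=config.isolated_clade_prob)
    return generate_bundle(cfg)
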