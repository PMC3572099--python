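"""Directed 3-node motif census and enrichment against a degree-preserving null.

The 13 weakly-connected isomorphism classes of 3-node digraphs are numbered
1..13 following the standard motif-dictionary ordering used in triad
significance profiles: 3 is the linear cascade X->Y->Z, 7 the feed-forward
loop (X->Y, X->Z, Y->Z) and 10 the mutual pair jointly regulating a third
node (X<->Y, X->Z, Y->Z).

The null model is edge switching applied separately to the unidirectional
and the reciprocal edge subsets, which preserves every node's in- and
out-degree exactly *and* the number of reciprocal pairs, without introducing
self-loops or parallel edges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TRIAD_NAMES",
    "classify_triad",
    "enumerate_triads",
    "TriadCensus",
    "randomize_directed",
    "motif_significance",
    "MotifSignificance",
    "directed_view",
]

# Representative edge sets on nodes {0, 1, 2} for dictionary IDs 1..13.
_REPRESENTATIVES: dict[int, frozenset] = {
    1: frozenset({(0, 1), (0, 2)}),                            # fan-out
    2: frozenset({(1, 0), (2, 0)}),                            # fan-in
    3: frozenset({(0, 1), (1, 2)}),                            # cascade (chain)
    4: frozenset({(0, 1), (1, 0), (2, 1)}),                    # mutual dyad, incoming
    5: frozenset({(0, 1), (1, 0), (1, 2)}),                    # mutual dyad, outgoing
    6: frozenset({(0, 1), (1, 2), (2, 0)}),                    # 3-cycle
    7: frozenset({(0, 1), (0, 2), (1, 2)}),                    # feed-forward loop
    8: frozenset({(0, 1), (1, 0), (0, 2), (2, 0)}),            # two mutual dyads
    9: frozenset({(0, 1), (1, 0), (2, 0), (2, 1)}),            # mutual pair, co-regulated
    10: frozenset({(0, 1), (1, 0), (0, 2), (1, 2)}),           # mutual pair co-regulating
    11: frozenset({(0, 1), (1, 0), (1, 2), (2, 0)}),           # mutual dyad on a cycle
    12: frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2)}),   # five edges
    13: frozenset({(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)}),  # complete
}

TRIAD_NAMES = {
    1: "fan-out",
    2: "fan-in",
    3: "cascade",
    4: "mutual-in",
    5: "mutual-out",
    6: "cycle",
    7: "feed-forward loop",
    8: "double mutual",
    9: "co-regulated mutual pair",
    10: "co-regulating mutual pair",
    11: "mutual cycle",
    12: "semi-complete",
    13: "complete",
}

_EDGE_BITS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_BIT_OF = {e: i for i, e in enumerate(_EDGE_BITS)}


def _mask(edges) -> int:
    m = 0
    for e in edges:
        m |= 1 << _BIT_OF[e]
    return m


def _permute_mask(mask: int, perm: tuple[int, int, int]) -> int:
    out = 0
    for i, (u, v) in enumerate(_EDGE_BITS):
        if mask >> i & 1:
            out |= 1 << _BIT_OF[(perm[u], perm[v])]
    return out


def _connected(mask: int) -> bool:
    und = set()
    for i, (u, v) in enumerate(_EDGE_BITS):
        if mask >> i & 1:
            und.add(frozenset((u, v)))
    if len(und) < 2:
        return False
    deg = {0: 0, 1: 0, 2: 0}
    for pair in und:
        for n in pair:
            deg[n] += 1
    return all(d > 0 for d in deg.values())


def _build_table() -> dict[int, int]:
    canon_to_id = {}
    for cid, rep in _REPRESENTATIVES.items():
        canon = min(
            _permute_mask(_mask(rep), p) for p in itertools.permutations((0, 1, 2))
        )
        canon_to_id[canon] = cid
    table = {}
    n_connected = 0
    for mask in range(64):
        if not _connected(mask):
            table[mask] = None
            continue
        n_connected += 1
        canon = min(_permute_mask(mask, p) for p in itertools.permutations((0, 1, 2)))
        cid = canon_to_id.get(canon)
        if cid is None:  # pragma: no cover - table defect would fail import
            raise AssertionError(f"connected mask {mask:06b} matches no dictionary class")
        table[mask] = cid
    # internal validation: 54 of the 64 adjacencies are weakly connected and
    # they partition into exactly the 13 classes
    assert n_connected == 54
    assert set(filter(None, table.values())) == set(range(1, 14))
    return table


_MASK_TO_ID = _build_table()


def classify_triad(edges, nodes=None) -> int | str:
    """Dictionary ID (1..13) of a 3-node directed adjacency, or "disconnected".

    ``edges`` are ordered pairs over exactly three distinct nodes; ``nodes``
    may pin the node set (needed when some node is isolated).
    """
    node_set = set(nodes) if nodes is not None else {n for e in edges for n in e}
    if len(node_set) != 3:
        raise ValueError(f"triad must have exactly 3 nodes, got {sorted(node_set)}")
    order = {n: i for i, n in enumerate(sorted(node_set, key=str))}
    mask = 0
    for u, v in edges:
        if u not in order or v not in order:
            raise ValueError(f"edge ({u}, {v}) leaves the triad node set")
        if u == v:
            raise ValueError("self-loops are not allowed in a triad")
        mask |= 1 << _BIT_OF[(order[u], order[v])]
    cid = _MASK_TO_ID[mask]
    return "disconnected" if cid is None else cid


@dataclass
class TriadCensus:
    """Per-class counts of connected triads in one directed network."""

    counts: dict[int, int]
    total: int

    def as_series(self) -> pd.Series:
        return pd.Series({cid: self.counts.get(cid, 0) for cid in range(1, 14)}, name="count")


def enumerate_triads(g: nx.DiGraph) -> TriadCensus:
    """Count every weakly-connected unordered node triple exactly once."""
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed")
    succ = {n: set(g.successors(n)) for n in g.nodes}
    und: dict = {n: set() for n in g.nodes}
    for u, v in g.edges:
        und[u].add(v)
        und[v].add(u)
    index = {n: i for i, n in enumerate(g.nodes)}
    triples = set()
    for u, v in g.edges:
        for w in (und[u] | und[v]) - {u, v}:
            triples.add(tuple(sorted((u, v, w), key=index.get)))
    counts: dict[int, int] = {}
    for a, b, c in triples:
        mask = 0
        sa, sb, sc = succ[a], succ[b], succ[c]
        if b in sa:
            mask |= 1
        if c in sa:
            mask |= 2
        if a in sb:
            mask |= 4
        if c in sb:
            mask |= 8
        if a in sc:
            mask |= 16
        if b in sc:
            mask |= 32
        cid = _MASK_TO_ID[mask]
        if cid is not None:
            counts[cid] = counts.get(cid, 0) + 1
    return TriadCensus(counts=counts, total=sum(counts.values()))


def randomize_directed(g: nx.DiGraph, n_swaps_per_edge: int = 10, seed=None) -> nx.DiGraph:
    """Degree-preserving switching randomization.

    Unidirectional edges and reciprocal pairs are switched within their own
    subsets, so in-degree, out-degree and the reciprocal-edge count are
    conserved exactly.  Deterministic given ``seed``.
    """
    if n_swaps_per_edge < 1:
        raise ValueError("n_swaps_per_edge must be >= 1")
    rng = np.random.default_rng(seed)
    adj = set(g.edges)
    recip = sorted({tuple(sorted((u, v))) for u, v in adj if (v, u) in adj})
    uni = sorted(e for e in adj if (e[1], e[0]) not in adj)

    def has_any(u, v):
        return (u, v) in adj or (v, u) in adj

    successes = 0
    target = n_swaps_per_edge * len(uni)
    attempts_left = max(100, 50 * target)
    # index pairs are drawn in batches: the rejection loop is hot and
    # per-call RNG overhead would dominate the whole randomization
    batch = np.empty((0, 2), dtype=np.int64)
    cursor = 0
    while successes < target and attempts_left > 0 and len(uni) >= 2:
        attempts_left -= 1
        if cursor >= len(batch):
            batch = rng.integers(0, len(uni), size=(max(1024, target), 2))
            cursor = 0
        i, j = batch[cursor]
        cursor += 1
        if i == j:
            continue
        (a, b), (c, d) = uni[i], uni[j]
        if len({a, b, c, d}) < 4:
            continue
        if has_any(a, d) or has_any(c, b):
            continue
        adj.discard((a, b))
        adj.discard((c, d))
        adj.add((a, d))
        adj.add((c, b))
        uni[i], uni[j] = (a, d), (c, b)
        successes += 1

    r_success = 0
    r_target = n_swaps_per_edge * len(recip)
    attempts_left = max(100, 50 * r_target)
    batch = np.empty((0, 3), dtype=np.int64)
    cursor = 0
    while r_success < r_target and attempts_left > 0 and len(recip) >= 2:
        attempts_left -= 1
        if cursor >= len(batch):
            batch = rng.integers(0, len(recip), size=(max(1024, r_target), 3))
            batch[:, 2] = batch[:, 2] % 2
            cursor = 0
        i, j, orient = batch[cursor]
        cursor += 1
        if i == j:
            continue
        (a, b), (c, d) = recip[i], recip[j]
        if len({a, b, c, d}) < 4:
            continue
        # orientation of the rewire chosen at random between the two options
        if orient:
            p1, p2 = (a, d), (c, b)
        else:
            p1, p2 = (a, c), (b, d)
        if p1[0] == p1[1] or p2[0] == p2[1] or has_any(*p1) or has_any(*p2):
            continue
        for u, v in ((a, b), (c, d)):
            adj.discard((u, v))
            adj.discard((v, u))
        for u, v in (p1, p2):
            adj.add((u, v))
            adj.add((v, u))
        recip[i], recip[j] = tuple(sorted(p1)), tuple(sorted(p2))
        r_success += 1

    if (target and not successes) and (r_target and not r_success):
        logger.warning("network too rigid to switch; returning an unshuffled copy")
    out = nx.DiGraph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(adj)
    return out


@dataclass
class MotifSignificance:
    """Enrichment of each triad class versus a randomized ensemble."""

    table: pd.DataFrame  # class_id-indexed: count, mean_rand, sd_rand, z, p, enriched
    ensemble_size: int
    seed: object
    alpha: float

    def enriched_classes(self) -> list[int]:
        return list(self.table.index[self.table["enriched"]])


def motif_significance(
    g: nx.DiGraph,
    ensemble_size: int = 1000,
    n_swaps_per_edge: int = 10,
    seed=None,
    alpha: float = 0.05,
) -> MotifSignificance:
    """Compare the real census against ``ensemble_size`` switching-null draws.

    The empirical enrichment p-value per class is (1 + #{random >= real}) /
    (R + 1), one-sided; z-scores are flagged NaN where the null sd is zero.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    real = enumerate_triads(g).as_series()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(ensemble_size)
    rand_counts = np.zeros((ensemble_size, 13), dtype=np.int64)
    for r in range(ensemble_size):
        gr = randomize_directed(g, n_swaps_per_edge=n_swaps_per_edge, seed=child_seeds[r])
        rand_counts[r] = enumerate_triads(gr).as_series().to_numpy()
    mean = rand_counts.mean(axis=0)
    sd = rand_counts.std(axis=0, ddof=1) if ensemble_size > 1 else np.zeros(13)
    realv = real.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (realv - mean) / sd, np.nan)
    p = (1 + (rand_counts >= realv[None, :]).sum(axis=0)) / (ensemble_size + 1)
    table = pd.DataFrame(
        {
            "name": [TRIAD_NAMES[c] for c in range(1, 14)],
            "count": realv,
            "mean_rand": mean,
            "sd_rand": sd,
            "z": z,
            "p": p,
            "enriched": p < alpha,
        },
        index=pd.Index(range(1, 14), name="class_id"),
    )
    return MotifSignificance(table=table, ensemble_size=ensemble_size, seed=seed, alpha=alpha)


def directed_view(net) -> nx.DiGraph:
    """DiGraph of an oriented :class:`~paralognet.model.AnnotatedNetwork`."""
    g = nx.DiGraph()
    g.add_nodes_from(net.proteins)
    for e in net.edges:
        pair = e.directed_pair
        if pair is None:
            raise ValueError(f"edge {e.a}-{e.b} has no orientation; run orient_network first")
        g.add_edge(*pair)
    return g
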