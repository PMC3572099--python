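"""Over-representation analysis of ontology terms in a query protein set.

The ontology is read from OBO v1.2 (via obonet); annotations propagate up
is_a edges under the true-path rule; per-term significance is the upper-tail
hypergeometric probability P(X >= k) of drawing k annotated proteins in a
query of size n from a universe of N containing K annotated, with
Benjamini-Hochberg q-values across the tested namespace.  The universe
defaults to the full assembled network's node set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import obonet
from scipy.stats import hypergeom

from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "EnrichmentResult",
    "propagate_annotations",
    "enrich",
    "adaptive_threshold",
    "compare_enrichment",
]

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


class OntologyDAG:
    """is_a DAG of ontology terms (child -> parent edges)."""

    def __init__(self, graph: nx.MultiDiGraph, n_obsolete: int = 0, include_part_of: bool = False):
        rels = {"is_a"} | ({"part_of"} if include_part_of else set())
        dag = nx.DiGraph()
        dag.add_nodes_from(graph.nodes(data=True))
        for child, parent, key in graph.edges(keys=True):
            if key in rels:
                dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("ontology contains an is_a cycle")
        self.dag = dag
        self.n_obsolete = n_obsolete
        if n_obsolete:
            logger.info("dropped %d obsolete terms at parse", n_obsolete)

    @classmethod
    def from_obo(cls, path, include_part_of: bool = False) -> "OntologyDAG":
        full = obonet.read_obo(path, ignore_obsolete=False)
        obsolete = [t for t, d in full.nodes(data=True) if d.get("is_obsolete") == "true"]
        full.remove_nodes_from(obsolete)
        return cls(full, n_obsolete=len(obsolete), include_part_of=include_part_of)

    def __contains__(self, term: str) -> bool:
        return term in self.dag

    def name(self, term: str) -> str:
        return self.dag.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self.dag.nodes[term].get("namespace")

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by is_a from ``term`` (excludes the term)."""
        return nx.descendants(self.dag, term)

    def terms(self, namespace: str | None = None) -> list[str]:
        if namespace is None:
            return list(self.dag.nodes)
        return [t for t, d in self.dag.nodes(data=True) if d.get("namespace") == namespace]


def propagate_annotations(direct: dict[str, set], dag: OntologyDAG) -> dict[str, set]:
    """True-path closure: each protein inherits every ancestor of each direct
    term.  Terms absent from the DAG are kept as direct-only (logged)."""
    full: dict[str, set] = {}
    missing: set[str] = set()
    cache: dict[str, set] = {}
    for pid, terms in direct.items():
        closure: set[str] = set()
        for t in terms:
            closure.add(t)
            if t not in dag:
                missing.add(t)
                continue
            if t not in cache:
                cache[t] = dag.ancestors(t)
            closure |= cache[t]
        full[pid] = closure
    if missing:
        logger.warning("%d annotated terms absent from the ontology: %s", len(missing), sorted(missing)[:5])
    return full


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's hypergeometric test: k of n query proteins annotated,
    K of N universe proteins annotated."""

    term_id: str
    name: str
    namespace: str | None
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float = float("nan")

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p)


def enrich(
    query: set[str],
    universe: set[str],
    annotations: dict[str, set],
    dag: OntologyDAG,
    namespace: str | None = None,
    propagate: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term with K >= 1.

    Results are sorted by ascending p; q is the BH-adjusted value across all
    tested terms (one family per call).
    """
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    ann = propagate_annotations(annotations, dag) if propagate else annotations
    term_to_universe: dict[str, set] = {}
    for pid in universe:
        for t in ann.get(pid, ()):  # only terms on universe proteins matter
            if t in dag and (namespace is None or dag.namespace(t) == namespace):
                term_to_universe.setdefault(t, set()).add(pid)
    N, n = len(universe), len(query)
    results = []
    for term, members in sorted(term_to_universe.items()):
        K = len(members)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(
            EnrichmentResult(
                term_id=term,
                name=dag.name(term),
                namespace=dag.namespace(term),
                k=k,
                n=n,
                K=K,
                N=N,
                p=min(max(p, 0.0), 1.0),
            )
        )
    if results:
        q = benjamini_hochberg([r.p for r in results])
        results = [
            EnrichmentResult(r.term_id, r.name, r.namespace, r.k, r.n, r.K, r.N, r.p, float(qv))
            for r, qv in zip(results, q)
        ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def adaptive_threshold(
    results: list[EnrichmentResult], lo: int = 35, hi: int = 50
) -> tuple[float, list[EnrichmentResult]]:
    """Largest observed-p cutoff whose significant set has between lo and hi
    terms; if no cutoff lands in the window, the nearest achievable size is
    returned with a warning."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    if not results:
        raise ValueError("no results to threshold")
    ordered = sorted(results, key=lambda r: (r.p, r.term_id))
    sizes = range(1, len(ordered) + 1)
    feasible = [s for s in sizes if lo <= s <= hi]
    if feasible:
        size = max(feasible)
    else:
        size = min(sizes, key=lambda s: min(abs(s - lo), abs(s - hi)))
        logger.warning(
            "no p cutoff yields between %d and %d terms (have %d); retaining %d",
            lo, hi, len(ordered), size,
        )
    cutoff = ordered[size - 1].p
    retained = [r for r in ordered if r.p <= cutoff]
    return cutoff, retained


def compare_enrichment(
    per_network: dict[str, list[EnrichmentResult]],
    term_list: list[str],
    alpha: float = 0.05,
) -> tuple["pd.DataFrame", "pd.DataFrame"]:
    """Isoform x term matrix of -log10 p for terms significant at alpha.

    Returns (matrix, tested) where ``tested`` flags whether the term was
    evaluated at all in that network; untested or non-significant cells hold
    0 in the matrix.
    """
    import pandas as pd

    labels = list(per_network)
    mat = pd.DataFrame(0.0, index=labels, columns=term_list)
    tested = pd.DataFrame(False, index=labels, columns=term_list)
    for lab, results in per_network.items():
        by_term = {r.term_id: r for r in results}
        for term in term_list:
            r = by_term.get(term)
            if r is None:
                continue
            tested.loc[lab, term] = True
            if r.p < alpha:
                mat.loc[lab, term] = r.neg_log10_p
    return mat, tested
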