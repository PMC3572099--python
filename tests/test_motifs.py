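"""Triad classification, census vs brute force, randomization conservation
laws and motif significance calibration/recovery."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from paralognet.motifs import (
    _MASK_TO_ID,
    classify_triad,
    enumerate_triads,
    motif_significance,
    randomize_directed,
)
from paralognet.simulate import planted_ffl_network


def brute_force_census(g: nx.DiGraph) -> dict[int, int]:
    counts: dict[int, int] = {}
    for trio in itertools.combinations(sorted(g.nodes, key=str), 3):
        edges = [(u, v) for u, v in itertools.permutations(trio, 2) if g.has_edge(u, v)]
        cid = classify_triad(edges, nodes=trio)
        if cid != "disconnected":
            counts[cid] = counts.get(cid, 0) + 1
    return counts


class TestClassify:
    def test_feed_forward_loop_is_class_7(self):
        assert classify_triad([("X", "Y"), ("X", "Z"), ("Y", "Z")]) == 7

    def test_linear_chain_is_class_3(self):
        assert classify_triad([("X", "Y"), ("Y", "Z")]) == 3

    def test_mutual_pair_coregulating_is_class_10(self):
        assert classify_triad([("X", "Y"), ("Y", "X"), ("X", "Z"), ("Y", "Z")]) == 10

    def test_cycle_and_fanout_fanin(self):
        assert classify_triad([("X", "Y"), ("Y", "Z"), ("Z", "X")]) == 6
        assert classify_triad([("X", "Y"), ("X", "Z")]) == 1
        assert classify_triad([("Y", "X"), ("Z", "X")]) == 2

    def test_single_edge_disconnected(self):
        assert classify_triad([("X", "Y")], nodes=("X", "Y", "Z")) == "disconnected"

    def test_isomorphism_invariance_on_random_triads(self):
        rng = np.random.default_rng(0)
        nodes = ("a", "b", "c")
        for _ in range(100):
            edges = [
                (u, v) for u, v in itertools.permutations(nodes, 2) if rng.random() < 0.5
            ]
            ids = set()
            for perm in itertools.permutations(nodes):
                relabel = dict(zip(nodes, perm))
                ids.add(classify_triad([(relabel[u], relabel[v]) for u, v in edges], nodes=nodes))
            assert len(ids) == 1

    def test_table_partitions_the_64_adjacencies(self):
        connected = [cid for cid in _MASK_TO_ID.values() if cid is not None]
        assert len(connected) == 54
        assert set(connected) == set(range(1, 14))

    def test_four_nodes_rejected(self):
        with pytest.raises(ValueError):
            classify_triad([("a", "b"), ("c", "d")])


class TestCensus:
    def test_single_ffl(self):
        g = nx.DiGraph([("X", "Y"), ("X", "Z"), ("Y", "Z")])
        c = enumerate_triads(g)
        assert c.counts == {7: 1} and c.total == 1

    def test_cycle_with_isolated_node(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        g.add_node("d")
        assert enumerate_triads(g).counts == {6: 1}

    def test_matches_brute_force_on_random_digraphs(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, rng.uniform(0.1, 0.5), seed=int(rng.integers(1 << 30)),
                                    directed=True)
            census = enumerate_triads(g).counts
            assert census == brute_force_census(g)

    def test_matches_networkx_triadic_census(self):
        # independent oracle: networkx triad codes mapped onto dictionary IDs
        code_of = {
            1: "021D", 2: "021U", 3: "021C", 4: "111D", 5: "111U", 6: "030C",
            7: "030T", 8: "201", 9: "120D", 10: "120U", 11: "120C", 12: "210", 13: "300",
        }
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1 << 30)), directed=True)
            nxc = nx.triadic_census(g)
            ours = enumerate_triads(g).counts
            for cid, code in code_of.items():
                assert ours.get(cid, 0) == nxc[code], f"class {cid} ({code})"

    def test_self_loop_rejected(self):
        g = nx.DiGraph([("a", "a"), ("a", "b")])
        with pytest.raises(ValueError):
            enumerate_triads(g)


class TestRandomize:
    def _degree_state(self, g):
        return (
            sorted(dict(g.in_degree).items()),
            sorted(dict(g.out_degree).items()),
            sum(1 for u, v in g.edges if g.has_edge(v, u)),
        )

    def test_chain_conserves_degrees(self):
        g = nx.DiGraph([("A", "B"), ("B", "C")])
        r = randomize_directed(g, seed=0)
        assert self._degree_state(r) == self._degree_state(g)

    def test_determinism_same_seed(self):
        g, _ = planted_ffl_network(n_nodes=40, n_edges=120, n_ffls=5, seed=9)
        r1 = randomize_directed(g, seed=42)
        r2 = randomize_directed(g, seed=42)
        assert sorted(r1.edges) == sorted(r2.edges)

    def test_conservation_on_many_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(10, 40))
            g = nx.gnp_random_graph(n, 0.15, seed=int(rng.integers(1 << 30)), directed=True)
            r = randomize_directed(g, n_swaps_per_edge=10, seed=int(rng.integers(1 << 30)))
            assert self._degree_state(r) == self._degree_state(g)
            assert not any(u == v for u, v in r.edges)
            assert r.number_of_edges() == g.number_of_edges()

    def test_actually_shuffles(self):
        g, _ = planted_ffl_network(n_nodes=60, n_edges=200, n_ffls=0, seed=4)
        r = randomize_directed(g, seed=5)
        assert set(r.edges) != set(g.edges)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            randomize_directed(nx.DiGraph([("a", "b")]), n_swaps_per_edge=0)


class TestSignificance:
    def test_planted_ffls_recovered(self):
        g, planted = planted_ffl_network(n_nodes=150, n_edges=400, n_ffls=30, seed=6)
        sig = motif_significance(g, ensemble_size=199, seed=7)
        assert sig.table.loc[7, "enriched"]
        assert sig.table.loc[7, "p"] <= 0.01

    def test_empirical_p_bounds_and_sd_flag(self):
        g, _ = planted_ffl_network(n_nodes=50, n_edges=120, n_ffls=0, seed=8)
        sig = motif_significance(g, ensemble_size=49, seed=9)
        t = sig.table
        assert ((t["p"] >= 1 / 50) & (t["p"] <= 1.0)).all()
        assert t.loc[t["sd_rand"] == 0, "z"].isna().all()

    def test_zero_ensemble_rejected(self):
        g = nx.DiGraph([("a", "b")])
        with pytest.raises(ValueError):
            motif_significance(g, ensemble_size=0)

    def test_null_calibration_per_class(self):
        """Type-I: on networks that are themselves degree-matched rewirings,
        per-class enrichment rate stays within alpha + 2*SE."""
        alpha = 0.05
        n_runs = 60
        rates = np.zeros(13)
        for i in range(n_runs):
            g, _ = planted_ffl_network(n_nodes=60, n_edges=180, n_ffls=0, seed=1000 + i)
            null_net = randomize_directed(g, seed=2000 + i)  # null by construction
            sig = motif_significance(null_net, ensemble_size=59, seed=3000 + i)
            rates += sig.table["enriched"].to_numpy()
        rates /= n_runs
        se = np.sqrt(alpha * (1 - alpha) / n_runs)
        assert (rates <= alpha + 2 * se).all(), rates
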