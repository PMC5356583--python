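"""Degrees, overlap tests, key regulators/drivers, subnetworks, mediators."""

import math
from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from imbnet.topology import (
    KeyRegulatorCall,
    call_key_regulators,
    common_downstream_genes,
    degree_correlation,
    distinct_key_drivers,
    mean_distance_to_drivers,
    neighborhood_overlap_test,
    node_degree,
    project_seed_subnetwork,
)
from tests.conftest import random_dag


def dg(edges, nodes=()):
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestNodeDegree:
    def test_isolated_node(self):
        assert node_degree(dg([], nodes=["a"]), "a") == 0

    def test_two_hop_path(self):
        g = dg([("a", "b"), ("b", "c")])
        assert node_degree(g, "a", hops=2) == 2
        assert node_degree(g, "a", hops=1) == 1

    def test_star_hub(self):
        g = dg([("hub", f"l{i}") for i in range(7)])
        assert node_degree(g, "hub") == 7

    def test_missing_gene(self):
        with pytest.raises(KeyError):
            node_degree(dg([("a", "b")]), "z")


class TestDegreeCorrelation:
    def test_identical_networks(self):
        genes, edges = random_dag(30, 0.1, seed=1)
        g = dg(edges, nodes=genes)
        rho, _ = degree_correlation(g, g.copy())
        assert rho == pytest.approx(1.0)

    def test_independent_graphs_uncorrelated(self):
        genes1, e1 = random_dag(200, 0.02, seed=2)
        genes2, e2 = random_dag(200, 0.02, seed=3)
        rho, _ = degree_correlation(dg(e1, genes1), dg(e2, genes2))
        assert abs(rho) < 0.2

    def test_too_few_common_genes(self):
        g1 = dg([("a", "b")])
        g2 = dg([("a", "b")])
        with pytest.raises(ValueError):
            degree_correlation(g1, g2)


def hypergeom_tail_oracle(k, M, K, n):
    """Exhaustive upper-tail hypergeometric sum P(X >= k)."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
        )
    return total


class TestNeighborhoodOverlap:
    def test_disjoint_neighborhoods_p_one(self):
        g1 = dg([("g", "a"), ("g", "b")], nodes=["c", "d"])
        g2 = dg([("g", "c"), ("g", "d")], nodes=["a", "b"])
        overlap, p = neighborhood_overlap_test(g1, g2, "g")
        assert overlap == 0
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_tail_sum(self):
        universe = {f"u{i}" for i in range(20)}
        n1 = [f"u{i}" for i in range(5)]       # size 5
        n2 = [f"u{i}" for i in range(1, 7)]    # size 6, overlap 4
        g1 = dg([("g", x) for x in n1], nodes=universe)
        g2 = dg([("g", x) for x in n2], nodes=universe)
        overlap, p = neighborhood_overlap_test(g1, g2, "g", universe=universe)
        assert overlap == 4
        assert p == pytest.approx(hypergeom_tail_oracle(4, 20, 5, 6), abs=1e-12)

    def test_maximal_overlap_smallest_p(self):
        universe = {f"u{i}" for i in range(12)}
        n1 = [f"u{i}" for i in range(4)]
        g1 = dg([("g", x) for x in n1], nodes=universe)
        g2 = dg([("g", x) for x in n1], nodes=universe)
        overlap, p = neighborhood_overlap_test(g1, g2, "g", universe=universe)
        assert overlap == 4
        assert p == pytest.approx(hypergeom_tail_oracle(4, 12, 4, 4), abs=1e-12)

    def test_random_universes_match_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            M = int(rng.integers(10, 60))
            universe = [f"u{i}" for i in range(M)]
            k1, k2 = rng.integers(1, M // 2 + 1, size=2)
            n1 = list(rng.choice(universe, size=k1, replace=False))
            n2 = list(rng.choice(universe, size=k2, replace=False))
            g1 = dg([("g", x) for x in n1], nodes=universe)
            g2 = dg([("g", x) for x in n2], nodes=universe)
            overlap, p = neighborhood_overlap_test(
                g1, g2, "g", universe=set(universe)
            )
            oracle = hypergeom_tail_oracle(overlap, M, len(n1), len(n2))
            assert p == pytest.approx(oracle, abs=1e-12)


def descendants_by_matrix_power(g, hops):
    """Oracle: reachability within `hops` steps via boolean matrix powers."""
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in g.edges:
        A[idx[u], idx[v]] = True
    reach = np.zeros_like(A)
    power = np.eye(len(nodes), dtype=bool)
    for _ in range(hops):
        power = power @ A
        reach |= power
    return {
        n: {m for m in nodes if reach[idx[n], idx[m]]} for n in nodes
    }


class TestKeyRegulators:
    def test_hub_called_key_in_sparse_graph(self):
        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(100)]
        edges = [("n0", f"n{i}") for i in range(1, 21)]
        # sparse background
        for _ in range(30):
            u, v = rng.choice(100, size=2, replace=False)
            if u < v:
                edges.append((f"n{u}", f"n{v}"))
        g = dg(edges, nodes=nodes)
        calls = {c.gene: c for c in call_key_regulators(g)}
        assert calls["n0"].is_key

    def test_empty_graph_no_keys(self):
        g = dg([], nodes=["a", "b", "c"])
        calls = call_key_regulators(g)
        assert all(not c.is_key for c in calls)

    def test_downstream_counts_match_matrix_power_oracle(self):
        for seed in range(50):
            genes, edges = random_dag(25, 0.1, seed=seed)
            g = dg(edges, nodes=genes)
            oracle = descendants_by_matrix_power(g, 3)
            for c in call_key_regulators(g, hops=3):
                assert c.downstream_count == len(oracle[c.gene])


class TestDistinctKeyDrivers:
    def _call(self, gene, degree, is_key=True):
        return KeyRegulatorCall(gene, 0, 0.0, is_key, degree)

    def test_no_edges_all_retained(self):
        g = dg([], nodes=["a", "b"])
        calls = [self._call("a", 5), self._call("b", 3)]
        assert set(distinct_key_drivers(g, calls)) == {"a", "b"}

    def test_higher_degree_regulator_removes_target(self):
        g = dg([("a", "b")])
        calls = [self._call("a", 5), self._call("b", 3)]
        assert distinct_key_drivers(g, calls) == ["a"]

    def test_equal_degree_mutual_edge_drops_later_name(self):
        g = dg([("a", "b"), ("b", "a")])
        calls = [self._call("a", 4), self._call("b", 4)]
        assert distinct_key_drivers(g, calls) == ["a"]

    def test_result_is_antichain(self):
        for seed in range(20):
            genes, edges = random_dag(30, 0.08, seed=100 + seed)
            g = dg(edges, nodes=genes)
            calls = call_key_regulators(g, sd_mult=0.5)
            keys = {c.gene: c for c in calls if c.is_key}
            survivors = distinct_key_drivers(g, calls)
            for a in survivors:
                for b in survivors:
                    if a != b and g.has_edge(a, b):
                        assert keys[a].degree <= keys[b].degree


class TestProjectSeedSubnetwork:
    def test_all_nodes_seeded_returns_whole_graph(self):
        g = dg([("a", "b"), ("b", "c"), ("c", "d")])
        res = project_seed_subnetwork(g, set(g.nodes), min_component_seeds=2)
        assert res.members == set(g.nodes)

    def test_path_projection_hand_case(self):
        g = dg([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        res = project_seed_subnetwork(g, {"a", "c"}, min_component_seeds=2)
        assert res.members == {"a", "b", "c", "d"}

    def test_members_superset_of_kept_seeds(self, small_truth):
        g = small_truth.to_digraph()
        seeds = set(small_truth.genes[:15])
        res = project_seed_subnetwork(g, seeds, min_component_seeds=2)
        for comp in res.components:
            assert len(comp & seeds) >= 2
            assert comp <= res.members

    def test_monotone_in_min_component_seeds(self, small_truth):
        g = small_truth.to_digraph()
        seeds = set(small_truth.genes[:15])
        sizes = []
        for m in [1, 2, 3, 5]:
            res = project_seed_subnetwork(g, seeds, min_component_seeds=m)
            sizes.append(len(res.members))
        assert sizes == sorted(sizes, reverse=True)

    def test_no_seed_in_network_rejected(self):
        g = dg([("a", "b")])
        with pytest.raises(ValueError):
            project_seed_subnetwork(g, {"zz"})


class TestMeanDistance:
    def test_driver_distance_zero(self):
        g = dg([("a", "b")])
        ranking = {r.gene: r for r in mean_distance_to_drivers(g, {"a"})}
        assert ranking["a"].mean_distance == 0.0

    def test_chain_distances(self):
        g = dg([("a", "b"), ("b", "c")])
        ranking = {r.gene: r for r in mean_distance_to_drivers(g, {"a"})}
        assert ranking["c"].mean_distance == 2.0

    def test_unreachable_gene_infinite(self):
        g = dg([("a", "b")], nodes=["x"])
        ranking = {r.gene: r for r in mean_distance_to_drivers(g, {"a"})}
        assert math.isinf(ranking["x"].mean_distance)
        assert ranking["x"].reachable_from == 0

    def test_matches_all_pairs_oracle(self):
        for seed in range(30):
            genes, edges = random_dag(20, 0.12, seed=200 + seed)
            g = dg(edges, nodes=genes)
            drivers = set(genes[:3])
            oracle = dict(nx.all_pairs_shortest_path_length(g))
            for r in mean_distance_to_drivers(g, drivers):
                dists = [oracle[d].get(r.gene, math.inf) for d in drivers]
                expect = (
                    sum(dists) / len(dists)
                    if all(math.isfinite(x) for x in dists)
                    else math.inf
                )
                assert r.mean_distance == expect

    def test_empty_drivers_rejected(self):
        with pytest.raises(ValueError):
            mean_distance_to_drivers(dg([("a", "b")]), set())


class TestCommonDownstream:
    def _rank(self, dists):
        from imbnet.topology import MediatorRanking

        return [
            MediatorRanking(f"g{i}", d, 1 if math.isfinite(d) else 0)
            for i, d in enumerate(dists)
        ]

    def test_top_decile_with_full_sort_oracle(self):
        dists = list(np.arange(20, dtype=float))
        got = common_downstream_genes(self._rank(dists), frac=0.1)
        assert got == ["g0", "g1"]

    def test_boundary_ties_included(self):
        dists = [1.0, 2.0, 2.0, 2.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        got = common_downstream_genes(self._rank(dists), frac=0.2)
        # ceil(0.2*10)=2, cutoff value 2.0, ties included
        assert set(got) == {"g0", "g1", "g2", "g3"}

    def test_full_fraction_returns_all_reachable(self):
        dists = [1.0, 2.0, math.inf, 3.0]
        got = common_downstream_genes(self._rank(dists), frac=1.0)
        assert set(got) == {"g0", "g1", "g3"}

    def test_unreachable_excluded_and_warning_on_empty(self):
        with pytest.warns(UserWarning):
            got = common_downstream_genes(self._rank([math.inf, math.inf]), 0.1)
        assert got == []
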