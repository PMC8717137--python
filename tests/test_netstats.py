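"""Clustering, path statistics, ER nulls and small-world sigma against oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from conftest import random_digraph
from ohcnet.netstats import (
    average_clustering,
    er_equivalent,
    local_clustering,
    network_metrics,
    path_stats,
    small_world_sigma,
)


def brute_local_clustering(g: nx.DiGraph, k) -> float:
    """Independent oracle: count directed links among the neighbor union."""
    nbrs = (set(g.successors(k)) | set(g.predecessors(k))) - {k}
    n = len(nbrs)
    if n < 2:
        return 0.0
    links = sum(
        1 for i in nbrs for j in nbrs if i != j and g.has_edge(i, j)
    )
    return links / (n * (n - 1))


def brute_path_stats(g: nx.DiGraph, mode: str):
    n = g.number_of_nodes()
    dists = []
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        dists.extend(d for t, d in lengths.items() if t != src)
    if not dists:
        return 0.0, 0
    diameter = max(dists)
    if mode == "all_pairs":
        return sum(dists) / (n * (n - 1)), diameter
    return sum(dists) / len(dists), diameter


class TestLocalClustering:
    def test_reciprocal_pair_among_neighbors(self):
        g = nx.DiGraph([("k", "i"), ("k", "j"), ("i", "j"), ("j", "i")])
        assert local_clustering(g, "k") == 1.0

    def test_single_link_among_neighbors(self):
        g = nx.DiGraph([("k", "i"), ("k", "j"), ("i", "j")])
        assert local_clustering(g, "k") == 0.5

    def test_under_two_neighbors_is_zero(self):
        g = nx.DiGraph([("k", "i")])
        assert local_clustering(g, "k") == 0.0

    def test_absent_node(self):
        with pytest.raises(KeyError):
            local_clustering(nx.DiGraph([("a", "b")]), "z")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_digraphs(self, seed):
        g = random_digraph(30, 0.12, seed=seed)
        for k in g.nodes:
            assert local_clustering(g, k) == pytest.approx(
                brute_local_clustering(g, k), abs=1e-12
            )


class TestAverageClustering:
    def test_complete_digraph(self):
        assert average_clustering(nx.complete_graph(4, nx.DiGraph)) == 1.0

    def test_directed_star(self):
        g = nx.DiGraph((0, i) for i in range(1, 6))
        assert average_clustering(g) == 0.0

    def test_mean_of_per_node_oracle(self):
        g = random_digraph(25, 0.15, seed=3)
        expected = np.mean([brute_local_clustering(g, k) for k in g.nodes])
        assert average_clustering(g) == pytest.approx(expected, abs=1e-12)

    def test_undirected_agrees_with_networkx(self):
        # On symmetric adjacency the definition reduces to Watts-Strogatz
        # clustering, for which networkx is an independent implementation.
        g = nx.erdos_renyi_graph(40, 0.15, seed=11)
        assert average_clustering(g) == pytest.approx(
            nx.average_clustering(g, count_zeros=True), abs=1e-12
        )


class TestPathStats:
    def test_chain_all_pairs_mode(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        l, diam = path_stats(g, mode="all_pairs")
        assert l == pytest.approx((1 + 2 + 1) / 6)
        assert diam == 2

    def test_complete_digraph(self):
        g = nx.complete_graph(3, nx.DiGraph)
        assert path_stats(g, mode="all_pairs") == (1.0, 1)

    def test_edgeless_graph_flagged_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        assert path_stats(g) == (0.0, 0)
        assert network_metrics(g).no_paths

    @pytest.mark.parametrize("mode", ["all_pairs", "reachable"])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_bfs_oracle(self, mode, seed):
        g = random_digraph(40, 0.06, seed=100 + seed)
        l, diam = path_stats(g, mode=mode)
        l_exp, diam_exp = brute_path_stats(g, mode)
        assert l == pytest.approx(l_exp, abs=1e-12)
        assert diam == diam_exp

    def test_all_pairs_equals_reachable_times_reachable_fraction(self):
        g = random_digraph(35, 0.05, seed=77)
        n = g.number_of_nodes()
        l_all, _ = path_stats(g, mode="all_pairs")
        l_reach, _ = path_stats(g, mode="reachable")
        n_reachable = sum(
            1
            for src, lengths in nx.all_pairs_shortest_path_length(g)
            for t in lengths
            if t != src
        )
        assert l_all == pytest.approx(
            l_reach * n_reachable / (n * (n - 1)), abs=1e-12
        )


class TestErEquivalent:
    def test_forced_complete_digraph(self):
        g = er_equivalent(4, 12, directed=True, seed=0)
        assert g.number_of_edges() == 12
        assert nx.density(g) == 1.0

    def test_zero_edges(self):
        g = er_equivalent(5, 0, directed=True, seed=0)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_infeasible_count(self):
        with pytest.raises(ValueError, match="infeasible"):
            er_equivalent(4, 13, directed=True, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            er_equivalent(4, 7, directed=False, seed=0)

    def test_no_self_loops_distinct_edges(self):
        for directed in (True, False):
            g = er_equivalent(30, 100, directed=directed, seed=5)
            assert g.number_of_edges() == 100
            assert all(u != v for u, v in g.edges)

    def test_per_edge_inclusion_uniform(self):
        # 200 replicates of (12 nodes, 30 directed edges): each of the 132
        # possible edges appears with probability 30/132.
        counts = {}
        for seed in range(200):
            g = er_equivalent(12, 30, directed=True, seed=seed)
            for e in g.edges:
                counts[e] = counts.get(e, 0) + 1
        freqs = np.array([counts.get((i, j), 0) for i in range(12) for j in range(12) if i != j])
        p = 30 / 132
        # binomial(200, p): allow 5 sigma around the mean
        sigma = math.sqrt(200 * p * (1 - p))
        assert abs(freqs.mean() - 200 * p) < 1.0
        assert (np.abs(freqs - 200 * p) < 5 * sigma).all()


class TestSmallWorldSigma:
    def test_triangle_free_star_gives_zero(self):
        g = nx.DiGraph((0, i) for i in range(1, 30))
        sw = small_world_sigma(g, n_replicates=10, seed=1)
        assert sw.c_obs == 0.0
        assert sw.sigma_mean == 0.0

    def test_reproducible(self):
        g = er_equivalent(100, 600, directed=True, seed=2)
        a = small_world_sigma(g, n_replicates=10, seed=3)
        b = small_world_sigma(g, n_replicates=10, seed=3)
        assert a == b

    def test_er_self_null_near_one(self):
        g = er_equivalent(300, 2000, directed=True, seed=4)
        sw = small_world_sigma(g, n_replicates=20, seed=5)
        assert 0.5 < sw.sigma_mean < 2.0

    def test_edgeless_graph_rejected(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(4))
        with pytest.raises(ValueError, match="no edges"):
            small_world_sigma(g, seed=0)

    def test_sigma_identity_on_replicate_means(self):
        g = er_equivalent(150, 900, directed=True, seed=6)
        sw = small_world_sigma(g, n_replicates=15, seed=7)
        # per-replicate sigmas were formed from the same c/l values
        assert sw.sigma_mean == pytest.approx(np.mean(sw.sigma_values))
        assert len(sw.sigma_values) <= sw.n_replicates
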