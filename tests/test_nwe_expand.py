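"""Node weighting, greedy expansion, scoring, significance and de-duplication."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from nwe.graph_core import Cluster, WeightedGraph
from nwe.matching_stats import concordance
from nwe.nwe_expand import (
    NWEParams,
    ScoreMatrix,
    cluster_score,
    cluster_significance,
    dedup_clusters,
    expand_from_seed,
    node_weights,
    overlap_ratio,
    restart_weights,
    run_nwe,
)
from nwe.random_walk import rwr_single_all

from conftest import clique_graph, random_connected_graph


class TestNodeWeights:
    def test_sum_of_incident_evidence(self, fig3_graph):
        w = node_weights(fig3_graph)
        assert w["u"] == pytest.approx(230.0)  # 100 + 50 + 80
        assert w["v"] == pytest.approx(4.0)    # 1 + 3

    def test_leaf_node_weight_is_its_single_edge(self, fig3_graph):
        assert node_weights(fig3_graph)["x2"] == pytest.approx(50.0)


class TestRestartWeights:
    def test_node_weighted_mass_proportional_to_evidence(self, fig3_graph):
        b = restart_weights({"u", "v"}, node_weights(fig3_graph))
        assert b["u"] == pytest.approx(230 / 234)
        assert b["v"] == pytest.approx(4 / 234)

    def test_uniform_mode_splits_mass_equally(self):
        b = restart_weights({"a", "b", "c", "d"}, {}, mode="uniform")
        assert all(v == pytest.approx(0.25) for v in b.values())

    def test_singleton_gets_all_mass_in_both_modes(self, fig3_graph):
        for mode in ("node-weighted", "uniform"):
            b = restart_weights({"u"}, node_weights(fig3_graph), mode=mode)
            assert b == {"u": pytest.approx(1.0)}


class TestClusterScore:
    def test_pair_score_is_mean_of_both_directions(self, triangle):
        singles = rwr_single_all(triangle)
        expected = (singles["a"]["b"] + singles["b"]["a"]) / 2
        assert cluster_score({"a", "b"}, singles) == pytest.approx(expected)

    def test_order_invariance_and_min_size(self, triangle):
        singles = rwr_single_all(triangle)
        assert cluster_score(["a", "b", "c"], singles) == pytest.approx(
            cluster_score(["c", "b", "a"], singles)
        )
        with pytest.raises(ValueError):
            cluster_score({"a"}, singles)

    def test_heavy_clique_outscores_scattered_nodes(self):
        rng = np.random.default_rng(3)
        g = random_connected_graph(rng, n=30)
        # plant a heavily connected 4-clique on top of the random background
        edges = {(u, v): w for u, v, w in g.edges()}
        clique = ["n000", "n001", "n002", "n003"]
        for u, v in itertools.combinations(clique, 2):
            edges[(u, v)] = 50.0
        g2 = WeightedGraph(edges)
        singles = rwr_single_all(g2)
        scattered = ["n005", "n012", "n019", "n026"]
        assert cluster_score(clique, singles) > cluster_score(scattered, singles)


class TestClusterSignificance:
    def test_best_possible_subset_attains_minimal_p_value(self):
        # exhaustive enumeration over all size-3 subsets of a 10-node graph
        rng = np.random.default_rng(11)
        g = random_connected_graph(rng, n=10)
        singles = rwr_single_all(g)
        sm = ScoreMatrix(singles)
        best = max(
            itertools.combinations(g.nodes, 3), key=lambda c: cluster_score(c, sm)
        )
        m = 199
        assert cluster_significance(best, sm, m_samples=m, rng_seed=5) == pytest.approx(
            1 / (m + 1)
        )

    def test_random_clusters_get_roughly_uniform_p_values(self):
        rng = np.random.default_rng(17)
        g = random_connected_graph(rng, n=12)
        sm = ScoreMatrix(rwr_single_all(g))
        vals = []
        for t in range(200):
            members = rng.choice(g.nodes, size=3, replace=False)
            vals.append(cluster_significance(members, sm, m_samples=99, rng_seed=t))
        assert 0.4 <= float(np.mean(vals)) <= 0.6

    def test_deterministic_given_seed_and_member_set(self, triangle):
        sm = ScoreMatrix(rwr_single_all(triangle))
        a = cluster_significance(["a", "b"], sm, m_samples=499, rng_seed=9)
        b = cluster_significance(["b", "a"], sm, m_samples=499, rng_seed=9)
        assert a == b
        assert a != cluster_significance(["a", "b"], sm, m_samples=499, rng_seed=10)

    def test_oversized_cluster_rejected(self, triangle):
        sm = ScoreMatrix(rwr_single_all(triangle))
        with pytest.raises(ValueError, match="larger than the graph"):
            cluster_significance(["a", "b", "c", "d"], sm)


class TestExpandFromSeed:
    def test_bridged_cliques_expansion_stays_in_seed_clique(self):
        g, planted = clique_graph([4, 4], weight=10.0)
        edges = {(u, v): w for u, v, w in g.edges()}
        edges[("P000", "P004")] = 0.1  # weak bridge between the cliques
        g = WeightedGraph(edges)
        params = NWEParams(min_size=4, max_size=4, rng_seed=1)
        singles = rwr_single_all(g, params.walk_settings())
        result = expand_from_seed(g, "P001", params, singles)
        assert result is not None and result.members == planted[0]

    def test_empty_size_window_returns_none(self, triangle):
        params = NWEParams(min_size=4, max_size=1)
        singles = rwr_single_all(triangle)
        assert expand_from_seed(triangle, "a", params, singles) is None

    def test_expansion_is_deterministic(self):
        rng = np.random.default_rng(23)
        g = random_connected_graph(rng, n=25)
        params = NWEParams(min_size=3, max_size=6, significance_samples=199, rng_seed=4)
        singles = rwr_single_all(g, params.walk_settings())
        seed = g.nodes[0]
        r1, t1 = expand_from_seed(g, seed, params, singles, return_trace=True)
        r2, t2 = expand_from_seed(g, seed, params, singles, return_trace=True)
        assert t1 == t2
        assert r1 == r2


class TestOverlapAndDedup:
    def test_overlap_ratio_cases(self):
        assert overlap_ratio("abcd", "abcd") == 1.0
        assert overlap_ratio("abcd", "wxyz") == 0.0
        assert overlap_ratio("abcd", "abwxyzpq") == pytest.approx(2 / 4)
        assert overlap_ratio("abcd", "abwxyzpq", measure="jaccard") == pytest.approx(2 / 10)

    def test_identical_clusters_keep_the_more_significant(self):
        a = Cluster(frozenset("abcd"), significance=0.01)
        b = Cluster(frozenset("abcd"), significance=0.2)
        kept = dedup_clusters([b, a], overlap_threshold=0.3)
        assert len(kept) == 1 and kept[0].significance == 0.01

    def test_disjoint_clusters_survive_any_threshold(self):
        a = Cluster(frozenset("abcd"), significance=0.5)
        b = Cluster(frozenset("wxyz"), significance=0.9)
        assert len(dedup_clusters([a, b], overlap_threshold=0.01)) == 2

    def test_greedy_chain_keeps_first_and_nonoverlapping(self):
        # A~B ratio 0.5, B~C ratio 0.5, A~C ratio 0; significances A < C < B
        a = Cluster(frozenset("abcd"), significance=0.01)
        b = Cluster(frozenset({"c", "d", "e", "f"}), significance=0.2)
        c = Cluster(frozenset({"e", "f", "g", "h"}), significance=0.05)
        assert overlap_ratio(a.members, b.members) == 0.5
        assert overlap_ratio(b.members, c.members) == 0.5
        assert overlap_ratio(a.members, c.members) == 0.0
        kept = dedup_clusters([a, b, c], overlap_threshold=0.3)
        assert {k.members for k in kept} == {a.members, c.members}


class TestRunNWE:
    def test_recovers_noisy_planted_cliques(self):
        rng = np.random.default_rng(5)
        g, planted = clique_graph([5] * 5, weight=10.0)
        edges = {(u, v): w for u, v, w in g.edges()}
        nodes = g.nodes
        target_noise = round(0.05 * g.n_edges)
        added = 0
        while added < target_noise:
            i, j = rng.choice(len(nodes), 2, replace=False)
            key = tuple(sorted((nodes[i], nodes[j])))
            if key not in edges:
                edges[key] = 0.5
                added += 1
        noisy = WeightedGraph(edges)
        clusters = run_nwe(noisy, NWEParams(max_size=8, rng_seed=3))
        for complex_members in planted:
            best = max(concordance(complex_members, c.members) for c in clusters)
            assert best >= 0.8

    def test_uniform_equals_node_weighted_when_degrees_are_equal(self):
        # a cycle with constant weights: every node weight is identical
        nodes = [f"c{i}" for i in range(8)]
        edges = {
            tuple(sorted((nodes[i], nodes[(i + 1) % 8]))): 3.0 for i in range(8)
        }
        g = WeightedGraph(edges)
        pu = NWEParams(min_size=3, max_size=5, mode="uniform", significance_samples=199)
        pw = NWEParams(min_size=3, max_size=5, mode="node-weighted", significance_samples=199)
        singles = rwr_single_all(g, pu.walk_settings())
        for seed in g.nodes:
            _, trace_u = expand_from_seed(g, seed, pu, singles, return_trace=True)
            _, trace_w = expand_from_seed(g, seed, pw, singles, return_trace=True)
            assert trace_u == trace_w

    def test_output_respects_size_window_and_overlap_threshold(self):
        rng = np.random.default_rng(31)
        g = random_connected_graph(rng, n=40)
        params = NWEParams(min_size=3, max_size=6, significance_samples=199, rng_seed=2)
        clusters = run_nwe(g, params)
        for c in clusters:
            assert params.min_size <= c.size <= params.max_size
        for c1, c2 in itertools.combinations(clusters, 2):
            assert (
                overlap_ratio(c1.members, c2.members, params.overlap_measure)
                <= params.overlap_threshold
            )

    def test_empty_size_window_yields_empty_cluster_set(self, triangle):
        clusters = run_nwe(triangle, NWEParams(min_size=4, max_size=2))
        assert len(clusters) == 0
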