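"""Synthetic catalog, altered-graph grid, degree-preserving shuffle, grid search."""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from nwe.benchgen import (
    BenchmarkConfig,
    alter_graph,
    altered_graph_suite,
    assign_weights,
    degree_preserving_shuffle,
    grid_search,
    synthesize_catalog,
    table1_nwe_grid,
)
from nwe.benchgen import test_graph as make_test_graph
from nwe.graph_core import ComplexCatalog
from nwe.nwe_expand import NWEParams

from conftest import random_connected_graph


class TestSynthesizeCatalog:
    def test_explicit_sizes_and_counting(self):
        cat = synthesize_catalog(5, size_dist=[4, 4, 5, 6, 8], rng_seed=0)
        assert len(cat) == 5
        assert len(cat.proteins()) == 27
        sets = cat.member_sets()
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_same_seed_is_deterministic(self):
        a = synthesize_catalog(10, rng_seed=3)
        b = synthesize_catalog(10, rng_seed=3)
        assert a.member_sets() == b.member_sets()

    def test_degenerate_size_distribution(self):
        cat = synthesize_catalog(6, size_dist=lambda rng: 4, rng_seed=1)
        assert all(len(m) == 4 for m in cat.member_sets())

    def test_default_sizes_stay_in_catalog_range(self):
        cat = synthesize_catalog(50, rng_seed=2)
        assert all(4 <= len(m) <= 20 for m in cat.member_sets())


class TestTestGraph:
    def test_disjoint_complexes_give_clique_union(self):
        cat = synthesize_catalog(2, size_dist=[4, 5], rng_seed=0)
        g = make_test_graph(cat)
        assert g.n_nodes == 9
        assert g.n_edges == 6 + 10  # C(4,2) + C(5,2)
        assert all(w == 1.0 for _, _, w in g.edges())

    def test_shared_pair_stored_once(self):
        cat = ComplexCatalog(
            (("c1", frozenset("abcd")), ("c2", frozenset("cdef"))), min_size=4
        )
        g = make_test_graph(cat)
        assert g.n_edges == 6 + 6 - 1  # edge (c, d) appears in both cliques

    def test_single_complex_is_complete_graph(self):
        cat = ComplexCatalog((("c1", frozenset("abcdef")),), min_size=4)
        assert make_test_graph(cat).n_edges == 15


class TestAlterGraph:
    @pytest.fixture
    def base(self):
        # 10 complexes of size 5 -> 100 original edges
        return make_test_graph(synthesize_catalog(10, size_dist=[5] * 10, rng_seed=0))

    def test_counts_are_exact(self, base):
        assert base.n_edges == 100
        alt = alter_graph(base, del_ratio=0.4, add_ratio=0.4, rng_seed=1)
        assert len(alt.kept) == 60
        assert len(alt.added) == 40

    def test_identity_alteration(self, base):
        alt = alter_graph(base, 0.0, 0.0, rng_seed=1)
        assert set(alt.kept) == {(u, v) for u, v, _ in base.edges()}
        assert alt.added == ()

    def test_kept_subset_and_added_disjoint_from_originals(self, base):
        originals = {(u, v) for u, v, _ in base.edges()}
        alt = alter_graph(base, 0.8, 1.0, rng_seed=2)
        assert set(alt.kept) <= originals
        assert not (set(alt.added) & originals)
        assert len(set(alt.added)) == len(alt.added)

    def test_heavy_deletion_arithmetic(self, base):
        alt = alter_graph(base, 0.8, 1.0, rng_seed=3)
        assert len(alt.kept) == 100 - round(0.8 * 100)
        assert len(alt.added) == 100

    def test_too_many_additions_rejected(self):
        cat = ComplexCatalog((("c1", frozenset("abcd")),), min_size=4)
        g = make_test_graph(cat)  # K4 has no non-edges
        with pytest.raises(ValueError, match="non-edges"):
            alter_graph(g, 0.0, 1.0, rng_seed=0)


class TestAssignWeights:
    def test_two_regime_integer_bounds(self):
        base = make_test_graph(synthesize_catalog(6, size_dist=[6] * 6, rng_seed=0))
        alt = alter_graph(base, 0.4, 0.4, rng_seed=1)
        g = assign_weights(alt, u_min=70, u_max=30, rng_seed=2)
        kept = set(alt.kept)
        for u, v, w in g.edges():
            assert w == int(w)
            if (u, v) in kept:
                assert 70 <= w <= 100
            else:
                assert 1 <= w <= 30

    def test_degenerate_intervals(self):
        base = make_test_graph(synthesize_catalog(4, size_dist=[5] * 4, rng_seed=0))
        alt = alter_graph(base, 0.2, 0.5, rng_seed=1)
        g = assign_weights(alt, u_min=100, u_max=1, rng_seed=2)
        kept = set(alt.kept)
        for u, v, w in g.edges():
            assert w == (100.0 if (u, v) in kept else 1.0)


class TestAlteredGraphSuite:
    def test_sixteen_graphs_with_exact_edge_counts(self):
        cat = synthesize_catalog(8, size_dist=[5] * 8, rng_seed=0)
        n_edges = make_test_graph(cat).n_edges
        suite = altered_graph_suite(cat, BenchmarkConfig(rng_seed=1))
        assert len(suite) == 16
        for name, graph in suite.items():
            d = 0.4 if "_del0.4_" in name else 0.8
            a = 0.4 if "_add0.4_" in name else 1.0
            assert graph.n_edges == round((1 - d + a) * n_edges)

    def test_same_master_seed_reproduces_suite(self):
        cat = synthesize_catalog(4, size_dist=[5] * 4, rng_seed=0)
        s1 = altered_graph_suite(cat, BenchmarkConfig(rng_seed=7))
        s2 = altered_graph_suite(cat, BenchmarkConfig(rng_seed=7))
        assert {k: g.digest for k, g in s1.items()} == {k: g.digest for k, g in s2.items()}


class TestDegreePreservingShuffle:
    def test_degree_sequence_weight_multiset_and_edge_count_invariant(self):
        rng = np.random.default_rng(0)
        g = random_connected_graph(rng, n=40)
        shuffled = degree_preserving_shuffle(g, 0.3, rng_seed=1)
        deg = lambda gr: {v: len(gr.neighbors(v)) for v in gr.nodes}
        assert deg(shuffled) == deg(g)
        assert Counter(w for _, _, w in shuffled.edges()) == Counter(
            w for _, _, w in g.edges()
        )
        assert shuffled.n_edges == g.n_edges
        assert shuffled.digest != g.digest  # topology actually changed

    def test_zero_ratio_is_identity(self, triangle):
        assert degree_preserving_shuffle(triangle, 0.0, rng_seed=1).digest == triangle.digest

    def test_overconstrained_graph_raises(self, triangle):
        # a triangle admits no double edge swap at all
        with pytest.raises(RuntimeError, match="constrained"):
            degree_preserving_shuffle(triangle, 1.0, rng_seed=1)


class TestGridSearch:
    def test_table_grid_has_81_parameter_sets(self):
        grid = table1_nwe_grid()
        assert len(grid) == 81
        assert len({(p.alpha, p.early_cutoff, p.overlap_threshold, p.max_size) for p in grid}) == 81
        assert all(p.min_size == 4 for p in grid)

    def test_single_point_grid_returns_it(self):
        cat = synthesize_catalog(3, size_dist=[4, 4, 4], rng_seed=0)
        g = make_test_graph(cat)
        params = NWEParams(max_size=6, significance_samples=99)
        runner = lambda graph, p: [m for m in cat.member_sets()]
        best, table = grid_search(runner, {"g": g}, cat, [params])
        assert best is params
        assert table.loc[0, "mean_f"] == 1.0

    def test_tie_breaks_to_first_and_failures_score_zero(self):
        cat = synthesize_catalog(3, size_dist=[4, 4, 4], rng_seed=0)
        g = make_test_graph(cat)
        p1 = NWEParams(alpha=0.6, max_size=6, significance_samples=99)
        p2 = NWEParams(alpha=0.7, max_size=6, significance_samples=99)
        perfect = lambda graph, p: cat.member_sets()
        best, table = grid_search(perfect, {"g": g}, cat, [p1, p2])
        assert best is p1  # identical scores -> first in grid order

        def failing(graph, p):
            raise RuntimeError("boom")

        best, table = grid_search(failing, {"g": g}, cat, [p1])
        assert table.loc[0, "mean_f"] == 0.0
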