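"""Sparsity thresholding, graph metrics vs. independent oracles, rewiring, AUC."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gmsnet as g
from gmsnet.metrics import GLOBAL_METRIC_NAMES


def _random_weights(n, seed):
    rng = np.random.default_rng(seed)
    w = rng.random((n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


def _adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return g.BinaryGraph(a, 0.5, 0.5)


def _random_graph(rng):
    n = int(rng.integers(4, 16))
    p = rng.uniform(0.15, 0.7)
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    a = a + a.T
    return g.BinaryGraph(a, 0.5, 0.5)


class TestThresholdAtSparsity:
    def test_edge_count_round_half_up(self):
        w = _random_weights(90, 1)
        bg = g.threshold_at_sparsity(w, 0.10)
        assert bg.n_edges == 401  # 0.10 * 4005 = 400.5 rounds up

    def test_all_zero_network_warns_empty(self):
        with pytest.warns(UserWarning, match="all-zero"):
            bg = g.threshold_at_sparsity(np.zeros((10, 10)), 0.2)
        assert bg.n_edges == 0

    def test_fewer_positive_weights_keeps_all(self):
        w = np.zeros((10, 10))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.4
        bg = g.threshold_at_sparsity(w, 0.5)
        assert bg.n_edges == 2
        assert bg.sparsity_actual == pytest.approx(2 / 45)

    def test_tie_break_deterministic(self):
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (0, 3), (0, 4)]:
            w[i, j] = w[j, i] = 0.7  # four equal weights at the cutoff
        a = g.threshold_at_sparsity(w, 0.14)  # keep 2 of 15 pairs
        b = g.threshold_at_sparsity(w, 0.14)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        assert a.n_edges == 2
        assert a.adjacency[0, 1] == 1 and a.adjacency[0, 2] == 1

    def test_out_of_range_sparsity(self):
        with pytest.raises(ValueError):
            g.threshold_at_sparsity(_random_weights(5, 0), 1.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_edge_sets_nest_across_sparsity(self, seed):
        w = _random_weights(20, seed)
        prev = None
        for s in (0.1, 0.2, 0.3, 0.5):
            adj = g.threshold_at_sparsity(w, s).adjacency
            if prev is not None:
                assert np.all(adj >= prev)  # superset of the sparser graph
            prev = adj


class TestGlobalMetrics:
    def test_complete_k4(self):
        m = g.compute_global_metrics(_adj_from_edges(4, [(i, j) for i in range(4)
                                                         for j in range(i + 1, 4)]))
        assert m.Cp == pytest.approx(1.0)
        assert m.Lp == pytest.approx(1.0)
        assert m.Eglob == pytest.approx(1.0)

    def test_path_p4(self):
        m = g.compute_global_metrics(_adj_from_edges(4, [(0, 1), (1, 2), (2, 3)]))
        assert m.Cp == pytest.approx(0.0)
        assert m.Lp == pytest.approx(10 / 6)
        assert m.Eglob == pytest.approx((4 + 1 / 3) / 6)

    def test_empty_graph(self):
        m = g.compute_global_metrics(_adj_from_edges(5, []))
        assert m.Cp == 0.0 and m.Eglob == 0.0 and m.Eloc == 0.0
        assert np.isnan(m.Lp)

    def test_oracle_equivalence_random_graphs(self):
        """Cp, Lp, Eglob, Eloc match networkx on random small graphs."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            bg = _random_graph(rng)
            if bg.n_edges == 0:
                continue
            G = nx.from_numpy_array(bg.adjacency)
            m = g.compute_global_metrics(bg)
            assert m.Cp == pytest.approx(nx.average_clustering(G), abs=1e-10)
            assert m.Eglob == pytest.approx(nx.global_efficiency(G), abs=1e-10)
            assert m.Eloc == pytest.approx(nx.local_efficiency(G), abs=1e-10)
            # Lp over connected ordered pairs only
            tot, cnt = 0, 0
            for src, dd in nx.all_pairs_shortest_path_length(G):
                for dst, d in dd.items():
                    if dst != src:
                        tot += d
                        cnt += 1
            if cnt:
                assert m.Lp == pytest.approx(tot / cnt, abs=1e-10)


class TestNodalMetrics:
    def test_star_graph(self):
        bg = _adj_from_edges(5, [(0, i) for i in range(1, 5)])
        nm = g.compute_nodal_metrics(bg)
        assert nm.degree[0] == 4
        assert nm.efficiency[0] == pytest.approx(1.0)
        assert nm.degree[1] == 1
        assert nm.efficiency[1] == pytest.approx((1 + 3 * 0.5) / 4)

    def test_isolated_node(self):
        bg = _adj_from_edges(4, [(0, 1)])
        nm = g.compute_nodal_metrics(bg)
        assert nm.degree[3] == 0
        assert nm.efficiency[3] == 0.0

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(43)
        for _ in range(60):
            bg = _random_graph(rng)
            if bg.n_edges == 0:
                continue
            G = nx.from_numpy_array(bg.adjacency)
            nm = g.compute_nodal_metrics(bg)
            n = bg.n_nodes
            for i in range(n):
                assert nm.degree[i] == G.degree[i]
                dd = nx.single_source_shortest_path_length(G, i)
                e = sum(1.0 / d for v, d in dd.items() if v != i) / (n - 1)
                assert nm.efficiency[i] == pytest.approx(e, abs=1e-10)


class TestRewiring:
    def test_degree_sequence_preserved_all_members(self):
        w = _random_weights(30, 7)
        bg = g.threshold_at_sparsity(w, 0.2)
        ens = g.rewire_random(bg, g.RandomEnsembleConfig(n_random=20, seed=1))
        deg0 = np.sort(bg.adjacency.sum(axis=1))
        for m in ens:
            np.testing.assert_array_equal(np.sort(m.adjacency.sum(axis=1)), deg0)
            assert np.all(np.diag(m.adjacency) == 0)

    def test_ring_lattice_loses_clustering(self):
        G = nx.watts_strogatz_graph(40, 6, 0.0, seed=1)  # pure ring lattice
        bg = g.BinaryGraph(nx.to_numpy_array(G, dtype=np.int8), 0.2, 0.2)
        ens = g.rewire_random(bg, g.RandomEnsembleConfig(n_random=15, seed=2))
        cp_in = g.compute_global_metrics(bg).Cp
        cp_ens = np.mean([g.compute_global_metrics(m).Cp for m in ens])
        assert cp_ens < cp_in

    def test_deterministic_given_seed(self):
        bg = g.threshold_at_sparsity(_random_weights(20, 8), 0.25)
        a = g.rewire_random(bg, g.RandomEnsembleConfig(n_random=3, seed=9))
        b = g.rewire_random(bg, g.RandomEnsembleConfig(n_random=3, seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)

    def test_unswappable_graph_returns_copies_with_warning(self):
        bg = _adj_from_edges(3, [(0, 1)])
        with pytest.warns(UserWarning, match="copies"):
            ens = g.rewire_random(bg, g.RandomEnsembleConfig(n_random=2, seed=1))
        np.testing.assert_array_equal(ens[0].adjacency, bg.adjacency)


class TestSmallWorldNormalization:
    def test_self_ensemble_identity(self):
        bg = g.threshold_at_sparsity(_random_weights(20, 11), 0.3)
        m = g.compute_global_metrics(bg)
        m = g.normalize_small_world(m, [bg] * 5)
        assert m.gamma == pytest.approx(1.0)
        assert m.lam == pytest.approx(1.0)
        assert m.sigma == pytest.approx(1.0)

    def test_watts_strogatz_small_world(self):
        G = nx.watts_strogatz_graph(90, 10, 0.1, seed=3)
        bg = g.BinaryGraph(nx.to_numpy_array(G, dtype=np.int8), 0.11, 0.11)
        m = g.compute_global_metrics(bg)
        ens = g.rewire_random(bg, g.RandomEnsembleConfig(n_random=20, seed=4))
        m = g.normalize_small_world(m, ens)
        assert m.gamma > 1.0
        assert m.lam == pytest.approx(1.0, abs=0.3)
        assert m.sigma > 1.0

    def test_erdos_renyi_sigma_near_one(self):
        G = nx.gnm_random_graph(90, 450, seed=5)
        bg = g.BinaryGraph(nx.to_numpy_array(G, dtype=np.int8), 0.11, 0.11)
        m = g.normalize_small_world(
            g.compute_global_metrics(bg),
            g.rewire_random(bg, g.RandomEnsembleConfig(n_random=20, seed=6)),
        )
        assert m.sigma == pytest.approx(1.0, abs=0.2)


class TestAUC:
    def test_constant_curve(self):
        grid = g.SparsityGrid()
        assert g.auc_over_grid(np.ones(25), grid) == pytest.approx(0.24)

    def test_linear_curve_triangle(self):
        grid = g.SparsityGrid()
        curve = np.linspace(0.0, 1.0, 25)
        assert g.auc_over_grid(curve, grid) == pytest.approx(0.12)

    def test_matches_manual_trapezoid(self):
        grid = g.SparsityGrid(tuple(np.round(np.linspace(0.1, 0.3, 9), 4)))
        rng = np.random.default_rng(12)
        curve = rng.random(9)
        x = grid.array
        manual = sum(
            (curve[i] + curve[i + 1]) / 2 * (x[i + 1] - x[i]) for i in range(8)
        )
        assert g.auc_over_grid(curve, grid) == pytest.approx(manual, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            g.auc_over_grid(np.ones(10), g.SparsityGrid())

    def test_default_grid_matches_stated_range(self):
        grid = g.SparsityGrid()
        assert len(grid) == 25
        assert grid.values[0] == pytest.approx(0.10)
        assert grid.values[-1] == pytest.approx(0.34)

    def test_curves_shapes_and_names(self):
        w = _random_weights(12, 13)
        grid = g.SparsityGrid((0.15, 0.25, 0.34))
        curves = g.metric_curves(w, grid, g.RandomEnsembleConfig(n_random=3, seed=1))
        for name in GLOBAL_METRIC_NAMES:
            assert curves[name].shape == (3,)
        assert curves["degree"].shape == (12, 3)
        summary = g.auc_summary(curves, grid)
        assert summary["degree"].shape == (12,)
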