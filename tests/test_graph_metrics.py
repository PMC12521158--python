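import numpy as np
import pytest

from netsweep import (
    SparsityGrid,
    auc_over_sweep,
    generate_null_networks,
    global_metrics,
    metrics_for_subject,
    nodal_metrics,
    sweep_graphs,
)
from netsweep.metrics import best_partition, modularity_q

from conftest import graph_from_edges, random_fc


def complete_graph(n):
    return graph_from_edges(n, [(i, j) for i in range(n)
                                for j in range(i + 1, n)])


class TestNodalMetrics:
    def test_triangle_is_fully_clustered_and_central(self):
        m = nodal_metrics(complete_graph(3))
        np.testing.assert_allclose(m.clustering, 1.0)
        np.testing.assert_allclose(m.nodal_efficiency, 1.0)
        np.testing.assert_allclose(m.betweenness, 0.0)

    def test_three_node_path_hand_enumeration(self):
        m = nodal_metrics(graph_from_edges(3, [(0, 1), (1, 2)]))
        assert m.betweenness[1] == pytest.approx(1.0)
        assert m.betweenness[0] == m.betweenness[2] == 0.0
        assert m.nodal_efficiency[1] == pytest.approx(1.0)
        assert m.nodal_efficiency[0] == pytest.approx(0.75)

    def test_star_center_routes_all_leaf_pairs(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        m = nodal_metrics(star)
        assert m.betweenness[0] == pytest.approx(6.0)  # C(4,2)
        np.testing.assert_allclose(m.betweenness[1:], 0.0)
        np.testing.assert_array_equal(m.degree_centrality, [4, 1, 1, 1, 1])

    def test_isolated_node_has_zero_clustering_and_efficiency(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2)])
        m = nodal_metrics(g)
        assert m.clustering[3] == 0.0
        assert m.nodal_efficiency[3] == 0.0


class TestGlobalMetrics:
    @pytest.mark.parametrize("n", [3, 5, 7])
    def test_complete_graph_closed_forms(self, n):
        gm = global_metrics(complete_graph(n), nulls=None)
        assert gm.Cp == pytest.approx(1.0)
        assert gm.Lp == pytest.approx(1.0)
        assert gm.Eglob == pytest.approx(1.0)
        assert gm.Eloc == pytest.approx(1.0)

    def test_three_node_path_lengths_and_efficiency(self):
        gm = global_metrics(graph_from_edges(3, [(0, 1), (1, 2)]),
                            nulls=None)
        assert gm.Lp == pytest.approx(4 / 3)
        assert gm.Eglob == pytest.approx(5 / 6)

    def test_star_graph_is_perfectly_disassortative(self):
        star = graph_from_edges(6, [(0, i) for i in range(1, 6)])
        gm = global_metrics(star, nulls=None)
        assert gm.assortativity == pytest.approx(-1.0)

    def test_two_cliques_partition_modularity(self):
        g = graph_from_edges(8, [(i, j) for i in range(4)
                                 for j in range(i + 1, 4)]
                             + [(i, j) for i in range(4, 8)
                                for j in range(i + 1, 8)])
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert modularity_q(g.adjacency, labels) == pytest.approx(0.5)
        # Louvain should find exactly this optimum
        _, q = best_partition(g.adjacency, n_runs=5, seed=0)
        assert q == pytest.approx(0.5)

    def test_sigma_is_exactly_gamma_over_lambda(self, rng):
        g = sweep_graphs(random_fc(25, rng),
                         SparsityGrid(np.array([0.25])))[0]
        nulls = generate_null_networks(g, 20, seed=9)
        gm = global_metrics(g, nulls)
        assert gm.sigma == gm.gamma / gm.lambda_

    def test_missing_null_ensemble_yields_nan_normalization(self, rng):
        g = sweep_graphs(random_fc(10, rng),
                         SparsityGrid(np.array([0.3])))[0]
        gm = global_metrics(g, nulls=None)
        assert np.isnan(gm.gamma) and np.isnan(gm.lambda_) \
            and np.isnan(gm.sigma)

    def test_empty_graph_is_an_error(self):
        from netsweep import BinaryGraph
        g = BinaryGraph(np.zeros((4, 4), dtype=np.int8), 0.1)
        with pytest.raises(ValueError, match="empty"):
            global_metrics(g, nulls=None)

    def test_best_of_runs_modularity_is_monotone(self, rng):
        g = sweep_graphs(random_fc(40, rng),
                         SparsityGrid(np.array([0.15])))[0]
        qs = [best_partition(g.adjacency, n_runs=k, seed=5)[1]
              for k in (1, 3, 10)]
        assert qs[0] <= qs[1] <= qs[2]


class TestNullNetworks:
    def test_degree_sequence_preserved_exactly(self, rng):
        g = sweep_graphs(random_fc(30, rng),
                         SparsityGrid(np.array([0.2])))[0]
        deg = g.adjacency.sum(axis=1)
        for nl in generate_null_networks(g, 10, seed=4):
            np.testing.assert_array_equal(nl.adjacency.sum(axis=1), deg)
            assert np.all(np.diag(nl.adjacency) == 0)

    def test_rewiring_destroys_lattice_triangles(self):
        n, k = 30, 6
        a = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                a[i, (i + d) % n] = a[(i + d) % n, i] = 1
        from netsweep import BinaryGraph
        ring = BinaryGraph(a, 0.2)
        cp_ring = global_metrics(ring, nulls=None).Cp
        nulls = generate_null_networks(ring, 20, seed=8)
        cp_null = np.mean([global_metrics(nl, nulls=None).Cp
                           for nl in nulls])
        assert cp_null < cp_ring

    def test_same_seed_reproduces_ensemble(self, rng):
        g = sweep_graphs(random_fc(15, rng),
                         SparsityGrid(np.array([0.3])))[0]
        e1 = generate_null_networks(g, 5, seed=3)
        e2 = generate_null_networks(g, 5, seed=3)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_star_graph_warns_and_returns_copies(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        with pytest.warns(UserWarning, match="no valid"):
            nulls = generate_null_networks(star, 3, seed=1)
        for nl in nulls:
            np.testing.assert_array_equal(nl.adjacency, star.adjacency)


class TestAucOverSweep:
    def test_constant_unit_curve_integrates_to_range_width(self):
        grid = SparsityGrid()
        assert auc_over_sweep(np.ones(25), grid) == pytest.approx(0.24)

    def test_identity_curve_trapezoid_by_hand(self):
        grid = SparsityGrid(np.array([0.1, 0.2, 0.3]))
        assert auc_over_sweep(np.array([0.1, 0.2, 0.3]), grid) == \
            pytest.approx(0.04)

    def test_zero_curve(self):
        assert auc_over_sweep(np.zeros(25), SparsityGrid()) == 0.0

    def test_linearity(self, rng):
        grid = SparsityGrid()
        v, w = rng.normal(size=25), rng.normal(size=25)
        lhs = auc_over_sweep(2.5 * v - 1.5 * w, grid)
        rhs = 2.5 * auc_over_sweep(v, grid) - 1.5 * auc_over_sweep(w, grid)
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            auc_over_sweep(np.ones(10), SparsityGrid())


class TestMetricsForSubject:
    def test_deterministic_given_seed_and_curves_bounded(self, rng):
        fc = random_fc(30, rng)
        grid = SparsityGrid(np.array([0.15, 0.2, 0.25]))
        m1 = metrics_for_subject(fc, grid, n_nulls=10, seed=42)
        m2 = metrics_for_subject(fc, grid, n_nulls=10, seed=42)
        for name in m1.global_curves:
            np.testing.assert_array_equal(m1.global_curves[name],
                                          m2.global_curves[name])
        for name in m1.nodal_curves:
            np.testing.assert_array_equal(m1.nodal_curves[name],
                                          m2.nodal_curves[name])
        width = grid.thresholds[-1] - grid.thresholds[0]
        assert 0 < m1.global_auc["Cp"] < width
        np.testing.assert_array_equal(
            m1.global_curves["sigma"],
            m1.global_curves["gamma"] / m1.global_curves["lambda"])

    def test_tidy_export_schema(self, rng):
        fc = random_fc(10, rng)
        grid = SparsityGrid(np.array([0.2, 0.3]))
        m = metrics_for_subject(fc, grid, n_nulls=5, seed=0)
        tidy = m.to_tidy()
        assert set(tidy.columns) == {"subject_id", "metric", "scope",
                                     "node_label", "threshold", "value"}
        # 9 global curves + 4 nodal metrics x 10 nodes, 2 thresholds each
        assert len(tidy) == (9 + 4 * 10) * 2
        aucs = m.auc_rows()
        assert len(aucs) == 9 + 4 * 10
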