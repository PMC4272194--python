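"""Adjacency structures, ICAR precisions, global extension and partial correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stcar
from stcar.stgraph import EdgeSet

from conftest import dense_gmrf_conditional


class TestSpatialGraph:
    def test_symmetry_and_dedup(self):
        g = stcar.SpatialGraph(3, ((1, 0), (0, 1), (2, 1)))
        assert g.edges == ((0, 1), (1, 2))

    @pytest.mark.parametrize("bad", [((0, 0),), ((0, 5),)])
    def test_invalid_edges_rejected(self, bad):
        with pytest.raises(ValueError):
            stcar.SpatialGraph(3, bad)

    def test_isolated_area_warns(self):
        import warnings

        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            stcar.SpatialGraph(3, ((0, 1),))
        assert any("no spatial neighbours" in str(w.message) for w in rec)


class TestSTAdjacency:
    @pytest.mark.parametrize(
        "graph_dims,T,expected",
        [((2, 2), 2, 12), ((2, 2), 1, 4)],  # 4*2 + 4*1; T=1 has no temporal links
    )
    def test_estimable_element_count_grid(self, graph_dims, T, expected):
        g = stcar.make_lattice(*graph_dims)
        adj = stcar.build_st_adjacency(g, T)
        assert adj.n_estimable() == expected
        assert len(adj.to_edgeset()) == expected

    def test_estimable_element_count_city_scale(self):
        # K=271 areas with 712 border pairs over 5 periods gives 4644
        # estimable relations for 1355 observations
        rng = np.random.default_rng(0)
        K, m = 271, 712
        edges = set()
        for k in range(1, K):  # spanning path keeps the graph connected
            edges.add((k - 1, k))
        while len(edges) < m:
            a, b = rng.integers(0, K, 2)
            if a != b:
                edges.add((min(a, b), max(a, b)))
        g = stcar.SpatialGraph(K, tuple(edges))
        adj = stcar.build_st_adjacency(g, 5)
        assert adj.n_estimable() == 4644
        assert adj.n_cells == 1355

    def test_invalid_arguments(self, grid22):
        with pytest.raises(ValueError):
            stcar.build_st_adjacency(grid22, 0)

    @given(rows=st.integers(2, 4), cols=st.integers(2, 4), T=st.integers(1, 4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_element_count_formula(self, rows, cols, T):
        g = stcar.make_lattice(rows, cols)
        adj = stcar.build_st_adjacency(g, T)
        K = rows * cols
        assert adj.n_estimable() == T * g.n_edges + K * (T - 1)

    def test_edgeset_roundtrip(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 3)
        rng = np.random.default_rng(1)
        es = adj.to_edgeset()
        vals = rng.integers(0, 2, len(es)).astype(np.uint8)
        es2 = EdgeSet(es.entries, vals)
        adj.set_from_edgeset(es2)
        assert adj.to_edgeset() == es2

    def test_w_matrix_structure(self, grid22):
        adj = stcar.build_st_adjacency(grid22, 3)
        W = adj.matrix().toarray()
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0)
        K = 4
        # off-diagonal blocks between non-adjacent periods must vanish
        assert np.all(W[:K, 2 * K :] == 0)
        # blocks between consecutive periods are the identity
        assert np.allclose(W[:K, K : 2 * K], np.eye(K))


class TestIcarPrecision:
    def test_path_graph_matrix(self, path3):
        Q = stcar.icar_precision(path3).Q.toarray()
        assert np.allclose(Q, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_row_sums_zero_any_state(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        rng = np.random.default_rng(7)
        es = adj.to_edgeset()
        adj.set_from_edgeset(
            EdgeSet(es.entries, rng.integers(0, 2, len(es)).astype(np.uint8))
        )
        Q = stcar.icar_precision(adj).Q
        assert np.abs(np.asarray(Q.sum(axis=1))).max() == 0

    def test_rank_of_connected_st_graph(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        Q = stcar.icar_precision(adj)
        dense_rank = np.linalg.matrix_rank(Q.Q.toarray())
        assert Q.rank() == dense_rank == 17  # KT - 1

    def test_psd_and_null_space(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        Q = stcar.icar_precision(adj).Q.toarray()
        w = np.linalg.eigvalsh(Q)
        assert w.min() > -1e-10
        assert np.allclose(Q @ np.ones(Q.shape[0]), 0)


class TestExtendWithGlobal:
    def test_global_state_gives_zero_w_star(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        ext = stcar.extend_with_global(adj)
        assert not ext.w_star.any()

    def test_all_zero_state_gives_all_ones(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        adj.spatial_state[:] = 0
        adj.temporal_state[:] = 0
        ext = stcar.extend_with_global(adj)
        assert ext.w_star.all()

    def test_single_cut_edge_flags_exactly_two_cells(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        t, e = 1, 3
        a, b = adj.graph.edges[e]
        adj.spatial_state[t, e] = 0
        ext = stcar.extend_with_global(adj)
        K = 9
        expected = np.zeros(18, dtype=np.uint8)
        expected[t * K + a] = expected[t * K + b] = 1
        assert np.array_equal(ext.w_star, expected)

    def test_boundary_periods_skip_absent_terms(self, grid22):
        # all relations on: cells at t=1 and t=T have fewer permitted relations
        # but none estimated zero, so w_star stays 0 there too
        adj = stcar.build_st_adjacency(grid22, 3)
        ext = stcar.extend_with_global(adj)
        assert not ext.w_star.any()

    def test_cut_temporal_link_flags_both_periods(self, grid22):
        adj = stcar.build_st_adjacency(grid22, 3)
        adj.temporal_state[2, 0] = 0  # area 2 between periods 0 and 1
        ext = stcar.extend_with_global(adj)
        flagged = np.flatnonzero(ext.w_star)
        assert set(flagged) == {2, 4 + 2}


class TestConditionalMoments:
    def test_simple_average(self, path3):
        adj = stcar.build_st_adjacency(path3, 2)
        ext = stcar.extend_with_global(adj)
        # cell (1, 0): spatial neighbours 0 and 2 at t=0, temporal self at t=1
        phi = np.zeros(7)
        phi[0], phi[2] = 0.2, 0.4
        phi[3 + 1] = 0.6
        mean, var = stcar.conditional_moments(ext, phi, tau=1.0, cell=(1, 0))
        assert mean == pytest.approx((0.2 + 0.4 + 0.6) / 3)
        assert var == pytest.approx(1 / 3)

    def test_isolated_cell_uses_global(self, path3):
        adj = stcar.build_st_adjacency(path3, 2)
        adj.spatial_state[:] = 0
        adj.temporal_state[:] = 0
        ext = stcar.extend_with_global(adj)
        phi = np.zeros(7)
        phi[-1] = 0.9
        mean, var = stcar.conditional_moments(ext, phi, tau=2.0, cell=(1, 0))
        assert mean == pytest.approx(0.9)
        assert var == pytest.approx(1 / 2)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_dense_oracle(self, grid33, seed):
        rng = np.random.default_rng(seed)
        adj = stcar.build_st_adjacency(grid33, 3)
        es = adj.to_edgeset()
        vals = rng.integers(0, 2, len(es)).astype(np.uint8)
        adj.set_from_edgeset(EdgeSet(es.entries, vals))
        ext = stcar.extend_with_global(adj)
        Q = stcar.icar_precision(ext).Q.toarray()
        tau = 1.7
        phi = rng.standard_normal(Q.shape[0])
        k, t = int(rng.integers(9)), int(rng.integers(3))
        i = adj.cell_index(k, t)
        rest, coef, var = dense_gmrf_conditional(Q, tau, i)
        mean, v = stcar.conditional_moments(ext, phi, tau, (k, t))
        assert mean == pytest.approx(float(coef @ phi[rest]), abs=1e-5)
        assert v == pytest.approx(var, rel=1e-4)


class TestPartialCorrelation:
    def test_linked_cells(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        # centre cell of the grid has 4 spatial neighbours + 1 temporal = 5
        assert adj.cell_degree(4, 0) == 5
        rho = stcar.partial_correlation(adj, (4, 0), (4, 1))
        assert rho == pytest.approx(1 / np.sqrt(5 * 5))

    def test_unlinked_cells_zero(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 2)
        assert stcar.partial_correlation(adj, (0, 0), (8, 1)) == 0.0

    def test_against_inverse_oracle(self, grid33):
        adj = stcar.build_st_adjacency(grid33, 3)
        Q = stcar.icar_precision(adj).Q.toarray()
        eps = 1e-8
        n = Q.shape[0]
        cov = np.linalg.inv(Q + eps * np.eye(n))
        i, j = adj.cell_index(4, 1), adj.cell_index(5, 1)
        rest = [r for r in range(n) if r not in (i, j)]
        S_ab = cov[np.ix_([i, j], [i, j])]
        S_ar = cov[np.ix_([i, j], rest)]
        S_rr = cov[np.ix_(rest, rest)]
        C = S_ab - S_ar @ np.linalg.solve(S_rr, S_ar.T)
        oracle = C[0, 1] / np.sqrt(C[0, 0] * C[1, 1])
        rho = stcar.partial_correlation(adj, (4, 1), (5, 1))
        assert rho == pytest.approx(oracle, abs=1e-5)

    def test_degree_zero_errors(self, path3):
        adj = stcar.build_st_adjacency(path3, 1)
        adj.spatial_state[:] = 0
        with pytest.raises(ValueError):
            stcar.partial_correlation(adj, (0, 0), (1, 0))
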