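"""Diffusion, optimal transport and curvature contracts."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.optimize import linprog

from orcnet import (
    build_laplacian,
    critical_curvature,
    curvature_trace,
    default_tau_grid,
    diffuse,
    edge_curvature,
    find_tau_crit,
    integrate_kappa,
    truncate_distribution,
    wasserstein_w1,
)
from orcnet.curvature import CurvatureTrace, _GraphFlowSolver

from conftest import network_from_shifted, random_connected_network


def w1_bruteforce(p, q, d):
    """Independent oracle: the full n x n coupling linear program."""
    n = len(p)
    A_eq = sp.vstack([
        sp.kron(sp.eye(n), np.ones((1, n))),
        sp.kron(np.ones((1, n)), sp.eye(n)),
    ]).tocsr()
    res = linprog(d.ravel(), A_eq=A_eq, b_eq=np.concatenate([p, q]),
                  method="highs")
    assert res.success
    return res.fun


class TestLaplacian:
    def test_two_vertex_row_normalization_cancels_weight(self, two_vertex_network):
        op = build_laplacian(two_vertex_network)
        assert np.allclose(op.L, [[1, -1], [-1, 1]])

    def test_triangle_equal_weights_is_identity_minus_half_adjacency(self):
        net = network_from_shifted({("a", "b"): 0.6, ("b", "c"): 0.6,
                                    ("a", "c"): 0.6})
        op = build_laplacian(net)
        A = np.ones((3, 3)) - np.eye(3)
        assert np.allclose(op.L, np.eye(3) - A / 2)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        net = random_connected_network(rng, 20)
        op = build_laplacian(net)
        assert np.abs(op.L.sum(axis=1)).max() < 1e-12

    def test_offdiagonal_nonpositive(self):
        rng = np.random.default_rng(1)
        net = random_connected_network(rng, 12)
        L = build_laplacian(net).L
        off = L[~np.eye(len(L), dtype=bool)]
        assert (off <= 1e-15).all()

    def test_scaling_all_correlations_leaves_laplacian_unchanged(self):
        rng = np.random.default_rng(2)
        net = random_connected_network(rng, 10)
        L1 = build_laplacian(net).L
        for e in net.graph.edges:
            net.graph.edges[e]["rho_shifted"] *= 0.37
        L2 = build_laplacian(net).L
        assert np.allclose(L1, L2, atol=1e-12)


class TestDiffusion:
    def test_tau_zero_is_identity(self, two_vertex_network):
        op = build_laplacian(two_vertex_network)
        assert np.array_equal(diffuse(op, 0.0), np.eye(2))

    @pytest.mark.parametrize("t", [0.1, 0.5, 2.0])
    def test_two_vertex_closed_form(self, two_vertex_network, t):
        op = build_laplacian(two_vertex_network)
        D = diffuse(op, t)
        a = (1 + np.exp(-2 * t)) / 2
        b = (1 - np.exp(-2 * t)) / 2
        assert np.allclose(D, [[a, b], [b, a]], atol=1e-10)

    def test_rows_are_probability_vectors_across_grid(self):
        rng = np.random.default_rng(5)
        net = random_connected_network(rng, 25)
        op = build_laplacian(net)
        for tau in default_tau_grid(n_tau=25):
            D = diffuse(op, tau)
            assert D.min() >= 0
            assert np.abs(D.sum(axis=1) - 1).max() < 1e-9

    def test_large_tau_reaches_common_stationary_distribution(self):
        rng = np.random.default_rng(6)
        net = random_connected_network(rng, 15)
        D = diffuse(build_laplacian(net), 100.0)
        tv = 0.5 * np.abs(D - D.mean(axis=0)).sum(axis=1)
        assert tv.max() < 1e-6

    def test_negative_tau_rejected(self, two_vertex_network):
        with pytest.raises(ValueError):
            diffuse(build_laplacian(two_vertex_network), -1.0)


class TestTruncation:
    def test_zero_floor_is_identity(self):
        p = np.array([0.5, 0.3, 0.2])
        assert truncate_distribution(p, 0.0) is p

    def test_small_mass_dropped_and_renormalized(self):
        p = np.array([0.5, 0.5, 1e-9])
        out = truncate_distribution(p, 1e-6)
        assert np.allclose(out, [0.5, 0.5, 0.0])
        assert out.sum() == pytest.approx(1.0)

    def test_everything_below_floor_rejected(self):
        with pytest.raises(ValueError):
            truncate_distribution(np.array([1e-9, 1e-9]), 1e-6)

    def test_truncated_w1_close_to_exact(self):
        rng = np.random.default_rng(7)
        net = random_connected_network(rng, 30)
        op = build_laplacian(net)
        D = diffuse(op, 0.5)
        i, j = net.index[net.edges[0][0]], net.index[net.edges[0][1]]
        exact = wasserstein_w1(D[i], D[j], net.d)
        p = truncate_distribution(D[i], 1e-6)
        q = truncate_distribution(D[j], 1e-6)
        assert abs(wasserstein_w1(p, q, net.d) - exact) < 1e-4


class TestWasserstein:
    def test_identical_distributions_cost_zero(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.array([0.3, 0.7])
        assert wasserstein_w1(p, p, d) == 0.0

    def test_dirac_pair_equals_distance(self):
        rng = np.random.default_rng(8)
        net = random_connected_network(rng, 6)
        n = len(net.nodes)
        p, q = np.zeros(n), np.zeros(n)
        p[0], q[3] = 1.0, 1.0
        assert wasserstein_w1(p, q, net.d) == pytest.approx(net.d[0, 3])

    def test_three_vertex_path_split_mass(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        p = np.array([1.0, 0.0, 0.0])
        q = np.array([0.0, 0.5, 0.5])
        assert wasserstein_w1(p, q, d) == pytest.approx(1.5)

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        net = random_connected_network(rng, 7)
        n = len(net.nodes)
        p = rng.dirichlet(np.ones(n))
        q = rng.dirichlet(np.ones(n))
        assert wasserstein_w1(p, q, net.d) == pytest.approx(
            wasserstein_w1(q, p, net.d), abs=1e-10)

    def test_unnormalized_input_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            wasserstein_w1(np.array([0.5, 0.4]), np.array([0.5, 0.5]), d)

    def test_matches_bruteforce_coupling_lp(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            net = random_connected_network(rng, int(rng.integers(3, 8)))
            n = len(net.nodes)
            p = rng.dirichlet(np.ones(n))
            q = rng.dirichlet(np.ones(n))
            assert wasserstein_w1(p, q, net.d) == pytest.approx(
                w1_bruteforce(p, q, net.d), abs=1e-8)

    def test_flow_solver_agrees_with_coupling_lp_on_both_paths(self):
        rng = np.random.default_rng(11)
        net = random_connected_network(rng, 12)
        _, ei, ej, _, w = net.edge_arrays()
        solver = _GraphFlowSolver(len(net.nodes), ei, ej, w)
        p = rng.dirichlet(np.ones(len(net.nodes)))
        q = rng.dirichlet(np.ones(len(net.nodes)))
        expected = wasserstein_w1(p, q, net.d)
        assert solver.solve(p - q) == pytest.approx(expected, abs=1e-7)
        solver._highs = None  # exercise the linprog fallback route
        assert solver.solve(p - q) == pytest.approx(expected, abs=1e-7)


class TestEdgeCurvature:
    def test_equal_distributions_give_curvature_one(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        p = np.array([0.5, 0.5])
        assert edge_curvature(p, p, d, (0, 1)) == pytest.approx(1.0)

    def test_undiffused_deltas_give_zero(self):
        d = np.array([[0.0, 2.0], [2.0, 0.0]])
        p = np.array([1.0, 0.0])
        q = np.array([0.0, 1.0])
        assert edge_curvature(p, q, d, (0, 1)) == pytest.approx(0.0)

    def test_zero_distance_rejected(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            edge_curvature(np.array([1.0, 0]), np.array([0, 1.0]), d, (0, 1))


class TestCurvatureTrace:
    def test_k4_symmetry_one_kappa_per_tau(self):
        edges = {(a, b): 0.7 for a in "abcd" for b in "abcd" if a < b}
        net = network_from_shifted(edges)
        trace = curvature_trace(net, default_tau_grid(n_tau=7))
        for t in range(7):
            assert np.ptp(trace.kappa[:, t]) < 1e-8

    def test_small_tau_kappa_near_zero_large_tau_near_one(self, barbell_network):
        trace = curvature_trace(barbell_network, np.array([1e-2, 1e2]))
        assert np.abs(trace.kappa[:, 0]).max() < 0.05
        assert trace.kappa[:, 1].min() > 0.99

    def test_kappa_never_exceeds_one(self, barbell_network):
        trace = curvature_trace(barbell_network, default_tau_grid(n_tau=15))
        assert trace.kappa.max() <= 1.0 + 1e-12

    def test_bridge_edge_has_minimum_curvature_at_intermediate_scales(
            self, barbell_network):
        grid = default_tau_grid(n_tau=15)
        trace = curvature_trace(barbell_network, grid)
        bridge = trace.edges.index(("c", "d"))
        for t, tau in enumerate(grid):
            if 0.05 < tau < 20:
                others = np.delete(trace.kappa[:, t], bridge)
                assert trace.kappa[bridge, t] < others.min()

    def test_large_tau_exceeds_small_tau_for_every_edge(self):
        rng = np.random.default_rng(12)
        net = random_connected_network(rng, 12)
        trace = curvature_trace(net, np.array([1e-2, 1e2]))
        assert (trace.kappa[:, 1] > trace.kappa[:, 0]).all()

    def test_scale_invariance_of_kappa(self):
        rng = np.random.default_rng(13)
        net = random_connected_network(rng, 8)
        grid = np.array([0.1, 1.0])
        before = curvature_trace(net, grid).kappa
        for e in net.graph.edges:
            net.graph.edges[e]["rho_shifted"] *= 2.7
        after = curvature_trace(net, grid).kappa
        assert np.allclose(before, after, atol=1e-7)

    def test_mass_floor_zero_reproduces_dense_computation(self, barbell_network):
        grid = default_tau_grid(n_tau=5)
        dense = curvature_trace(barbell_network, grid, mass_floor=0.0)
        again = curvature_trace(barbell_network, grid, mass_floor=0.0)
        assert np.array_equal(dense.kappa, again.kappa)

    def test_unsorted_grid_rejected(self, barbell_network):
        with pytest.raises(ValueError):
            curvature_trace(barbell_network, np.array([1.0, 0.5]))


class TestCriticalScale:
    def _trace(self, kappa, taus):
        return CurvatureTrace(edges=[("a", "b")] * kappa.shape[0],
                              tau_grid=np.asarray(taus, float),
                              kappa=np.asarray(kappa, float))

    def test_all_ones_selects_first_grid_point(self):
        trace = self._trace(np.ones((4, 3)), [0.1, 1.0, 10.0])
        assert find_tau_crit(trace) == 0.1

    def test_condition_never_met_raises(self):
        trace = self._trace(np.full((4, 3), 0.5), [0.1, 1.0, 10.0])
        with pytest.raises(ValueError, match="grid"):
            find_tau_crit(trace)

    def test_percentile_is_interpolated_over_edges(self):
        # 99th percentile of [0.5, 0.5, 0.5, 1.0] = 0.985 >= 0.75
        kappa = np.array([[0.5], [0.5], [0.5], [1.0]])
        trace = self._trace(kappa, [1.0])
        assert find_tau_crit(trace) == 1.0

    def test_fraction_mode_requires_mass_of_edges(self):
        kappa = np.array([[0.5], [0.5], [0.5], [1.0]])
        trace = self._trace(kappa, [1.0])
        with pytest.raises(ValueError):
            find_tau_crit(trace, mode="fraction")


class TestIntegration:
    def test_constant_kappa_averages_to_itself(self):
        taus = np.linspace(0.01, 2.0, 9)
        trace = CurvatureTrace(edges=[("a", "b")], tau_grid=taus,
                               kappa=np.full((1, 9), 0.42))
        bar, raw = integrate_kappa(trace, 2.0)
        assert bar[0] == pytest.approx(0.42)
        assert raw[0] == pytest.approx(0.42 * (2.0 - 0.01))

    def test_linear_ramp_averages_to_half(self):
        taus = np.linspace(0.01, 1.0, 200)
        kappa = ((taus - 0.01) / (1.0 - 0.01))[None, :]
        trace = CurvatureTrace(edges=[("a", "b")], tau_grid=taus, kappa=kappa)
        bar, _ = integrate_kappa(trace, 1.0)
        assert bar[0] == pytest.approx(0.5, abs=1e-3)

    def test_average_bounded_by_pointwise_range(self):
        rng = np.random.default_rng(14)
        taus = np.sort(rng.uniform(0.01, 5, 12))
        kappa = rng.uniform(-1, 1, (3, 12))
        trace = CurvatureTrace(edges=[("a", "b")] * 3, tau_grid=taus, kappa=kappa)
        bar, _ = integrate_kappa(trace, taus[-1])
        assert (bar <= kappa.max(axis=1) + 1e-12).all()
        assert (bar >= kappa.min(axis=1) - 1e-12).all()

    def test_tau_crit_outside_grid_rejected(self):
        trace = CurvatureTrace(edges=[("a", "b")], tau_grid=np.array([0.1, 1.0]),
                               kappa=np.zeros((1, 2)))
        with pytest.raises(ValueError):
            integrate_kappa(trace, 0.5)
        with pytest.raises(ValueError):
            integrate_kappa(trace, 0.01)


class TestCriticalCurvatureDriver:
    def test_early_stop_matches_full_sweep(self, barbell_network):
        grid = default_tau_grid(n_tau=11)
        fast = critical_curvature(barbell_network, grid, early_stop=True)
        full = critical_curvature(barbell_network, grid, early_stop=False)
        assert fast.tau_crit == full.tau_crit
        for e in fast.edges:
            assert fast.kappa_bar_crit[e] == pytest.approx(full.kappa_bar_crit[e])

    def test_kappa_bar_crit_magnitude_bounded(self, barbell_network):
        trace = critical_curvature(barbell_network, default_tau_grid(n_tau=11))
        assert max(abs(v) for v in trace.kappa_bar_crit.values()) <= 1.0

    def test_threads_do_not_change_values(self, barbell_network):
        grid = default_tau_grid(n_tau=5)
        one = curvature_trace(barbell_network, grid, threads=1)
        two = curvature_trace(barbell_network, grid, threads=2)
        assert np.allclose(one.kappa, two.kappa, atol=1e-9)
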