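"""MM updates, block-coordinate fitting and quasi-Newton acceleration."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cpba.estimation import (
    FitSettings,
    SecantBuffer,
    fit_parameters,
    init_propensities,
    qn_accelerate,
    update_p_frobenius,
    update_p_poisson,
    update_R_frobenius,
    update_R_poisson,
)
from cpba.model import CPBAModel, frobenius_objective, poisson_loglik

from conftest import random_instance


def _objective(kind):
    return frobenius_objective if kind == "frobenius" else poisson_loglik


def _eval(A, c, p, R, kind):
    return _objective(kind)(A, CPBAModel(c=c, p=p, R=R, objective_kind=kind))


COUNTS3 = np.array([[0.0, 2, 0], [2, 0, 4], [0, 4, 0]])  # n_12=2, n_13=0, n_23=4


class TestSimilarityUpdates:
    def test_poisson_direct_formula(self):
        # a={node0}, b={nodes 1,2}: total count 6, propensity sums 1 and 4
        A = np.array([[0.0, 2, 4], [2, 0, 0], [4, 0, 0]])
        R = update_R_poisson(A, np.array([1, 2, 2]), np.array([1.0, 1.0, 3.0]))
        assert R[1, 2] == pytest.approx(6.0 / 4.0)
        assert R[2, 1] == R[1, 2]
        assert R[1, 1] == 1.0 and R[2, 2] == 1.0

    def test_no_edges_between_clusters_gives_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 3.0
        R = update_R_poisson(A, np.array([1, 1, 2, 2]), np.array([1.0, 1, 1, 1]))
        assert R[1, 2] == 0.0

    def test_zero_propensity_cluster_with_edges_raises(self):
        A = np.zeros((3, 3))
        A[0, 2] = A[2, 0] = 1.0
        with pytest.raises(ValueError, match="unidentifiable"):
            update_R_poisson(A, np.array([1, 1, 2]), np.array([1.0, 1.0, 0.0]))

    def test_frobenius_direct_formula(self):
        A = np.array([[0.0, 0.5], [0.5, 0.0]])
        R = update_R_frobenius(A, np.array([1, 2]), np.array([1.0, 0.5]))
        assert R[1, 2] == pytest.approx(1.0)

    def test_frobenius_zero_cross_block(self):
        A = np.zeros((4, 4))
        R = update_R_frobenius(A, np.array([1, 1, 2, 2]), np.ones(4))
        assert R[1, 2] == 0.0

    @pytest.mark.parametrize("kind", ["poisson", "frobenius"])
    def test_update_zeroes_numeric_partial(self, kind, rng):
        """The closed-form R update is a stationary point of the objective."""
        update = update_R_poisson if kind == "poisson" else update_R_frobenius
        for _ in range(10):
            A, model = random_instance(rng, n=10, K=3, kind=kind)
            R = update(A, model.c, model.p)
            h = 1e-5
            for a in range(1, 4):
                for b in range(a + 1, 4):
                    for sign in (+1, -1):
                        Rs = R.copy()
                        Rs[a, b] = Rs[b, a] = R[a, b] + sign * h
                        val = _eval(A, model.c, model.p, Rs, kind)
                        if sign > 0:
                            hi = val
                        else:
                            lo = val
                    deriv = (hi - lo) / (2 * h)
                    assert abs(deriv) < 1e-6


class TestPropensityUpdates:
    def test_poisson_hand_evaluation(self):
        p = update_p_poisson(COUNTS3, np.ones(3, dtype=int), np.ones(3), np.eye(2))
        assert p == pytest.approx([1.0, np.sqrt(3.0), np.sqrt(2.0)])

    def test_poisson_fixed_point_at_exact_factorization(self, rng):
        p = rng.uniform(0.5, 2.0, 6)
        A = np.outer(p, p)
        np.fill_diagonal(A, 0.0)
        p1 = update_p_poisson(A, np.ones(6, dtype=int), p, np.eye(2))
        assert p1 == pytest.approx(p, rel=1e-12)

    def test_isolated_node_maps_to_zero(self):
        p = update_p_poisson(COUNTS3 * [[1, 1, 0], [1, 1, 0], [0, 0, 0]], np.ones(3, int), np.ones(3), np.eye(2))
        assert p[2] == 0.0

    def test_frobenius_hand_evaluation(self):
        A = np.full((3, 3), 0.25)
        p = update_p_frobenius(A, np.ones(3, dtype=int), np.ones(3), np.eye(2))
        assert p == pytest.approx([(0.5 / 2.0) ** 0.25] * 3)
        assert p[0] == pytest.approx(0.7071, abs=1e-4)

    def test_frobenius_fixed_point_at_exact_factorization(self, rng):
        f = rng.uniform(0.2, 0.9, 6)
        A = np.outer(f, f)
        p1 = update_p_frobenius(A, np.ones(6, dtype=int), f, np.eye(2))
        assert p1 == pytest.approx(f, rel=1e-12)

    @pytest.mark.parametrize("kind", ["poisson", "frobenius"])
    def test_single_step_monotonicity(self, kind, rng):
        update = update_p_poisson if kind == "poisson" else update_p_frobenius
        for _ in range(50):
            A, m = random_instance(rng, n=8, K=2, kind=kind)
            before = _eval(A, m.c, m.p, m.R, kind)
            p1 = update(A, m.c, m.p, m.R)
            after = _eval(A, m.c, p1, m.R, kind)
            if kind == "poisson":
                assert after >= before - 1e-12
            else:
                assert after <= before + 1e-12

    @pytest.mark.parametrize("kind", ["poisson", "frobenius"])
    def test_fixed_point_matches_coordinatewise_scan(self, kind, rng):
        """Iterating the MM map to convergence lands each propensity on the
        1-D optimum of the true objective in that coordinate."""
        update = update_p_poisson if kind == "poisson" else update_p_frobenius
        sign = -1.0 if kind == "poisson" else 1.0  # scan minimizes
        for _ in range(5):
            A, m = random_instance(rng, n=6, K=2, kind=kind)
            p = m.p.copy()
            for _ in range(5000):
                p1 = update(A, m.c, p, m.R)
                if np.max(np.abs(p1 - p)) < 1e-14:
                    break
                p = p1
            for i in range(3):
                def f(x, i=i):
                    q = p.copy()
                    q[i] = x
                    return sign * _eval(A, m.c, q, m.R, kind)

                res = minimize_scalar(f, bounds=(1e-6, 20.0), method="bounded",
                                      options={"xatol": 1e-10})
                assert res.x == pytest.approx(p[i], abs=1e-6)


class TestQuasiNewton:
    def test_linear_1d_reaches_fixed_point_in_one_step(self):
        # F(x) = 0.5 x + 1 from x0 = 0: u = 1, v = 0.5, proposal = 2 = x*
        buf = SecantBuffer(q=6)
        x = np.array([0.0])
        Fx = np.array([1.0])
        FFx = np.array([1.5])
        buf.push(Fx - x, FFx - Fx)
        prop = qn_accelerate(buf, x, Fx)
        assert prop == pytest.approx([2.0])

    def test_at_fixed_point_falls_back(self):
        buf = SecantBuffer(q=2)
        x = np.array([2.0])
        buf.push(np.zeros(1), np.zeros(1))
        assert qn_accelerate(buf, x, x) is None

    def test_empty_buffer_falls_back(self):
        assert qn_accelerate(SecantBuffer(q=3), np.ones(2), np.ones(2)) is None

    def test_linear_map_dim5_recovers_closed_form_fixed_point(self, rng):
        M = rng.uniform(-0.3, 0.3, (5, 5))
        b = rng.uniform(-1, 1, 5)
        F = lambda x: M @ x + b
        x_star = np.linalg.solve(np.eye(5) - M, b)
        buf = SecantBuffer(q=5)
        x = rng.uniform(-1, 1, 5)
        for _ in range(5):  # five fresh secants determine M exactly
            Fx = F(x)
            buf.push(Fx - x, F(Fx) - Fx)
            x = Fx
        prop = qn_accelerate(buf, x, F(x))
        assert prop == pytest.approx(x_star, abs=1e-8)

    def test_buffer_is_fifo_with_capacity_q(self):
        buf = SecantBuffer(q=2)
        for k in range(4):
            buf.push(np.array([float(k)]), np.array([0.1 * k]))
        assert len(buf) == 2
        assert buf.U.ravel() == pytest.approx([2.0, 3.0])


class TestFitParameters:
    def test_exactly_factorizable_recovery(self, rng):
        f = rng.uniform(0.2, 0.9, 10)
        A = np.outer(f, f)
        res = fit_parameters(
            A, np.ones(10, dtype=int),
            FitSettings(objective_kind="frobenius", tol=1e-13, inner_tol=1e-12),
        )
        assert res.converged
        assert res.model.objective_value < 1e-10
        assert np.max(np.abs(res.model.p - f) / f) < 1e-6

    def test_poisson_recovery_at_true_clustering(self, rng):
        from cpba.simulate import simulate_poisson_cpba

        c = np.repeat([1, 2], [40, 40])
        p_true = rng.uniform(2.0, 3.0, 80)
        R = np.array([[1, 0, 0], [0, 1, 0.15], [0, 0.15, 1.0]])
        A = simulate_poisson_cpba(c, p_true, R, rng_seed=3)
        res = fit_parameters(A, c, FitSettings(objective_kind="poisson"))
        rms = np.sqrt(np.mean((res.model.p - p_true) ** 2)) / np.sqrt(np.mean(p_true**2))
        assert rms < 0.10
        assert res.model.R[1, 2] == pytest.approx(0.15, rel=0.15)

    @pytest.mark.parametrize("kind", ["poisson", "frobenius"])
    def test_trace_is_monotone(self, kind, rng):
        A, m = random_instance(rng, n=12, K=3, kind=kind)
        res = fit_parameters(A, m.c, FitSettings(objective_kind=kind))
        diffs = np.diff(res.objective_trace)
        if kind == "poisson":
            assert np.all(diffs >= -1e-9)
        else:
            assert np.all(diffs <= 1e-9)

    @pytest.mark.parametrize("kind", ["poisson", "frobenius"])
    def test_acceleration_reaches_same_optimum(self, kind, rng):
        for _ in range(5):
            A, m = random_instance(rng, n=10, K=2, kind=kind)
            kw = dict(objective_kind=kind, tol=1e-10, inner_tol=1e-10)
            res_fast = fit_parameters(A, m.c, FitSettings(accelerate=True, **kw))
            res_slow = fit_parameters(A, m.c, FitSettings(accelerate=False, **kw))
            assert res_fast.model.objective_value == pytest.approx(
                res_slow.model.objective_value, abs=1e-6, rel=1e-9
            )

    def test_nonconvergence_is_reported_not_raised(self, rng):
        A, m = random_instance(rng, n=10, K=2, kind="poisson")
        res = fit_parameters(A, m.c, FitSettings(tol=1e-15, max_outer_iter=2, max_inner_iter=2, accelerate=False))
        assert res.converged is False
        assert len(res.objective_trace) >= 2


class TestInitPropensities:
    def test_counts_formula(self):
        p = init_propensities(COUNTS3)
        assert p == pytest.approx(np.array([2.0, 6.0, 4.0]) / np.sqrt(12.0))

    def test_single_pair_closed_form(self):
        m = 8.0
        A = np.array([[0.0, m], [m, 0.0]])
        assert init_propensities(A) == pytest.approx([np.sqrt(m / 2)] * 2)

    def test_near_factorizable_approximation(self):
        f = np.linspace(0.01, 0.05, 50)  # sum f >> sum f^2
        A = np.outer(f, f)
        np.fill_diagonal(A, 0.0)
        p = init_propensities(A, "frobenius")
        assert np.max(np.abs(p - f) / f) < 0.05

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning, match="no connections"):
            p = init_propensities(np.zeros((3, 3)))
        assert np.all(p == 0)
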