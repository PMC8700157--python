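"""Solvers: backtracked ISTA, self-concordant M-ISTA, bounds, ADMM reference."""

import numpy as np
import pytest

from proxjgl import (
    BoundsReport,
    CovarianceSet,
    PenaltySpec,
    PrecisionSet,
    admm_reference_solve,
    bb_initial_step,
    compute_bounds,
    default_theta0,
    fixed_point_residual,
    ista_solve,
    ista_step,
    mista_solve,
    neg_log_lik_f,
    objective_F,
    quadratic_model_Q,
    safe_step_size,
    stopping_relative_error,
    SolverConfig,
)
from conftest import random_cov_set, random_pd_stack


def scalar_cov(s=2.0, n=1.0):
    return CovarianceSet(np.array([[[s]]]), [n])


class TestQuadraticModel:
    def test_equal_points_give_f(self, pd_pair):
        theta, cov = pd_pair
        q = quadratic_model_Q(theta, theta, 0.5, cov)
        assert q == pytest.approx(neg_log_lik_f(theta, cov), rel=1e-12)

    def test_large_eta_drops_quadratic_term(self, pd_pair):
        theta, cov = pd_pair
        other = PrecisionSet(theta.matrices + 0.01 * np.eye(theta.p))
        q_inf = quadratic_model_Q(other, theta, 1e12, cov)
        from proxjgl import gradient_f

        diff = other.matrices - theta.matrices
        linear = neg_log_lik_f(theta, cov) + float(np.sum(diff * gradient_f(theta, cov)))
        assert q_inf == pytest.approx(linear, rel=1e-9)

    def test_matches_componentwise_evaluation(self, pd_pair, rng):
        theta, cov = pd_pair
        other = PrecisionSet(random_pd_stack(2, 5, rng))
        from proxjgl import gradient_f

        eta = 0.37
        g = gradient_f(theta, cov)
        expected = neg_log_lik_f(theta, cov)
        for k in range(2):
            d = other.matrices[k] - theta.matrices[k]
            expected += float(np.sum(d * g[k])) + float(np.sum(d * d)) / (2 * eta)
        assert quadratic_model_Q(other, theta, eta, cov) == pytest.approx(
            expected, rel=1e-12
        )


class TestIstaStep:
    def test_small_eta_accepted_without_backtracking(self, small_cov):
        pen = PenaltySpec("fused", 0.1, 0.1)
        theta = default_theta0(small_cov, pen)
        _, eta, bts, info = ista_step(
            theta, 1e-5, small_cov, pen, SolverConfig(), theta0=theta
        )
        assert bts == 0 and eta == 1e-5 and not info["safe_step"]

    def test_indefinite_prox_output_forces_backtracking(self):
        # huge step with no penalty: Theta - eta*grad is indefinite until
        # eta shrinks enough for Cholesky to succeed
        cov = scalar_cov(s=2.0, n=1.0)
        pen = PenaltySpec("fused", 0.0, 0.0)
        theta = PrecisionSet(np.array([[[1.0]]]))
        _, eta, bts, _ = ista_step(
            theta, 1e4, cov, pen, SolverConfig(c=0.5), theta0=theta
        )
        assert bts > 0 and eta < 1e4

    def test_scalar_gradient_step(self):
        # p=1: no off-diagonal, prox is the identity on the diagonal
        cov = scalar_cov(s=2.0)
        pen = PenaltySpec("fused", 5.0, 0.0)
        theta = PrecisionSet(np.array([[[1.0]]]))
        new, eta, _, _ = ista_step(theta, 0.01, cov, pen, SolverConfig(), theta0=theta)
        # gradient = s - 1/theta = 1, step moves toward theta* = 0.5
        assert new.matrices[0, 0, 0] == pytest.approx(1.0 - eta * 1.0)


class TestIstaSolve:
    def test_scalar_solution(self):
        theta, trace = ista_solve(scalar_cov(s=2.0), PenaltySpec("fused", 3.0, 0.0))
        assert trace.converged
        assert theta.matrices[0, 0, 0] == pytest.approx(0.5, rel=1e-4)

    def test_lambda2_zero_separates_into_single_class_solves(self, rng):
        cov = random_cov_set(2, 8, 40, rng)
        pen = PenaltySpec("fused", 3.0, 0.0)
        cfg = SolverConfig(tol=1e-6)
        joint, _ = ista_solve(cov, pen, cfg)
        for k in range(2):
            sub = CovarianceSet(cov.S[k][None], [cov.weights[k]])
            single, _ = ista_solve(sub, pen, cfg)
            assert (
                np.linalg.norm(joint.matrices[k] - single.matrices[0]) < 1e-4
            )

    def test_group_large_lambda1_gives_diagonal_mle(self, rng):
        cov = random_cov_set(2, 6, 30, rng)
        pen = PenaltySpec("group", 1e4, 1.0)
        theta, trace = ista_solve(cov, pen, SolverConfig(tol=1e-8))
        off = ~np.eye(6, dtype=bool)
        assert np.all(theta.matrices[:, off] == 0.0)
        np.testing.assert_allclose(
            np.stack([np.diag(theta.matrices[k]) for k in range(2)]),
            1.0 / cov.diag,
            atol=1e-6,
        )

    def test_monotone_descent_and_objective_error_rule(self, small_cov):
        pen = PenaltySpec("group", 1.0, 0.5)
        theta, trace = ista_solve(small_cov, pen, SolverConfig(tol=1e-6))
        obj = np.array(trace.objective)
        assert np.all(np.diff(obj) <= 1e-12)
        # objective-error rule stops within tol of the tight optimum
        cfg_obj = SolverConfig(tol=1e-4, stop_rule="objective_error")
        theta2, trace2 = ista_solve(small_cov, pen, cfg_obj)
        ref, _ = ista_solve(small_cov, pen, SolverConfig(tol=1e-10, max_iter=5000))
        gap = objective_F(theta2, small_cov, pen) - objective_F(ref, small_cov, pen)
        assert trace2.converged and gap <= 1e-4 + 1e-8

    def test_non_pd_start_rejected(self, small_cov):
        bad = PrecisionSet(np.tile(-np.eye(small_cov.p), (small_cov.K, 1, 1)))
        with pytest.raises(Exception):
            ista_solve(small_cov, PenaltySpec("fused", 0.1, 0.1), theta0=bad)


class TestMista:
    def test_agrees_with_ista(self, rng):
        cov = random_cov_set(2, 8, 50, rng)
        pen = PenaltySpec("fused", 2.0, 1.0)
        cfg = SolverConfig(tol=1e-8, max_iter=3000)
        ti, _ = ista_solve(cov, pen, cfg)
        tm, trace = mista_solve(cov, pen, cfg)
        assert np.linalg.norm((ti.matrices - tm.matrices).ravel()) < 1e-4
        alphas = np.array(trace.alpha)[:-1]  # last record may be the d=0 fixed point
        assert np.all((alphas > 0) & (alphas <= 1.0))
        al = np.array(trace.alpha_lam)
        assert np.nanmax(al) < 1.0

    def test_fixed_point_is_stationary(self, rng):
        cov = random_cov_set(1, 4, 30, rng)
        pen = PenaltySpec("fused", 1.0, 0.0)
        sol, _ = ista_solve(cov, pen, SolverConfig(tol=1e-10, max_iter=4000))
        _, trace = mista_solve(cov, pen, SolverConfig(tol=1e-8), theta0=sol)
        assert trace.iterations <= 3  # immediately recognises the solution

    def test_step_arithmetic(self):
        # beta = lambda = 1 -> alpha = 1/2
        beta = lam = 1.0
        assert beta / (lam * (lam + beta)) == 0.5

    def test_monotone_descent_group(self, rng):
        cov = random_cov_set(3, 6, 40, rng)
        _, trace = mista_solve(cov, PenaltySpec("group", 1.5, 0.8), SolverConfig(tol=1e-7))
        assert np.all(np.diff(np.array(trace.objective)) <= 1e-12)


class TestStepHelpers:
    def test_bb_identities(self, rng):
        d = rng.normal(size=(2, 3, 3))
        assert bb_initial_step(d, d, fallback=7.0) == pytest.approx(1.0)
        assert bb_initial_step(d, 2 * d, fallback=7.0) == pytest.approx(0.5)
        assert bb_initial_step(d, -d, fallback=7.0) == pytest.approx(7.0)

    def test_bb_clipping(self, rng):
        d = rng.normal(size=(1, 2, 2))
        assert bb_initial_step(d, 1e-12 * d, fallback=1.0, hi=1e8) == 1e8

    def test_relative_error_values(self):
        a = PrecisionSet(np.array([[[1.0, 0.2], [0.2, 2.0]]]))
        b = PrecisionSet(np.array([[[1.1, 0.2], [0.2, 1.8]]]))
        num = np.linalg.norm(b.matrices[0] - a.matrices[0])
        den = np.linalg.norm(a.matrices[0])
        assert stopping_relative_error(b, a) == pytest.approx(num / den)
        tiny = PrecisionSet(1e-8 * np.eye(2)[None])
        tiny2 = PrecisionSet(2e-8 * np.eye(2)[None])
        # denominator clamps at 1 for tiny iterates
        assert stopping_relative_error(tiny2, tiny) == pytest.approx(
            np.linalg.norm(tiny2.matrices[0] - tiny.matrices[0])
        )

    def test_residual_zero_at_scalar_solution(self):
        cov = scalar_cov(s=2.0)
        theta = PrecisionSet(np.array([[[0.5]]]))
        pen = PenaltySpec("fused", 0.7, 0.0)
        assert fixed_point_residual(theta, cov, pen, 0.1) < 1e-14
        bumped = PrecisionSet(np.array([[[0.6]]]))
        assert fixed_point_residual(bumped, cov, pen, 0.1) > 1e-3

    def test_residual_shrinks_along_iterations(self, rng):
        cov = random_cov_set(2, 5, 40, rng)
        _, trace = ista_solve(cov, PenaltySpec("fused", 1.0, 0.5), SolverConfig(tol=1e-8))
        res = np.array(trace.residual)
        assert res[-1] < res[0] / 100


class TestBounds:
    def test_k1_lambda2_zero_reduces(self, rng):
        cov = random_cov_set(1, 4, 30, rng)
        pen = PenaltySpec("fused", 0.5, 0.0)
        rep = compute_bounds(cov, pen)
        assert rep.lambda_c == pytest.approx(pen.lambda1**2)
        assert rep.available and 0 < rep.spectral_lower <= rep.spectral_upper

    def test_diagonal_covariance_hand_value(self):
        s = 2.0
        S = np.stack([s * np.eye(3)])
        cov = CovarianceSet(S, [10.0])
        pen = PenaltySpec("fused", 1.0, 0.0)
        rep = compute_bounds(cov, pen)
        # ||S||_2 = s; lower = n p/(lambda_c + n s); upper = N p/l1 + p/s
        assert rep.spectral_lower == pytest.approx(10 * 3 / (1.0 + 10 * s))
        assert rep.spectral_upper == pytest.approx(10 * 3 / 1.0 + 3 / s)

    def test_upper_bound_monotone_in_lambda1(self, small_cov):
        ups = [
            compute_bounds(small_cov, PenaltySpec("fused", l1, 0.3)).spectral_upper
            for l1 in (0.1, 0.5, 2.0)
        ]
        assert ups[0] >= ups[1] >= ups[2]

    def test_zero_diagonal_marks_unavailable(self):
        S = np.zeros((1, 2, 2))
        S[0, 0, 0] = 1.0  # second diagonal entry is zero
        cov = CovarianceSet(S, [5.0])
        rep = compute_bounds(cov, PenaltySpec("fused", 0.5, 0.0))
        assert not rep.available and np.isnan(rep.spectral_upper)
        with pytest.raises(ValueError, match="backtracking"):
            safe_step_size(rep)

    def test_safe_step_values(self):
        rep = BoundsReport(
            lambda_c=1.0, spectral_lower=0.1, spectral_upper=10.0, M=10.0, m=1.0,
            C1=1.0, n_l=1.0, n_m=2.0, a_l=1.0, b_m=10.0, eta_safe=0.5,
        )
        assert safe_step_size(rep) == pytest.approx(0.5)
        rep2 = BoundsReport(**{**rep.__dict__, "n_m": 4.0})
        assert safe_step_size(rep2) == pytest.approx(0.25)  # doubling n_m halves eta
        assert 0 < safe_step_size(rep) < 2 * rep.a_l**2 / rep.n_m
        assert rep.gamma(safe_step_size(rep)) < 1.0


class TestAdmmReference:
    def test_unpenalized_recovers_inverse_covariance(self, rng):
        S = random_pd_stack(2, 4, rng)
        cov = CovarianceSet(S, [20.0, 30.0])
        sol = admm_reference_solve(cov, PenaltySpec("fused", 0.0, 0.0),
                                   SolverConfig(tol=1e-9))
        for k in range(2):
            np.testing.assert_allclose(
                sol.matrices[k], np.linalg.inv(S[k]), atol=1e-5
            )

    def test_lambda2_zero_matches_per_class(self, rng):
        cov = random_cov_set(2, 6, 40, rng)
        pen = PenaltySpec("group", 2.0, 0.0)
        cfg = SolverConfig(tol=1e-9)
        joint = admm_reference_solve(cov, pen, cfg)
        for k in range(2):
            sub = CovarianceSet(cov.S[k][None], [cov.weights[k]])
            single = admm_reference_solve(sub, pen, cfg)
            assert np.linalg.norm(joint.matrices[k] - single.matrices[0]) < 1e-3

    def test_agrees_with_ista_on_fused_problem(self, rng):
        cov = random_cov_set(2, 10, 60, rng)
        pen = PenaltySpec("fused", 3.0, 1.0)
        a = admm_reference_solve(cov, pen, SolverConfig(tol=1e-9))
        i, _ = ista_solve(cov, pen, SolverConfig(tol=1e-9, max_iter=4000))
        assert np.linalg.norm((a.matrices - i.matrices).ravel()) < 1e-3
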