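"""Proximal-gradient solvers for the joint graphical lasso.

Two first-order methods share the proximal step
``prox_{eta g}(Theta - eta * grad f(Theta))``:

* ``ista_solve`` — ISTA with a backtracking line search: the step size is
  multiplied by ``c`` until the candidate is positive definite and satisfies
  the majorization condition ``f(Theta+) <= Q_eta(Theta+, Theta)``.

* ``mista_solve`` — modified ISTA: exploits self-concordance of f. From the
  proximal-gradient direction ``d_t`` it forms ``beta_t = ||d_t||_F^2/eta_t``
  and the local Hessian norm ``lambda_t = <grad^2 f(Theta_t) d_t, d_t>^{1/2}``
  and takes the damped step ``alpha_t = beta_t/(lambda_t(lambda_t+beta_t))``,
  which keeps every iterate positive definite without any Cholesky-driven
  line search.

Both use Barzilai–Borwein initialization of the step size, monotonically
decrease the objective, and stop on the relative-error or objective-error
criterion.  ``admm_reference_solve`` is a Danaher-style ADMM splitting kept
purely as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .model_core import (
    CovarianceSet,
    NotPositiveDefiniteError,
    PenaltySpec,
    PrecisionSet,
    gradient_f,
    neg_log_lik_f,
    objective_F,
    penalty_g,
    symmetrize,
)
from .prox_ops import prox_matrices

__all__ = [
    "SolverConfig",
    "SolverTrace",
    "BoundsReport",
    "default_theta0",
    "quadratic_model_Q",
    "ista_step",
    "ista_solve",
    "mista_solve",
    "bb_initial_step",
    "compute_bounds",
    "safe_step_size",
    "stopping_relative_error",
    "fixed_point_residual",
    "admm_reference_solve",
]

logger = logging.getLogger("proxjgl")


@dataclass
class SolverConfig:
    """Solver knobs.

    ``tol`` is the stopping tolerance epsilon; ``stop_rule`` selects the
    relative-error criterion (default) or the objective-error criterion
    (which first computes a reference optimum at ``tol/100``).  ``c`` is the
    backtracking shrink factor, ``eta0`` the initial step size.  The
    numerical defaults below are package choices (see docs/methods.md).
    """

    tol: float = 1e-5
    max_iter: int = 1000
    stop_rule: str = "relative_error"
    c: float = 0.5
    eta0: float = 1.0
    max_backtracks: int = 50
    halving_cap: int = 60
    bb_min: float = 1e-8
    bb_max: float = 1e8
    lambda_form: str = "hessian"  # or "printed": sum_k n_k ||Theta^-1 d||_F
    debug: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.c < 1.0):
            raise ValueError("backtracking constant c must be in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.stop_rule not in ("relative_error", "objective_error"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.lambda_form not in ("hessian", "printed"):
            raise ValueError(f"unknown lambda_form {self.lambda_form!r}")


@dataclass
class SolverTrace:
    """Per-iteration record supporting convergence-rate analysis."""

    objective: list = field(default_factory=list)
    eta: list = field(default_factory=list)
    alpha: list = field(default_factory=list)
    alpha_lam: list = field(default_factory=list)
    backtracks: list = field(default_factory=list)
    rel_error: list = field(default_factory=list)
    residual: list = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    safe_step_used: int = 0

    def record(self, F, eta, alpha, backtracks, rel_error, residual, alpha_lam=None):
        self.objective.append(float(F))
        self.eta.append(float(eta))
        self.alpha.append(float(alpha) if alpha is not None else np.nan)
        self.alpha_lam.append(float(alpha_lam) if alpha_lam is not None else np.nan)
        self.backtracks.append(int(backtracks))
        self.rel_error.append(float(rel_error))
        self.residual.append(float(residual))
        self.iterations = len(self.objective)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": np.arange(len(self.objective)),
                "objective": self.objective,
                "eta": self.eta,
                "alpha": self.alpha,
                "alpha_lam": self.alpha_lam,
                "backtracks": self.backtracks,
                "rel_error": self.rel_error,
                "residual": self.residual,
            }
        )


def default_theta0(cov: CovarianceSet, pen: PenaltySpec) -> PrecisionSet:
    """Diagonal start theta_{k,i,i} = 1/(s_{k,i,i} + lambda1): cheap, PD,
    scale-aware."""
    diag = 1.0 / (cov.diag + pen.lambda1)
    mats = np.zeros((cov.K, cov.p, cov.p))
    for k in range(cov.K):
        np.fill_diagonal(mats[k], diag[k])
    return PrecisionSet(mats)


def _f_from_chols(mats, chols, cov):
    total = 0.0
    for k in range(cov.K):
        logdet = 2.0 * np.sum(np.log(np.diag(chols[k])))
        tr = float(np.sum(cov.S[k] * mats[k]))
        total -= cov.weights[k] * (logdet - tr)
    return total


def _try_chols(mats):
    try:
        return [np.linalg.cholesky(m) for m in mats]
    except np.linalg.LinAlgError:
        return None


def quadratic_model_Q(
    theta_new: PrecisionSet,
    theta: PrecisionSet,
    eta: float,
    cov: CovarianceSet,
    grad: np.ndarray | None = None,
    f_theta: float | None = None,
) -> float:
    """Quadratic majorization model
    Q_eta(T', T) = f(T) + sum_k <T'(k)-T(k), grad f(T)(k)> + ||T'-T||_F^2/(2 eta).
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    if f_theta is None:
        f_theta = neg_log_lik_f(theta, cov)
    if grad is None:
        grad = gradient_f(theta, cov)
    diff = theta_new.matrices - theta.matrices
    return (
        f_theta
        + float(np.sum(diff * grad))
        + float(np.sum(diff * diff)) / (2.0 * eta)
    )


def stopping_relative_error(theta_new: PrecisionSet, theta_old: PrecisionSet) -> float:
    """sum_k ||T+(k)-T(k)||_F / max{sum_k ||T(k)||_F, 1}."""
    num = sum(
        np.linalg.norm(theta_new.matrices[k] - theta_old.matrices[k])
        for k in range(theta_old.K)
    )
    den = max(sum(np.linalg.norm(m) for m in theta_old.matrices), 1.0)
    return float(num / den)


def fixed_point_residual(
    theta: PrecisionSet, cov: CovarianceSet, pen: PenaltySpec, eta: float
) -> float:
    """||Theta - prox_{eta g}(Theta - eta grad f)||_F / (1 + ||Theta||_F).

    Zero exactly at a solution (for any eta > 0); an optimality diagnostic.
    """
    if eta <= 0:
        raise ValueError("eta must be positive")
    grad = gradient_f(theta, cov)
    prox = prox_matrices(theta.matrices - eta * grad, eta, pen)
    num = np.linalg.norm((theta.matrices - prox).ravel())
    return float(num / (1.0 + np.linalg.norm(theta.matrices.ravel())))


def bb_initial_step(
    delta_theta: np.ndarray,
    delta_grad: np.ndarray,
    fallback: float,
    lo: float = 1e-8,
    hi: float = 1e8,
) -> float:
    """Barzilai–Borwein spectral step <dT,dT>/<dT,dG> summed over classes,
    clipped to [lo, hi]; ``fallback`` when the curvature estimate is <= 0."""
    num = float(np.sum(delta_theta * delta_theta))
    den = float(np.sum(delta_theta * delta_grad))
    if den <= 0 or num == 0.0:
        return float(min(max(fallback, lo), hi))
    return float(min(max(num / den, lo), hi))


def _empirical_safe_step(theta: PrecisionSet, theta0: PrecisionSet, n_m: float) -> float:
    """Safe step a_l^2/n_m with a_l estimated from the smallest eigenvalue
    among the current iterate and the start (used when backtracking fails)."""
    a_l = np.inf
    for ps in (theta, theta0):
        for m in ps.matrices:
            a_l = min(a_l, float(np.linalg.eigvalsh(m)[0]))
    if not np.isfinite(a_l) or a_l <= 0:
        raise RuntimeError("cannot estimate a safe step: iterates not PD")
    return a_l * a_l / n_m


def ista_step(
    theta: PrecisionSet,
    eta: float,
    cov: CovarianceSet,
    pen: PenaltySpec,
    cfg: SolverConfig,
    grad: np.ndarray | None = None,
    f_theta: float | None = None,
    theta0: PrecisionSet | None = None,
):
    """One backtracked proximal step.

    Shrinks eta by cfg.c until the prox output is PD (Cholesky first — f needs
    logdet) and satisfies f(T+) <= Q_eta(T+, T).  Returns
    ``(theta_new, accepted_eta, n_backtracks, info)`` where ``info`` carries
    the new Cholesky factors, f value, direction and a safe-step flag.
    """
    if grad is None:
        grad = gradient_f(theta, cov)
    if f_theta is None:
        f_theta = neg_log_lik_f(theta, cov)
    mats = theta.matrices
    used_safe = False
    for bt in range(cfg.max_backtracks + 1):
        cand = prox_matrices(mats - eta * grad, eta, pen)
        chols = _try_chols(cand)
        if chols is not None:
            f_new = _f_from_chols(cand, chols, cov)
            diff = cand - mats
            q = f_theta + float(np.sum(diff * grad)) + float(np.sum(diff * diff)) / (
                2.0 * eta
            )
            if f_new <= q:
                break
        eta *= cfg.c
    else:
        # backtracking exhausted: fall back to the theoretically safe step
        used_safe = True
        eta = _empirical_safe_step(theta, theta0 if theta0 is not None else theta,
                                   float(np.max(cov.weights)))
        cand = prox_matrices(mats - eta * grad, eta, pen)
        chols = _try_chols(cand)
        if chols is None:
            raise NotPositiveDefiniteError(
                "safe-step fallback produced an indefinite iterate"
            )
        f_new = _f_from_chols(cand, chols, cov)
        bt = cfg.max_backtracks + 1
    theta_new = PrecisionSet(cand)
    info = {
        "chols": chols,
        "f": f_new,
        "direction": cand - mats,
        "safe_step": used_safe,
    }
    return theta_new, eta, bt, info


def ista_solve(
    cov: CovarianceSet,
    pen: PenaltySpec,
    cfg: SolverConfig | None = None,
    theta0: PrecisionSet | None = None,
):
    """ISTA with backtracking for the JGL problem.

    Returns ``(PrecisionSet, SolverTrace)``.  The objective is nonincreasing
    across accepted iterations; every stored iterate passes Cholesky.
    """
    cfg = cfg or SolverConfig()
    f_star = _reference_objective(cov, pen, cfg) if cfg.stop_rule == "objective_error" else None

    start = theta0.copy() if theta0 is not None else default_theta0(cov, pen)
    theta = start
    chols = theta.cholesky_all()
    f_cur = _f_from_chols(theta.matrices, chols, cov)
    trace = SolverTrace()
    eta = cfg.eta0
    prev_mats = prev_grad = None

    for t in range(cfg.max_iter):
        grad = gradient_f(theta, cov, chols=chols)
        if prev_mats is not None:
            eta = bb_initial_step(
                theta.matrices - prev_mats, grad - prev_grad, eta, cfg.bb_min, cfg.bb_max
            )
        theta_new, eta_acc, bts, info = ista_step(
            theta, eta, cov, pen, cfg, grad=grad, f_theta=f_cur, theta0=start
        )
        if info["safe_step"]:
            trace.safe_step_used += 1
        rel = stopping_relative_error(theta_new, theta)
        resid = float(
            np.linalg.norm(info["direction"].ravel())
            / (1.0 + np.linalg.norm(theta.matrices.ravel()))
        )
        F_new = info["f"] + penalty_g(theta_new, pen)
        trace.record(F_new, eta_acc, None, bts, rel, resid)
        logger.debug(
            "ISTA t=%d F=%.10g eta=%.3g backtracks=%d rel=%.3g", t, F_new, eta_acc, bts, rel
        )
        prev_mats, prev_grad = theta.matrices, grad
        theta, chols, f_cur = theta_new, info["chols"], info["f"]
        eta = eta_acc
        if cfg.stop_rule == "relative_error":
            if rel <= cfg.tol:
                trace.converged = True
                break
        else:
            if F_new - f_star <= cfg.tol:
                trace.converged = True
                break
    return theta, trace


def _lambda_t(mats, chols, d, weights, form: str) -> float:
    """Curvature of f along d.

    ``hessian`` (default): the exact local Hessian norm
    (sum_k n_k tr(T^-1 d T^-1 d))^{1/2}, computed via triangular solves.
    ``printed``: sum_k n_k ||T(k)^-1 d(k)||_F, the flattened variant.
    """
    if form == "hessian":
        total = 0.0
        for k in range(len(chols)):
            L = chols[k]
            x = solve_triangular(L, d[k], lower=True)
            m = solve_triangular(L, x.T, lower=True)
            total += weights[k] * float(np.sum(m * m))
        return float(np.sqrt(total))
    total = 0.0
    for k in range(len(chols)):
        L = chols[k]
        x = solve_triangular(L, d[k], lower=True)
        y = solve_triangular(L.T, x, lower=False)
        total += weights[k] * float(np.linalg.norm(y))
    return float(total)


def mista_solve(
    cov: CovarianceSet,
    pen: PenaltySpec,
    cfg: SolverConfig | None = None,
    theta0: PrecisionSet | None = None,
):
    """Modified ISTA: self-concordant step-size selection, no backtracking.

    Per iteration: direction d_t from the prox step, beta_t = ||d_t||_F^2/eta_t,
    lambda_t the Hessian norm of d_t, damped step
    alpha_t = beta_t/(lambda_t(lambda_t + beta_t)).  While alpha_t > 1 the
    step size is halved (up to ``cfg.halving_cap``); because alpha_t > 1
    implies lambda_t < 1, the step alpha_t = 1 is always admissible and is
    used when halving fails to bring alpha_t below 1 (see the methods note).
    alpha_t * lambda_t < 1 at every accepted step, which keeps the iterate in
    the PD cone without a line search; a Cholesky assertion runs in debug mode.
    """
    cfg = cfg or SolverConfig()
    f_star = _reference_objective(cov, pen, cfg) if cfg.stop_rule == "objective_error" else None

    theta = theta0.copy() if theta0 is not None else default_theta0(cov, pen)
    chols = theta.cholesky_all()
    f_cur = _f_from_chols(theta.matrices, chols, cov)
    trace = SolverTrace()
    eta = cfg.eta0
    prev_mats = prev_grad = None

    for t in range(cfg.max_iter):
        grad = gradient_f(theta, cov, chols=chols)
        if prev_mats is not None:
            eta = bb_initial_step(
                theta.matrices - prev_mats, grad - prev_grad, eta, cfg.bb_min, cfg.bb_max
            )

        halvings = 0
        alpha_prev = np.inf
        while True:
            d = prox_matrices(theta.matrices - eta * grad, eta, pen) - theta.matrices
            dnorm2 = float(np.sum(d * d))
            if dnorm2 == 0.0:
                alpha, beta, lam = 0.0, 0.0, 0.0
                break
            beta = dnorm2 / eta
            lam = _lambda_t(theta.matrices, chols, d, cov.weights, cfg.lambda_form)
            alpha = beta / (lam * (lam + beta)) if lam > 0 else 1.0
            if alpha <= 1.0:
                break
            if halvings >= cfg.halving_cap or alpha >= alpha_prev:
                # Halving is not reducing alpha (it cannot when lambda_t < 1
                # and d scales with eta); alpha = 1 is admissible here.
                alpha = 1.0
                break
            alpha_prev = alpha
            eta *= 0.5
            halvings += 1

        if dnorm2 == 0.0:
            rel = 0.0
            trace.record(f_cur + penalty_g(theta, pen), eta, 0.0, halvings, rel, 0.0)
            trace.converged = True
            break

        new_mats = symmetrize(theta.matrices + alpha * d)
        new_chols = _try_chols(new_mats)
        if new_chols is None:
            raise NotPositiveDefiniteError(
                "M-ISTA produced an indefinite iterate (numerical trouble)"
            )
        if cfg.debug:
            assert alpha * lam < 1.0 + 1e-12, "self-concordant PD condition violated"
        theta_new = PrecisionSet(new_mats)
        f_new = _f_from_chols(new_mats, new_chols, cov)
        rel = stopping_relative_error(theta_new, theta)
        resid = float(np.sqrt(dnorm2) / (1.0 + np.linalg.norm(theta.matrices.ravel())))
        F_new = f_new + penalty_g(theta_new, pen)
        trace.record(F_new, eta, alpha, halvings, rel, resid, alpha_lam=alpha * lam)
        logger.debug(
            "M-ISTA t=%d F=%.10g eta=%.3g alpha=%.3g lam=%.3g rel=%.3g",
            t, F_new, eta, alpha, lam, rel,
        )
        prev_mats, prev_grad = theta.matrices, grad
        theta, chols, f_cur = theta_new, new_chols, f_new
        if cfg.stop_rule == "relative_error":
            if rel <= cfg.tol:
                trace.converged = True
                break
        else:
            if F_new - f_star <= cfg.tol:
                trace.converged = True
                break
    return theta, trace


def _reference_objective(cov, pen, cfg) -> float:
    """F(Theta*) for the objective-error rule: a relative-error solve at
    tol/100 provides the reference optimum."""
    ref_cfg = SolverConfig(
        tol=cfg.tol / 100.0,
        max_iter=max(cfg.max_iter * 10, 2000),
        stop_rule="relative_error",
        c=cfg.c,
        eta0=cfg.eta0,
        max_backtracks=cfg.max_backtracks,
        lambda_form=cfg.lambda_form,
    )
    theta_ref, _ = ista_solve(cov, pen, ref_cfg)
    return objective_F(theta_ref, cov, pen)


# ---------------------------------------------------------------------------
# Boundedness diagnostics
# ---------------------------------------------------------------------------


@dataclass
class BoundsReport:
    """Solution/iterate bounds under the documented reading of the printed
    constants (typographically ambiguous in the source; diagnostics only)."""

    lambda_c: float
    spectral_lower: float
    spectral_upper: float
    M: float
    m: float
    C1: float
    n_l: float
    n_m: float
    a_l: float
    b_m: float
    eta_safe: float
    available: bool = True

    def gamma(self, eta: float) -> float:
        """Contraction factor max{eta*n_m/a_l^2 - 1, 1 - eta*n_l/b_m^2}."""
        return max(eta * self.n_m / self.a_l**2 - 1.0, 1.0 - eta * self.n_l / self.b_m**2)


def compute_bounds(
    cov: CovarianceSet,
    pen: PenaltySpec,
    theta0: PrecisionSet | None = None,
    F0: float | None = None,
) -> BoundsReport:
    """Evaluate the solution and iterate bounds as runtime diagnostics.

    Readings (see docs/methods.md): lambda_c = (sqrt(K) lambda1 + lambda2)^2;
    spectral upper bound N p / lambda1 + sum_k sum_i 1/s_{k,i,i};
    M = ||Theta0||_F + 2 N p/lambda1 + 2 sum 1/s; m = exp(-C1/n_m) M^(1-Kp).
    A zero covariance diagonal (or lambda1 = 0) makes the bounds unavailable.
    """
    K, p, N = cov.K, cov.p, cov.N
    if theta0 is None:
        theta0 = default_theta0(cov, pen)
    if F0 is None:
        F0 = objective_F(theta0, cov, pen)
    lam1, lam2 = pen.lambda1, pen.lambda2
    lambda_c = (np.sqrt(K) * lam1 + lam2) ** 2
    spec_norms = np.array([np.linalg.norm(cov.S[k], 2) for k in range(K)])
    lower = float(np.max(cov.weights * p / (lambda_c + cov.weights * spec_norms)))
    n_l = float(np.min(cov.weights))
    n_m = float(np.max(cov.weights))

    diag = cov.diag
    if np.any(diag <= 0) or lam1 <= 0:
        return BoundsReport(
            lambda_c=float(lambda_c), spectral_lower=lower, spectral_upper=np.nan,
            M=np.nan, m=np.nan, C1=float(F0), n_l=n_l, n_m=n_m,
            a_l=np.nan, b_m=np.nan, eta_safe=np.nan, available=False,
        )
    inv_diag_sum = float(np.sum(1.0 / diag))
    upper = N * p / lam1 + inv_diag_sum
    M = float(np.linalg.norm(theta0.matrices.ravel())) + 2.0 * N * p / lam1 + 2.0 * inv_diag_sum
    with np.errstate(over="ignore", under="ignore"):
        m = float(np.exp(-F0 / n_m) * M ** (1.0 - K * p))
    a_l, b_m = m, M
    eta_safe = a_l**2 / n_m if a_l > 0 else np.nan
    return BoundsReport(
        lambda_c=float(lambda_c), spectral_lower=lower, spectral_upper=float(upper),
        M=M, m=m, C1=float(F0), n_l=n_l, n_m=n_m, a_l=a_l, b_m=b_m,
        eta_safe=float(eta_safe), available=np.isfinite(eta_safe) and eta_safe > 0,
    )


def safe_step_size(report: BoundsReport) -> float:
    """eta = a_l^2/n_m, the midpoint of the admissible interval (0, 2 a_l^2/n_m)
    that guarantees a contraction (gamma_t < 1)."""
    if not report.available or not np.isfinite(report.a_l) or report.a_l <= 0:
        raise ValueError(
            "bounds unavailable: use the backtracking line search instead"
        )
    return report.a_l**2 / report.n_m


# ---------------------------------------------------------------------------
# ADMM reference solver (cross-check only)
# ---------------------------------------------------------------------------


def admm_reference_solve(
    cov: CovarianceSet,
    pen: PenaltySpec,
    cfg: SolverConfig | None = None,
    rho: float | None = None,
    max_iter: int = 20000,
) -> PrecisionSet:
    """Danaher-style ADMM splitting for the JGL; used as an oracle in tests.

    Theta-update: per-class eigendecomposition of rho(Z-U) - n_k S(k);
    Z-update: prox_{g/rho}(Theta + U); dual ascent on U.  Stops when scaled
    primal and dual residuals fall below cfg.tol.
    """
    cfg = cfg or SolverConfig()
    K, p = cov.K, cov.p
    rho = float(rho if rho is not None else cov.N)
    theta = default_theta0(cov, pen).matrices
    Z = theta.copy()
    U = np.zeros_like(theta)
    for it in range(max_iter):
        for k in range(K):
            C = symmetrize(rho * (Z[k] - U[k]) - cov.weights[k] * cov.S[k])
            w, V = np.linalg.eigh(C)
            wt = (w + np.sqrt(w**2 + 4.0 * rho * cov.weights[k])) / (2.0 * rho)
            theta[k] = symmetrize((V * wt) @ V.T)
        Z_new = prox_matrices(theta + U, 1.0 / rho, pen)
        dual = rho * np.linalg.norm((Z_new - Z).ravel())
        Z = Z_new
        U += theta - Z
        primal = np.linalg.norm((theta - Z).ravel())
        scale = max(1.0, np.linalg.norm(theta.ravel()), np.linalg.norm(Z.ravel()))
        if primal / scale < cfg.tol and dual / scale < rho * cfg.tol:
            break
    else:
        raise RuntimeError(f"ADMM reference did not converge in {max_iter} iterations")
    return PrecisionSet(Z)
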