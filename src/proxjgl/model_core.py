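"""Problem construction for the joint graphical lasso (JGL).

Multi-class Gaussian graphical models: for classes ``k = 1..K`` with ``n_k``
observations of ``p`` jointly Gaussian variables, the JGL estimates K sparse
precision matrices ``Theta(k)`` by minimising the composite objective

    F(Theta) = f(Theta) + g(Theta)

with the smooth (convex, self-concordant) negative log-likelihood

    f(Theta) = -sum_k n_k { logdet Theta(k) - trace(S(k) Theta(k)) }

and the nonsmooth penalty

    g(Theta) = lambda1 * sum_k sum_{i!=j} |theta_{k,i,j}| + P(Theta),

where ``P`` is either the fused penalty
``lambda2 * sum_{k<l} sum_{i,j} |theta_{k,i,j} - theta_{l,i,j}|``
(all entries, diagonal included) or the group penalty
``lambda2 * sum_{i!=j} sqrt(sum_k theta_{k,i,j}^2)`` (off-diagonal only).

A zero off-diagonal entry ``theta_{k,i,j}`` encodes conditional independence
of variables i and j in class k given the remaining variables.

Class weights are the raw sample counts ``n_k`` (not ``n_k/N``), matching the
objective exactly; graphical lasso is the K = 1 special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiClassDataset",
    "CovarianceSet",
    "PrecisionSet",
    "PenaltySpec",
    "NotPositiveDefiniteError",
    "compute_class_covariances",
    "neg_log_lik_f",
    "gradient_f",
    "penalty_g",
    "objective_F",
    "symmetrize",
]

_SYM_TOL = 1e-8


class NotPositiveDefiniteError(ValueError):
    """Raised when a precision matrix required to be PD fails Cholesky."""


def symmetrize(a: np.ndarray) -> np.ndarray:
    """Return (A + A^T)/2 applied to the trailing two axes.

    All theory assumes symmetric matrices; symmetrizing covariances, gradients
    and prox outputs suppresses floating-point drift.
    """
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def _check_symmetric(a: np.ndarray, what: str, tol: float = _SYM_TOL) -> None:
    dev = np.max(np.abs(a - np.swapaxes(a, -1, -2)), initial=0.0)
    scale = max(1.0, float(np.max(np.abs(a), initial=0.0)))
    if dev > tol * scale:
        raise ValueError(f"{what} is not symmetric (max deviation {dev:.3e})")


def _as_stack(matrices, what: str = "matrix set") -> np.ndarray:
    """Coerce a list of K p-by-p matrices (or a (K,p,p) array) to a stack."""
    arr = np.asarray(matrices, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError(f"{what} must be K square matrices, got shape {arr.shape}")
    return arr


@dataclass
class MultiClassDataset:
    """Per-class sample matrices: class k holds an (n_k, p) array of rows."""

    samples_per_class: list
    class_labels: list | None = None

    def __post_init__(self):
        mats = [np.atleast_2d(np.asarray(x, dtype=float)) for x in self.samples_per_class]
        if not mats:
            raise ValueError("need at least one class")
        p = mats[0].shape[1]
        for k, x in enumerate(mats):
            if x.shape[0] < 1:
                raise ValueError(f"class {k} has zero samples")
            if x.shape[1] != p:
                raise ValueError(
                    f"inconsistent feature count: class {k} has p={x.shape[1]}, expected {p}"
                )
        self.samples_per_class = mats
        if self.class_labels is None:
            self.class_labels = list(range(1, len(mats) + 1))
        elif len(self.class_labels) != len(mats):
            raise ValueError("class_labels length must match number of classes")

    @property
    def K(self) -> int:
        return len(self.samples_per_class)

    @property
    def p(self) -> int:
        return self.samples_per_class[0].shape[1]

    @property
    def n_k(self) -> np.ndarray:
        return np.array([x.shape[0] for x in self.samples_per_class])

    @property
    def N(self) -> int:
        return int(self.n_k.sum())


@dataclass
class CovarianceSet:
    """K empirical covariance matrices S(k) with their class sizes n_k."""

    S: np.ndarray
    weights: np.ndarray
    feature_names: list | None = None
    class_labels: list | None = None

    def __post_init__(self):
        self.S = _as_stack(self.S, "covariance set")
        _check_symmetric(self.S, "covariance set")
        self.S = symmetrize(self.S)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.S.shape[0],):
            raise ValueError("weights must give one n_k per class")
        if np.any(self.weights < 1):
            raise ValueError("every class needs n_k >= 1")
        if np.any(np.diagonal(self.S, axis1=1, axis2=2) < -_SYM_TOL):
            raise ValueError("covariance diagonals must be nonnegative")
        if self.class_labels is None:
            self.class_labels = list(range(1, self.K + 1))

    @property
    def K(self) -> int:
        return self.S.shape[0]

    @property
    def p(self) -> int:
        return self.S.shape[1]

    @property
    def N(self) -> float:
        return float(self.weights.sum())

    @property
    def diag(self) -> np.ndarray:
        """Per-class covariance diagonals s_{k,i,i}, shape (K, p)."""
        return np.diagonal(self.S, axis1=1, axis2=2)


@dataclass
class PrecisionSet:
    """The iterate/solution Theta = [Theta(1), ..., Theta(K)].

    Symmetry is enforced on construction; positive definiteness is an
    invariant of solver iterates and is checked where the contract needs it
    (``cholesky_all``), not in the constructor, so that prox outputs — which
    may be indefinite before the line search accepts them — can be held too.
    """

    matrices: np.ndarray

    def __post_init__(self):
        self.matrices = _as_stack(self.matrices, "precision set")
        _check_symmetric(self.matrices, "precision set")
        self.matrices = symmetrize(self.matrices)

    @property
    def K(self) -> int:
        return self.matrices.shape[0]

    @property
    def p(self) -> int:
        return self.matrices.shape[1]

    def copy(self) -> "PrecisionSet":
        return PrecisionSet(self.matrices.copy())

    def cholesky_all(self) -> list:
        """Lower Cholesky factor per class; raises if any block is not PD."""
        try:
            return [np.linalg.cholesky(m) for m in self.matrices]
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(
                "precision set is not positive definite"
            ) from exc

    def is_positive_definite(self) -> bool:
        try:
            self.cholesky_all()
            return True
        except NotPositiveDefiniteError:
            return False


@dataclass
class PenaltySpec:
    """Penalty family (fused | group) with lambda1, lambda2 >= 0."""

    family: str = "fused"
    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self):
        if self.family not in ("fused", "group"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty parameters must be nonnegative")

    def evaluate(self, theta: PrecisionSet) -> float:
        return penalty_g(theta, self)


def compute_class_covariances(
    dataset: MultiClassDataset, center: bool = True
) -> CovarianceSet:
    """Empirical covariances S(k) = (1/n_k) sum_{i: y_i = k} x_i^T x_i.

    The model assumes zero-mean Gaussians; ``center=True`` (default) removes
    per-class column means first, ``center=False`` applies the formula to the
    raw rows.
    """
    mats = []
    for x in dataset.samples_per_class:
        xc = x - x.mean(axis=0, keepdims=True) if center else x
        mats.append(symmetrize(xc.T @ xc / x.shape[0]))
    return CovarianceSet(np.stack(mats), dataset.n_k.astype(float))


def _chol_logdets(theta: PrecisionSet):
    """Cholesky factors and logdets for every class, shared by f and its uses."""
    chols = theta.cholesky_all()
    logdets = [2.0 * np.sum(np.log(np.diag(L))) for L in chols]
    return chols, logdets


def neg_log_lik_f(theta: PrecisionSet, cov: CovarianceSet) -> float:
    """Smooth term -sum_k n_k { logdet Theta(k) - trace(S(k) Theta(k)) }."""
    _, logdets = _chol_logdets(theta)
    total = 0.0
    for k in range(cov.K):
        tr = float(np.sum(cov.S[k] * theta.matrices[k]))
        total -= cov.weights[k] * (logdets[k] - tr)
    return total


def gradient_f(theta: PrecisionSet, cov: CovarianceSet, chols=None) -> np.ndarray:
    """Gradient blocks n_k (S(k) - Theta(k)^{-1}), shape (K, p, p), symmetric.

    Inverses come from Cholesky solves against the identity (pass ``chols`` to
    reuse factors already computed for the objective).
    """
    from scipy.linalg import cho_solve

    if chols is None:
        chols = theta.cholesky_all()
    eye = np.eye(theta.p)
    grads = np.empty_like(theta.matrices)
    for k in range(theta.K):
        inv = cho_solve((chols[k], True), eye)
        grads[k] = cov.weights[k] * (cov.S[k] - symmetrize(inv))
    return grads


def penalty_g(theta: PrecisionSet, pen: PenaltySpec) -> float:
    """Penalty g(Theta): off-diagonal l1 plus the fused or group coupling.

    The fused coupling sums |theta_{k,i,j} - theta_{l,i,j}| over ALL (i, j)
    (diagonal included, as defined); the l1 term and the group coupling are
    off-diagonal only.
    """
    th = theta.matrices
    K, p = theta.K, theta.p
    off = ~np.eye(p, dtype=bool)
    total = pen.lambda1 * float(np.abs(th[:, off]).sum())
    if pen.lambda2 > 0 and K > 1:
        if pen.family == "fused":
            for k in range(K):
                for l in range(k + 1, K):
                    total += pen.lambda2 * float(np.abs(th[k] - th[l]).sum())
        else:
            norms = np.sqrt((th**2).sum(axis=0))
            total += pen.lambda2 * float(norms[off].sum())
    return total


def objective_F(theta: PrecisionSet, cov: CovarianceSet, pen: PenaltySpec) -> float:
    """Full objective F = f + g, used by backtracking, descent checks, traces."""
    return neg_log_lik_f(theta, cov) + penalty_g(theta, pen)
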