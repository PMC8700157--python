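"""Synthetic multi-class problems and edge-recovery metrics.

The generator builds K sparse symmetric positive-definite ground-truth
precision matrices that share a common support (a random or chain base graph)
plus class-specific extra edges, then draws Gaussian samples from the implied
covariances Sigma(k) = Theta(k)^{-1}.

Construction per class: signed edge magnitudes uniform on +-[0.2, 0.8]
(shared edges reuse the same value across classes), positive definiteness by
diagonal dominance (diagonal = off-diagonal absolute row sum + 0.1 margin),
then a symmetric rescale D^{-1/2} Theta D^{-1/2} that sets the diagonal to 1
while preserving both definiteness and the support.

Metrics follow the edge-selection convention: an off-diagonal pair (i < j) in
class k is selected when |theta_hat| exceeds ``zero_tol`` (prox outputs are
exact zeros, so the tolerance only guards float dust).  TP/FP counts, ROC
sweeps over lambda1 and the off-diagonal MSE

    MSE = 2/(K p (p-1)) * sum_k sum_{i<j} (theta_hat - theta)^2

mirror the evaluation protocol for the method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    CovarianceSet,
    MultiClassDataset,
    PenaltySpec,
    PrecisionSet,
    compute_class_covariances,
    symmetrize,
)
from .solvers import SolverConfig, ista_solve, mista_solve

__all__ = [
    "GenParams",
    "SyntheticProblem",
    "EvalResult",
    "generate_problem",
    "count_tp_fp",
    "mse_offdiag",
    "roc_sweep",
    "normalized_auc",
]


@dataclass
class GenParams:
    """Knobs of the generator; defaults state the evaluation world.

    ``n_edges`` is the per-class support size (default p, i.e. average node
    degree 2); ``shared_fraction`` of it is common to all classes and the
    rest are class-specific extras.  Explicit ``n_shared_edges`` /
    ``n_extra_edges`` override the fraction.
    """

    p: int = 50
    K: int = 2
    n_per_class: int | list = 100
    shared_fraction: float = 0.8
    n_edges: int | None = None
    n_shared_edges: int | None = None
    n_extra_edges: int | None = None
    magnitude: tuple = (0.2, 0.8)
    base_graph: str = "erdos"  # or "chain"
    diag_margin: float = 0.1

    def __post_init__(self):
        if self.p < 2 or self.K < 1:
            raise ValueError("need p >= 2 and K >= 1")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.base_graph not in ("erdos", "chain"):
            raise ValueError(f"unknown base graph {self.base_graph!r}")
        n_k = self.n_per_class
        self.n_per_class = (
            [int(n_k)] * self.K if np.isscalar(n_k) else [int(v) for v in n_k]
        )
        if len(self.n_per_class) != self.K or min(self.n_per_class) < 1:
            raise ValueError("need n_k >= 1 for every class")
        total = self.n_edges if self.n_edges is not None else self.p
        if self.n_shared_edges is None:
            self.n_shared_edges = int(round(self.shared_fraction * total))
        if self.n_extra_edges is None:
            self.n_extra_edges = total - self.n_shared_edges
        max_pairs = self.p * (self.p - 1) // 2
        if self.n_shared_edges + self.n_extra_edges > max_pairs:
            raise ValueError(
                f"{self.n_shared_edges}+{self.n_extra_edges} edges infeasible for p={self.p}"
            )
        if self.n_shared_edges < 0 or self.n_extra_edges < 0:
            raise ValueError("edge counts must be nonnegative")


@dataclass
class SyntheticProblem:
    truth: PrecisionSet
    supports: np.ndarray  # (K, p, p) boolean off-diagonal adjacency
    dataset: MultiClassDataset
    gen_params: GenParams
    seed: int

    @property
    def covariances(self) -> CovarianceSet:
        return compute_class_covariances(self.dataset, center=False)


@dataclass
class EvalResult:
    TP: int
    FP: int
    total_selected: int
    mse: float
    lambda1: float = np.nan
    lambda2: float = np.nan
    roc_points: list = field(default_factory=list)


def _draw_pairs(rng, p, count, exclude=frozenset()):
    """Sample ``count`` distinct unordered pairs i<j avoiding ``exclude``."""
    pairs = set()
    while len(pairs) < count:
        i, j = rng.integers(0, p, size=2)
        if i == j:
            continue
        pair = (min(i, j), max(i, j))
        if pair not in exclude:
            pairs.add(pair)
    return sorted(pairs)


def generate_problem(gen_params: GenParams | None = None, seed: int = 0) -> SyntheticProblem:
    """Build ground-truth precision matrices and draw Gaussian samples.

    Fully reproducible from ``seed``; shared edges carry the same signed
    magnitude in every class.
    """
    gp = gen_params or GenParams()
    rng = np.random.default_rng(seed)
    p, K = gp.p, gp.K
    lo, hi = gp.magnitude

    if gp.base_graph == "chain":
        chain = [(i, i + 1) for i in range(p - 1)]
        if gp.n_shared_edges > len(chain):
            raise ValueError("chain base graph has only p-1 edges")
        idx = rng.choice(len(chain), size=gp.n_shared_edges, replace=False)
        shared = sorted(chain[i] for i in idx)
    else:
        shared = _draw_pairs(rng, p, gp.n_shared_edges)
    shared_vals = rng.uniform(lo, hi, size=len(shared)) * rng.choice([-1.0, 1.0], size=len(shared))

    mats = np.zeros((K, p, p))
    supports = np.zeros((K, p, p), dtype=bool)
    taken = frozenset(shared)
    for k in range(K):
        extra = _draw_pairs(rng, p, gp.n_extra_edges, exclude=taken)
        extra_vals = rng.uniform(lo, hi, size=len(extra)) * rng.choice(
            [-1.0, 1.0], size=len(extra)
        )
        B = np.zeros((p, p))
        for (i, j), v in zip(shared, shared_vals):
            B[i, j] = B[j, i] = v
        for (i, j), v in zip(extra, extra_vals):
            B[i, j] = B[j, i] = v
        d = np.abs(B).sum(axis=1) + gp.diag_margin
        np.fill_diagonal(B, d)
        scale = 1.0 / np.sqrt(d)
        theta = symmetrize(B * scale[:, None] * scale[None, :])
        mats[k] = theta
        supports[k] = theta != 0
        np.fill_diagonal(supports[k], False)

    truth = PrecisionSet(mats)
    samples = []
    for k in range(K):
        sigma = np.linalg.inv(mats[k])
        L = np.linalg.cholesky(symmetrize(sigma))
        z = rng.standard_normal((gp.n_per_class[k], p))
        samples.append(z @ L.T)
    dataset = MultiClassDataset(samples)
    return SyntheticProblem(truth, supports, dataset, gp, seed)


def count_tp_fp(
    theta_hat: PrecisionSet, truth: PrecisionSet, zero_tol: float = 1e-6
):
    """Selected-edge counts over off-diagonal unordered pairs i<j per class.

    TP: selected where the true entry is nonzero; FP: selected where it is
    zero.  Selection means |theta_hat| > zero_tol.
    """
    if theta_hat.matrices.shape != truth.matrices.shape:
        raise ValueError("estimate and truth shapes differ")
    p = truth.p
    iu = np.triu_indices(p, k=1)
    tp = fp = 0
    for k in range(truth.K):
        sel = np.abs(theta_hat.matrices[k][iu]) > zero_tol
        true_edge = truth.matrices[k][iu] != 0
        tp += int(np.sum(sel & true_edge))
        fp += int(np.sum(sel & ~true_edge))
    return tp, fp


def mse_offdiag(theta_hat: PrecisionSet, truth: PrecisionSet) -> float:
    """2/(K p (p-1)) * sum_k sum_{i<j} (theta_hat - theta)^2."""
    if theta_hat.matrices.shape != truth.matrices.shape:
        raise ValueError("estimate and truth shapes differ")
    K, p = truth.K, truth.p
    iu = np.triu_indices(p, k=1)
    total = sum(
        float(np.sum((theta_hat.matrices[k][iu] - truth.matrices[k][iu]) ** 2))
        for k in range(K)
    )
    return 2.0 * total / (K * p * (p - 1))


def roc_sweep(
    problem: SyntheticProblem,
    lambda1_grid,
    lambda2: float,
    pen_family: str = "fused",
    cfg: SolverConfig | None = None,
    solver: str = "ista",
    zero_tol: float = 1e-6,
) -> list:
    """One (FP, TP, MSE) point per lambda1 at fixed lambda2.

    The grid is swept from the sparsest (largest lambda1) down, warm-starting
    each fit from the previous solution.  Results are returned in the order
    of the given grid.
    """
    grid = list(lambda1_grid)
    if not grid:
        raise ValueError("empty lambda1 grid")
    cfg = cfg or SolverConfig()
    solve = {"ista": ista_solve, "mista": mista_solve}[solver]
    cov = problem.covariances
    order = np.argsort(grid)[::-1]
    results = [None] * len(grid)
    warm = None
    for idx in order:
        pen = PenaltySpec(pen_family, grid[idx], lambda2)
        theta_hat, _ = solve(cov, pen, cfg, theta0=warm)
        warm = theta_hat
        tp, fp = count_tp_fp(theta_hat, problem.truth, zero_tol)
        results[idx] = EvalResult(
            TP=tp,
            FP=fp,
            total_selected=tp + fp,
            mse=mse_offdiag(theta_hat, problem.truth),
            lambda1=grid[idx],
            lambda2=lambda2,
            roc_points=[(fp, tp)],
        )
    return results


def normalized_auc(results: list, truth: PrecisionSet) -> float:
    """Area under TP-rate vs FP-rate through the sweep points.

    Rates are normalized by the true edge/non-edge counts (summed over
    classes); the endpoints (0,0) and (1,1) are appended before the
    trapezoidal integral.
    """
    K, p = truth.K, truth.p
    iu = np.triu_indices(p, k=1)
    n_pos = sum(int(np.sum(truth.matrices[k][iu] != 0)) for k in range(K))
    n_neg = K * len(iu[0]) - n_pos
    fpr = np.array([r.FP / max(n_neg, 1) for r in results])
    tpr = np.array([r.TP / max(n_pos, 1) for r in results])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.argsort(fpr)
    return float(np.trapezoid(tpr[order], fpr[order]))
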