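"""V-fold cross-validation over a (lambda1, lambda2) grid.

The score is the predictive negative log-likelihood

    CV(l1, l2) = sum_v sum_k n_k { trace(S_v(k) Theta_hat(k)) - logdet Theta_hat(k) }

where S_v(k) is the test-fold covariance of class k and Theta_hat the fit on
the remaining V-1 folds.  Splitting is stratified within class so every class
is present in every training set (fold sizes within a class differ by at most
one); n_k in the score is the TEST-fold class count.  Non-converged fits score
+inf rather than aborting the grid.
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
)
from .solvers import SolverConfig, ista_solve, mista_solve

__all__ = ["CVResult", "cv_score", "cross_validate", "make_folds"]


@dataclass
class CVResult:
    grid: list
    scores: np.ndarray
    best_pair: tuple
    folds: int
    fold_assignments: list  # one integer array per class, fold id per sample
    seed: int
    converged: np.ndarray = field(default=None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "lambda1": [g[0] for g in self.grid],
                "lambda2": [g[1] for g in self.grid],
                "cv_score": self.scores,
                "converged": self.converged,
            }
        )


def cv_score(theta_hat: PrecisionSet, test_cov: CovarianceSet) -> float:
    """sum_k n_k { trace(S_v(k) Theta_hat(k)) - logdet Theta_hat(k) }."""
    chols = theta_hat.cholesky_all()
    total = 0.0
    for k in range(test_cov.K):
        logdet = 2.0 * np.sum(np.log(np.diag(chols[k])))
        tr = float(np.sum(test_cov.S[k] * theta_hat.matrices[k]))
        total += test_cov.weights[k] * (tr - logdet)
    return float(total)


def make_folds(dataset: MultiClassDataset, V: int, seed: int) -> list:
    """Seeded stratified fold ids: per class, a shuffled round-robin assignment.

    Within each class, fold sizes differ by at most one and every sample lands
    in exactly one test fold.
    """
    if V < 2:
        raise ValueError("V must be >= 2")
    rng = np.random.default_rng(seed)
    assignments = []
    for k, x in enumerate(dataset.samples_per_class):
        n = x.shape[0]
        if n < V:
            raise ValueError(f"class {k} has {n} samples, fewer than V={V} folds")
        ids = np.tile(np.arange(V), n // V + 1)[:n]
        rng.shuffle(ids)
        assignments.append(ids)
    return assignments


def cross_validate(
    dataset: MultiClassDataset,
    grid: list,
    V: int = 6,
    pen_family: str = "fused",
    cfg: SolverConfig | None = None,
    seed: int = 0,
    solver: str = "ista",
    center: bool = True,
) -> CVResult:
    """V-fold CV: fit every (lambda1, lambda2) pair on each training split,
    score on the held-out fold, sum over folds, return the argmin.

    Deterministic given ``seed``; V defaults to 6.  Within a fold the solver
    is warm-started from the previous grid point's solution.
    """
    if not grid:
        raise ValueError("empty grid")
    cfg = cfg or SolverConfig()
    solve = {"ista": ista_solve, "mista": mista_solve}[solver]
    assignments = make_folds(dataset, V, seed)
    scores = np.zeros(len(grid))
    converged = np.ones(len(grid), dtype=bool)

    for v in range(V):
        train = MultiClassDataset(
            [x[ids != v] for x, ids in zip(dataset.samples_per_class, assignments)],
            class_labels=list(dataset.class_labels),
        )
        test = MultiClassDataset(
            [x[ids == v] for x, ids in zip(dataset.samples_per_class, assignments)],
            class_labels=list(dataset.class_labels),
        )
        train_cov = compute_class_covariances(train, center=center)
        test_cov = compute_class_covariances(test, center=center)
        warm = None
        for g, (lam1, lam2) in enumerate(grid):
            pen = PenaltySpec(pen_family, lam1, lam2)
            theta_hat, trace = solve(train_cov, pen, cfg, theta0=warm)
            warm = theta_hat
            if trace.converged:
                scores[g] += cv_score(theta_hat, test_cov)
            else:
                scores[g] = np.inf
                converged[g] = False

    best = int(np.argmin(scores))
    return CVResult(
        grid=list(grid),
        scores=scores,
        best_pair=tuple(grid[best]),
        folds=V,
        fold_assignments=assignments,
        seed=seed,
        converged=converged,
    )
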