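"""Penalized parametric baselines: ridge regression and ridge-penalized
Poisson regression (log link), with cross-validated penalty selection.

Both losses penalize only the slope coefficients; the intercept is free.
Ridge solves the centered normal equations exactly; the Poisson fit uses
penalized iteratively reweighted least squares.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings

import numpy as np

from .metrics import mae

__all__ = [
    "Family",
    "PenalizedFit",
    "fit_ridge",
    "fit_poisson_ridge",
    "default_lambda_grid",
    "select_lambda",
]

_ETA_MAX = 30.0  # linear-predictor clip for the log link


class Family(enum.Enum):
    GAUSSIAN = "gaussian"
    POISSON = "poisson"


@dataclasses.dataclass(frozen=True)
class PenalizedFit:
    intercept: float
    coefficients: np.ndarray
    lam: float
    family: Family

    def predict(self, X) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coefficients
        if self.family is Family.POISSON:
            return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        return eta


def fit_ridge(X, y, lam: float) -> PenalizedFit:
    """Minimize ``sum (y - b0 - X b)^2 + lam * ||b||^2`` exactly.

    Centering removes the (unpenalized) intercept, leaving the ridge normal
    equations, which are well posed for ``lam > 0`` even when p > n.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    p = X.shape[1]
    gram = Xc.T @ Xc + lam * np.eye(p)
    if lam == 0.0 and np.linalg.matrix_rank(Xc) < p:
        raise ValueError("design is rank deficient at lambda=0; use lambda > 0")
    beta = np.linalg.solve(gram, Xc.T @ yc)
    return PenalizedFit(
        intercept=float(y_mean - x_mean @ beta),
        coefficients=beta,
        lam=lam,
        family=Family.GAUSSIAN,
    )


def fit_poisson_ridge(
    X, y, lam: float, tol: float = 1e-8, max_iter: int = 100
) -> PenalizedFit:
    """Minimize ``-sum(y_i log mu_i - mu_i) + lam * ||b||^2`` with log link.

    Penalized IRLS (Newton) with step halving; converges when the largest
    coefficient update falls below ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("Poisson responses must be nonnegative integers")
    n, p = X.shape
    ybar = y.mean()
    beta = np.zeros(p)
    b0 = np.log(ybar) if ybar > 0 else -_ETA_MAX

    def objective(b0_, beta_):
        eta = np.clip(b0_ + X @ beta_, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(y > 0, y * eta, 0.0) - mu
        return -ll.sum() + lam * beta_ @ beta_

    obj = objective(b0, beta)
    trace = [obj]
    for _ in range(max_iter):
        eta = np.clip(b0 + X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        grad = np.concatenate(([-(y - mu).sum()], -X.T @ (y - mu) + 2.0 * lam * beta))
        Xa = np.column_stack([np.ones(n), X])
        hess = (Xa * mu[:, None]).T @ Xa
        hess[1:, 1:] += 2.0 * lam * np.eye(p)
        hess[np.diag_indices_from(hess)] += 1e-12
        step = np.linalg.solve(hess, grad)
        scale = 1.0
        for _half in range(30):
            cand0 = b0 - scale * step[0]
            cand = beta - scale * step[1:]
            new_obj = objective(cand0, cand)
            if new_obj <= obj + 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = max(abs(scale * step[0]), np.max(np.abs(scale * step[1:])) if p else 0.0)
        b0, beta, obj = cand0, cand, new_obj
        trace.append(obj)
        if delta < tol:
            return PenalizedFit(float(b0), beta, lam, Family.POISSON)
    # a flat objective counts as converged; otherwise report the trace
    if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < 1e-10 * (1.0 + abs(trace[-1])):
        return PenalizedFit(float(b0), beta, lam, Family.POISSON)
    raise RuntimeError(f"Poisson ridge IRLS did not converge; objective trace: {trace}")


def default_lambda_grid(X, y, n_points: int = 100) -> np.ndarray:
    """Log-spaced grid over ``[1e-4 * lam_max, lam_max]``.

    ``lam_max = max_j |sum_i x_ij (y_i - ybar)| / n`` (same anchor for both
    families), descending so ties in CV break toward stronger shrinkage.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / y.size)
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-4, n_points)


def select_lambda(X, y, family: Family, k_folds: int, grid, seed: int) -> float:
    """Pick the grid value minimizing mean k-fold CV MAE; ties -> largest lambda."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = y.size
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(n) % k_folds)
    scores = np.zeros(grid.size)
    for fold in range(k_folds):
        test = assignment == fold
        train = ~test
        for gi, lam in enumerate(grid):
            if family is Family.GAUSSIAN:
                fit = fit_ridge(X[train], y[train], lam)
            else:
                fit = fit_poisson_ridge(X[train], y[train], lam)
            scores[gi] += mae(y[test], fit.predict(X[test]))
    scores /= k_folds
    best = np.min(scores)
    candidates = grid[scores <= best + 1e-12]
    return float(np.max(candidates))
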