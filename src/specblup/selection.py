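"""Penalized wavelength selection: Lasso / elastic net with recovery rates.

Cyclic coordinate descent on the elastic-net objective

    (1/2n) ||y - X b||^2 + lambda * (alpha ||b||_1 + (1-alpha)/2 ||b||^2),

with lambda tuned by k-fold cross-validation over a descending
log-spaced path from lambda_max (the smallest lambda with an all-zero
Lasso solution) and, for the elastic net, alpha tuned by an outer CV
over a user grid.  Bands are aggregated over repeated training
resamples: a band counts as selected when its recovery rate (fraction
of fits with a nonzero coefficient) strictly exceeds the threshold
(default 40%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "PenalizedFit",
    "SelectionResult",
    "fit_penalized",
    "lambda_path",
    "cv_select_lambda",
    "cv_select_alpha",
    "recovery_selection",
    "run_band_selection",
]


@dataclass
class PenalizedFit:
    beta: np.ndarray
    intercept: float
    lam: float
    alpha: float
    n_iter: int
    objective: float
    converged: bool

    @property
    def active_set(self) -> np.ndarray:
        return np.nonzero(self.beta)[0]


def _objective(X, y, beta, intercept, lam, alpha):
    n = len(y)
    r = y - intercept - X @ beta
    return (0.5 / n * r @ r
            + lam * (alpha * np.abs(beta).sum()
                     + 0.5 * (1 - alpha) * beta @ beta))


@njit(cache=True)
def _cd_solve(X, yc, beta, r, colsq, lam, alpha, tol, max_iter):
    """Active-set cyclic coordinate descent (compiled inner loop)."""
    n, b = X.shape
    thresh = lam * alpha
    it = 0
    while it < max_iter:
        it += 1
        # full sweep refreshes the active set and checks optimality
        max_change = 0.0
        for j in range(b):
            bj = beta[j]
            rho = np.dot(X[:, j], r) / n + colsq[j] * bj
            den = colsq[j] + lam * (1.0 - alpha)
            new = 0.0
            if den > 0.0:
                if rho > thresh:
                    new = (rho - thresh) / den
                elif rho < -thresh:
                    new = (rho + thresh) / den
            if new != bj:
                diff = bj - new
                for i in range(n):
                    r[i] += X[i, j] * diff
                beta[j] = new
                if abs(diff) > max_change:
                    max_change = abs(diff)
        if max_change < tol:
            return it, True
        # inner sweeps over the nonzero coordinates only
        while it < max_iter:
            it += 1
            max_change = 0.0
            for j in range(b):
                bj = beta[j]
                if bj == 0.0:
                    continue
                rho = np.dot(X[:, j], r) / n + colsq[j] * bj
                den = colsq[j] + lam * (1.0 - alpha)
                new = 0.0
                if den > 0.0:
                    if rho > thresh:
                        new = (rho - thresh) / den
                    elif rho < -thresh:
                        new = (rho + thresh) / den
                if new != bj:
                    diff = bj - new
                    for i in range(n):
                        r[i] += X[i, j] * diff
                    beta[j] = new
                    if abs(diff) > max_change:
                        max_change = abs(diff)
            if max_change < tol:
                break
    return it, False


def fit_penalized(X: np.ndarray, y: np.ndarray, lam: float, alpha: float = 1.0,
                  tol: float = 1e-7, max_iter: int = 10_000,
                  beta0: np.ndarray | None = None) -> PenalizedFit:
    """Elastic-net fit by cyclic coordinate descent.

    ``X`` columns should be standardized and ``y`` is centred
    internally (intercept unpenalized).  ``alpha`` = 1 is the Lasso,
    0 is ridge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y)):
        raise ValueError("X and y must be finite")
    if lam < 0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("require lambda >= 0 and alpha in [0, 1]")
    n, b = X.shape
    intercept = float(y.mean())
    yc = y - intercept
    beta = np.zeros(b) if beta0 is None else beta0.copy()
    colsq = (X ** 2).sum(axis=0) / n
    r = yc - X @ beta
    it, converged = _cd_solve(np.asfortranarray(X), yc, beta, r,
                              colsq, float(lam), float(alpha),
                              float(tol), max_iter)
    return PenalizedFit(
        beta=beta, intercept=intercept, lam=lam, alpha=alpha, n_iter=it,
        objective=_objective(X, y, beta, intercept, lam, alpha),
        converged=converged,
    )


def lambda_path(X: np.ndarray, y: np.ndarray, alpha: float,
                n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced path from the all-zero point lambda_max."""
    n = len(y)
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / (n * max(alpha, 1e-3))
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _folds(n: int, k: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    return np.array_split(idx, k)


def cv_select_lambda(X: np.ndarray, y: np.ndarray, alpha: float = 1.0,
                     k: int = 10, seed: int = 0,
                     n_lambda: int = 100, ratio: float = 1e-3):
    """k-fold CV over the lambda path; returns (lambda_opt, path, mse)."""
    n = len(y)
    if k > n:
        raise ValueError("more folds than observations")
    path = lambda_path(X, y, alpha, n_lambda, ratio)
    rng = np.random.default_rng(seed)
    folds = _folds(n, k, rng)
    mse = np.zeros((k, len(path)))
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        Xt, yt = X[train], y[train]
        beta = np.zeros(X.shape[1])
        for i, lam in enumerate(path):          # warm starts down the path
            fit = fit_penalized(Xt, yt, lam, alpha, beta0=beta)
            beta = fit.beta
            pred = fit.intercept + X[test] @ beta
            mse[f, i] = np.mean((y[test] - pred) ** 2)
    mean_mse = mse.mean(axis=0)
    lam_opt = float(path[int(np.argmin(mean_mse))])
    return lam_opt, path, mean_mse


def cv_select_alpha(X: np.ndarray, y: np.ndarray,
                    alpha_grid=(0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
                    k: int = 10, seed: int = 0,
                    n_lambda: int = 100, ratio: float = 1e-3):
    """Pick alpha minimizing the minimum CV MSE; ties go to the larger
    (sparser) alpha.  Returns (alpha_opt, lambda_opt_at_alpha)."""
    grid = list(alpha_grid)
    if not grid:
        raise ValueError("empty alpha grid")
    best = None
    for a in sorted(grid):
        lam_opt, _, mean_mse = cv_select_lambda(X, y, a, k=k, seed=seed,
                                                n_lambda=n_lambda, ratio=ratio)
        score = float(mean_mse.min())
        if best is None or score <= best[0]:    # <=: ties -> larger alpha
            best = (score, a, lam_opt)
    return best[1], best[2]


@dataclass
class SelectionResult:
    band_names: list[str]
    recovery_rate: np.ndarray
    threshold: float
    active_sets: list[np.ndarray] = field(repr=False)

    @property
    def selected(self) -> list[str]:
        return [b for b, r in zip(self.band_names, self.recovery_rate)
                if r > self.threshold]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "band": self.band_names,
            "recovery_rate": self.recovery_rate,
            "selected": self.recovery_rate > self.threshold,
        })


def recovery_selection(active_sets: list, n_bands: int,
                       band_names: list[str] | None = None,
                       threshold: float = 0.40) -> SelectionResult:
    """Aggregate active sets of repeated fits into per-band recovery
    rates; a band is selected iff its rate strictly exceeds ``threshold``."""
    if len(active_sets) < 2:
        raise ValueError("need >= 2 selection runs")
    counts = np.zeros(n_bands)
    sets = []
    for s in active_sets:
        s = np.asarray(s, dtype=int)
        counts[s] += 1
        sets.append(s)
    rates = counts / len(active_sets)
    names = band_names if band_names is not None else [str(i) for i in range(n_bands)]
    return SelectionResult(band_names=list(names), recovery_rate=rates,
                           threshold=threshold, active_sets=sets)


def run_band_selection(X: np.ndarray, y: np.ndarray,
                       band_names: list[str], method: str = "lasso",
                       n_runs: int = 100, train_frac: float = 0.8,
                       threshold: float = 0.40, k: int = 10,
                       seed: int = 0) -> SelectionResult:
    """Repeated-resample band selection (one penalized fit per training
    resample), mirroring the per-CV-iteration fits of the S1 scheme."""
    rng = np.random.default_rng(seed)
    n = len(y)
    if method == "lasso":
        alpha = 1.0
    elif method in ("en", "elastic-net"):
        alpha, _ = cv_select_alpha(X, y, k=k, seed=seed)
    else:
        raise ValueError("method must be 'lasso' or 'en'")
    active = []
    for _ in range(n_runs):
        train = rng.choice(n, size=int(round(train_frac * n)), replace=False)
        lam_opt, _, _ = cv_select_lambda(
            X[train], y[train], alpha, k=min(k, len(train)),
            seed=int(rng.integers(2 ** 31)), n_lambda=60,
        )
        fit = fit_penalized(X[train], y[train], lam_opt, alpha)
        active.append(fit.active_set)
    return recovery_selection(active, X.shape[1], band_names, threshold)
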