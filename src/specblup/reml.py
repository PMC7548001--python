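"""Dense average-information REML for linear covariance structures.

The engine estimates variance parameters of models

    y = X beta + sum_k u_k,      V = Var(y) = sum_k theta_k * V_k,

where each ``V_k`` is a known symmetric matrix contributed by a random
term: a grouped factor (``V_k = Z Z'``), a diagonal weight structure
(``V_k = diag(d)``), a kernel term (``V_k = Z K Z'``) or an arbitrary
dense symmetric matrix.  Covariance parameters (e.g. the off-diagonal of
an unstructured 2x2 trait covariance) are supported as unbounded
components; variances are constrained non-negative.

Updates are Newton steps on the REML log-likelihood using the average
information matrix, with step halving and an EM-flavoured fallback when
the AI step is not an ascent direction.  Components are floored at
``floor_frac * var(y)``; a component held at the floor with a negative
gradient is treated as bound-constrained and excluded from the step.

This is a dense implementation: all matrices are materialised at the
size of the observation vector.  It is intended for the data volumes of
plot-level field trials and genotype-level prediction models (up to a
few thousand observations), not for large animal-breeding evaluations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "RandomTerm",
    "factor_term",
    "diag_term",
    "kernel_term",
    "dense_term",
    "REMLResult",
    "ai_reml",
    "SingularFixedEffectsError",
]


class SingularFixedEffectsError(ValueError):
    """Raised when the fixed-effects design matrix is rank deficient."""


@dataclass
class RandomTerm:
    """One component of the covariance structure ``V = sum theta_k V_k``."""

    name: str
    Z: sp.csr_matrix | None = None       # n x L incidence (factor / kernel)
    K: np.ndarray | None = None          # L x L kernel for kernel terms
    D: np.ndarray | None = None          # length-n diagonal for diag terms
    A: np.ndarray | None = None          # dense n x n for free-form terms
    bounded: bool = True                 # variance (>=0) vs covariance (free)
    _ZZt: sp.csr_matrix | None = field(default=None, repr=False)
    _dense: np.ndarray | None = field(default=None, repr=False)
    _coo: tuple | None = field(default=None, repr=False)

    @property
    def n_levels(self) -> int:
        if self.Z is not None:
            return self.Z.shape[1]
        if self.D is not None:
            return int(np.count_nonzero(self.D))
        return self.A.shape[0]

    def materialize(self) -> None:
        """Cache what repeated iterations need."""
        if self.Z is not None and self.K is None and self._ZZt is None:
            self._ZZt = (self.Z @ self.Z.T).tocsr()
            coo = self._ZZt.tocoo()
            self._coo = (coo.row, coo.col, coo.data)
        if self.Z is not None and self.K is not None and self._dense is None:
            ZK = self.Z @ self.K                       # n x L dense
            self._dense = np.asarray(ZK @ self.Z.T.toarray() if sp.issparse(self.Z)
                                     else ZK @ self.Z.T)
        if self.A is not None and self._dense is None:
            self._dense = self.A

    def add_to(self, V: np.ndarray, theta: float) -> None:
        if self.D is not None:
            V[np.diag_indices_from(V)] += theta * self.D
        elif self._dense is not None:
            V += theta * self._dense
        else:
            # csr products have unique (row, col) pairs, so fancy += is safe
            row, col, data = self._coo
            V[row, col] += theta * data

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """``V_k @ x``."""
        if self.D is not None:
            return self.D * x
        if self._dense is not None:
            return self._dense @ x
        return self._ZZt @ x

    def trace_with(self, P: np.ndarray) -> float:
        """``tr(P V_k)`` for symmetric ``P``."""
        if self.D is not None:
            return float(np.dot(np.diagonal(P), self.D))
        if self._dense is not None:
            return float(np.sum(P * self._dense))
        row, col, data = self._coo
        return float(np.dot(P[row, col], data))


def factor_term(name: str, codes: np.ndarray, bounded: bool = True) -> RandomTerm:
    """Random term for a grouping factor given integer level codes.

    Rows with a negative code receive a zero incidence row; this is how
    per-group (heterogeneous) variance components restrict a term to one
    group of observations.
    """
    codes = np.asarray(codes)
    n = codes.size
    mask = codes >= 0
    if mask.sum() == 0:
        raise ValueError(f"term {name!r}: no observations")
    levels = np.unique(codes[mask])
    remap = {lv: i for i, lv in enumerate(levels)}
    rows = np.nonzero(mask)[0]
    cols = np.array([remap[c] for c in codes[mask]])
    Z = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, len(levels))
    )
    return RandomTerm(name=name, Z=Z, bounded=bounded)


def diag_term(name: str, d: np.ndarray, bounded: bool = True) -> RandomTerm:
    return RandomTerm(name=name, D=np.asarray(d, dtype=float), bounded=bounded)


def kernel_term(
    name: str, codes: np.ndarray, K: np.ndarray, bounded: bool = True
) -> RandomTerm:
    """Random term ``u ~ N(0, theta*K)`` mapped to observations by ``codes``."""
    codes = np.asarray(codes)
    n = codes.size
    mask = codes >= 0
    rows = np.nonzero(mask)[0]
    cols = codes[mask]
    Z = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, K.shape[0]))
    return RandomTerm(name=name, Z=Z, K=np.asarray(K, dtype=float), bounded=bounded)


def dense_term(name: str, A: np.ndarray, bounded: bool = True) -> RandomTerm:
    return RandomTerm(name=name, A=np.asarray(A, dtype=float), bounded=bounded)


@dataclass
class REMLResult:
    """Converged (or flagged) REML fit."""

    theta: dict[str, float]
    beta: np.ndarray
    beta_cov: np.ndarray            # (X' V^-1 X)^-1
    loglik: float
    converged: bool
    n_iter: int
    resid: np.ndarray               # y - X beta
    Vinv: np.ndarray
    Py: np.ndarray
    term_names: list[str]

    def varcomp(self, name: str) -> float:
        return self.theta[name]


def _check_design(X: np.ndarray, names: Sequence[str] | None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR
        _, _, piv = la.qr(X, mode="economic", pivoting=True)
        aliased = piv[rank:]
        labels = (
            [names[j] for j in aliased] if names is not None else list(aliased)
        )
        raise SingularFixedEffectsError(
            f"fixed-effects design is singular; aliased columns: {labels}"
        )


def _loglik(V: np.ndarray, X: np.ndarray, y: np.ndarray):
    """REML log-likelihood and the by-products each iteration reuses."""
    c, low = la.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * float(np.sum(np.log(np.diagonal(c))))
    Vinv = la.cho_solve((c, low), np.eye(V.shape[0]), check_finite=False)
    ViX = Vinv @ X
    XtViX = X.T @ ViX
    cx, lowx = la.cho_factor(XtViX, lower=True, check_finite=False)
    logdet_X = 2.0 * float(np.sum(np.log(np.diagonal(cx))))
    beta_cov = la.cho_solve((cx, lowx), np.eye(X.shape[1]), check_finite=False)
    Viy = Vinv @ y
    XtViy = X.T @ Viy
    beta = beta_cov @ XtViy
    Py = Viy - ViX @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (logdet_V + logdet_X + yPy)
    P = Vinv - ViX @ beta_cov @ ViX.T
    return ll, P, Py, beta, beta_cov, Vinv


def _project_psd_groups(theta, psd_groups, eps=1e-8):
    """Shrink covariance entries so each 2x2 block stays PSD."""
    for (i11, i12, i22) in psd_groups:
        v1, c, v2 = theta[i11], theta[i12], theta[i22]
        bound = np.sqrt(max(v1, 0.0) * max(v2, 0.0))
        lim = (1.0 - eps) * bound
        if abs(c) > lim:
            theta[i12] = np.sign(c) * lim


def ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: Sequence[RandomTerm],
    *,
    init: np.ndarray | None = None,
    max_iter: int = 80,
    tol: float = 1e-10,
    floor_frac: float = 1e-10,
    psd_groups: Sequence[tuple[int, int, int]] = (),
    fixed_names: Sequence[str] | None = None,
) -> REMLResult:
    """Estimate ``theta`` by average-information REML.

    Parameters
    ----------
    y, X
        Response vector and full-rank fixed-effects design.
    terms
        Covariance components; ``V = sum theta_k V_k``.
    psd_groups
        Index triples ``(i_var1, i_cov, i_var2)`` of 2x2 covariance
        blocks kept positive semi-definite by shrinking the covariance.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if n - X.shape[1] < 1:
        raise ValueError("no residual degrees of freedom")
    _check_design(X, fixed_names)

    terms = list(terms)
    for t in terms:
        t.materialize()
    m = len(terms)
    vary = float(np.var(y)) or 1.0
    floor = floor_frac * vary

    theta = np.empty(m)
    if init is not None:
        theta[:] = init
    else:
        n_bounded = sum(t.bounded for t in terms) or 1
        for k, t in enumerate(terms):
            theta[k] = vary / n_bounded if t.bounded else 0.0
    theta[[t.bounded for t in terms]] = np.maximum(
        theta[[t.bounded for t in terms]], floor
    )
    _project_psd_groups(theta, psd_groups)

    def build_V(th):
        V = np.zeros((n, n))
        for k, t in enumerate(terms):
            if th[k] != 0.0:
                t.add_to(V, th[k])
        # numerical jitter keeps V PD when everything is floored
        V[np.diag_indices_from(V)] += 1e-12 * vary + 0.0
        return V

    # variance cap: a weakly identified component (e.g. two levels of a
    # date effect) can crawl toward +inf while the likelihood approaches
    # a finite asymptote; beyond the cap the term is effectively fixed
    cap = 1e6 * vary

    ll, P, Py, beta, beta_cov, Vinv = _loglik(build_V(theta), X, y)
    converged = False
    it = 0
    n_stagnant = 0
    for it in range(1, max_iter + 1):
        # score vector and AI matrix
        W = np.empty((n, m))
        traces = np.empty(m)
        for k, t in enumerate(terms):
            W[:, k] = t.matvec(Py)
            traces[k] = t.trace_with(P)
        score = 0.5 * (W.T @ Py - traces)
        PW = P @ W
        AI = 0.5 * (W.T @ PW)

        # active bound constraints: floored variances pushing further down,
        # capped variances pushing further up
        active = np.array(
            [t.bounded and ((theta[k] <= floor * 1.001 and score[k] < 0.0)
                            or (theta[k] >= cap * 0.999 and score[k] > 0.0))
             for k, t in enumerate(terms)]
        )
        free = ~active
        delta = np.zeros(m)
        if free.any():
            AIf = AI[np.ix_(free, free)]
            try:
                delta[free] = la.solve(
                    AIf + 1e-10 * np.eye(free.sum()) * np.trace(AIf),
                    score[free], assume_a="pos",
                )
            except la.LinAlgError:
                delta[free] = score[free] / np.maximum(np.diagonal(AIf), 1e-12)

        # Newton decrement: expected gain of the full AI step; when it is
        # negligible the maximum is reached even if parameters still drift
        if free.any() and float(score[free] @ delta[free]) < 1e-4 * tol * (1.0 + abs(ll)):
            converged = True
            break

        def try_step(step):
            cand = theta + step * delta
            for k, t in enumerate(terms):
                if t.bounded:
                    cand[k] = min(max(cand[k], floor), cap)
            _project_psd_groups(cand, psd_groups)
            try:
                return cand, _loglik(build_V(cand), X, y)
            except la.LinAlgError:
                return cand, None

        improved = False
        step = 1.0
        for _ in range(12):
            cand, out = try_step(step)
            if out is not None and out[0] >= ll - 1e-10:
                improved = True
                break
            step *= 0.5
        if improved and step == 1.0 and it > 10:
            # slow crawl toward a flat asymptote (e.g. a two-level variance
            # drifting upward): expand the step while it keeps helping
            while step < 300.0:
                cand2, out2 = try_step(step * 3.0)
                if out2 is None or out2[0] < out[0]:
                    break
                cand, out, step = cand2, out2, step * 3.0
        if improved:
            ll_new, P_new, Py_new, beta_new, bcov_new, Vinv_new = out

        if not improved:
            # EM-flavoured fallback: guaranteed-ascent direction for
            # bounded terms, damped gradient for covariances
            cand = theta.copy()
            for k, t in enumerate(terms):
                q = t.n_levels
                if t.bounded:
                    upd = theta[k] + theta[k] ** 2 * (2.0 * score[k]) / max(q, 1)
                    cand[k] = min(max(upd, floor), cap)
                else:
                    cand[k] = theta[k] + score[k] * theta_scale(theta, k, terms)
            _project_psd_groups(cand, psd_groups)
            try:
                ll_new, P_new, Py_new, beta_new, bcov_new, Vinv_new = _loglik(
                    build_V(cand), X, y
                )
                improved = ll_new >= ll - 1e-8
            except la.LinAlgError:
                improved = False
            if not improved:
                logger.debug("REML: no ascent step found at iter %d", it)
                converged = abs(ll) > 0  # stuck at a stationary/boundary point
                break

        dll = ll_new - ll
        theta, ll = cand, ll_new
        P, Py, beta, beta_cov, Vinv = P_new, Py_new, beta_new, bcov_new, Vinv_new
        if abs(dll) < tol * (1.0 + abs(ll)):
            converged = True
            break
        # stagnation: repeated sub-1e-6 relative gains mean we are creeping
        # along a likelihood ridge; accept the fit
        if abs(dll) < 1e-6 * (1.0 + abs(ll)):
            n_stagnant += 1
            if n_stagnant >= 3:
                converged = True
                break
        else:
            n_stagnant = 0
    else:
        logger.warning("REML did not converge in %d iterations", max_iter)

    resid = y - X @ beta
    return REMLResult(
        theta={t.name: float(theta[k]) for k, t in enumerate(terms)},
        beta=beta,
        beta_cov=beta_cov,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        resid=resid,
        Vinv=Vinv,
        Py=Py,
        term_names=[t.name for t in terms],
    )


def theta_scale(theta: np.ndarray, k: int, terms: Sequence[RandomTerm]) -> float:
    """Conservative step scale for unbounded (covariance) parameters."""
    bounded_vals = [abs(theta[j]) for j, t in enumerate(terms) if t.bounded]
    base = max(bounded_vals) if bounded_vals else 1.0
    return 1e-3 * base / max(terms[k].n_levels, 1)
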