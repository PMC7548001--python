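"""Third-stage breeding-value prediction from relationship matrices.

Six models share one machinery:

* GBLUP / HBLUP — single kernel, y = mu 1 + g + e with
  g ~ N(0, K sigma^2) and e ~ N(0, R), R diagonal from stage weights
  with one estimated scale;
* G+H — two independent kernel effects, combined prediction g_K + g_H;
* Bivariate_G / Bivariate_H / Bivariate_G+H — DMY and a secondary
  trait (plant height) stacked, with per-kernel unstructured 2x2 trait
  covariances C (Kronecker with the kernel) and an unstructured 2x2
  residual covariance; fitted unweighted.

All fits run the shared AI-REML engine on the observed rows; breeding
values for every genotype in the kernel universe — including genotypes
whose response is masked — come from the Gaussian conditional
expectation  E[g | y] = Cov(g, y) V^{-1} (y - X beta).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import KernelMatrix
from .reml import ai_reml, dense_term, diag_term, kernel_term
from .stagewise import AdjustedMeans

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionFit",
    "fit_single_kernel",
    "fit_multi_kernel",
    "fit_bivariate",
    "predict_validation",
]

MODEL_TAGS = ("GBLUP", "HBLUP", "G+H", "Bivariate_G", "Bivariate_H",
              "Bivariate_G+H")


@dataclass
class PredictionFit:
    model: str
    mu: np.ndarray                     # (1,) univariate, (2,) bivariate
    varcomps: dict[str, float]
    ebv: pd.DataFrame                  # per-genotype effects + combined
    loglik: float
    converged: bool
    # prediction machinery (training-row covariance pieces)
    _ids: list[str] = field(repr=False, default_factory=list)
    _kernels: dict = field(repr=False, default_factory=dict)
    _Vinv_resid: np.ndarray | None = field(repr=False, default=None)
    _row_geno: np.ndarray | None = field(repr=False, default=None)
    _row_trait: np.ndarray | None = field(repr=False, default=None)
    _trait_cov: dict = field(repr=False, default_factory=dict)

    def predicted(self, ids=None) -> pd.Series:
        """mu + combined breeding value, the DMY-scale prediction."""
        out = self.mu[0] + self.ebv["combined"]
        return out if ids is None else out.loc[list(ids)]


def _align(y: AdjustedMeans, kernels: list[KernelMatrix]):
    ids = list(kernels[0].ids)
    for K in kernels[1:]:
        if set(K.ids) != set(ids):
            raise ValueError("kernels cover different genotype sets")
    missing = set(y.blues.index) - set(ids)
    if missing:
        raise ValueError(f"response genotypes missing from kernel: {sorted(missing)[:5]}")
    return ids


def _kernel_corr(G: np.ndarray, H: np.ndarray) -> float:
    g = G[np.triu_indices_from(G)]
    h = H[np.triu_indices_from(H)]
    return float(np.corrcoef(g, h)[0, 1])


def fit_single_kernel(y: AdjustedMeans, K: KernelMatrix,
                      weights: pd.Series | None = None,
                      model: str | None = None) -> PredictionFit:
    """GBLUP (marker kernel) / HBLUP (spectral kernel) fit and BLUPs for
    every genotype in the kernel, phenotyped or not."""
    return _fit_univariate(y, [K], weights,
                           model or ("GBLUP" if K.kind == "G" else "HBLUP"))


def fit_multi_kernel(y: AdjustedMeans, G: KernelMatrix, H: KernelMatrix,
                     weights: pd.Series | None = None) -> PredictionFit:
    """Two independent kernel effects g_K + g_H (multi-kernel model)."""
    if _kernel_corr(G.reindex(sorted(G.ids)).values,
                    H.reindex(sorted(G.ids)).values) > 0.99:
        logger.warning("G and H are nearly identical: the split of genetic "
                       "variance between kernels is not identifiable")
    return _fit_univariate(y, [G, H], weights, "G+H")


def _fit_univariate(y, kernels, weights, model) -> PredictionFit:
    ids = _align(y, kernels)
    kernels = [K.reindex(ids).psd_repaired() for K in kernels]
    obs = [g for g in ids if g in y.blues.index]
    yv = y.blues.loc[obs].to_numpy(dtype=float)
    n = len(obs)
    pos = {g: i for i, g in enumerate(ids)}
    codes = np.array([pos[g] for g in obs])
    terms = [kernel_term(K.kind, codes, K.values) for K in kernels]
    if weights is not None:
        w = weights.loc[obs].to_numpy(dtype=float)
        terms.append(diag_term("residual", 1.0 / w))
    else:
        terms.append(diag_term("residual", np.ones(n)))
    X = np.ones((n, 1))
    res = ai_reml(yv, X, terms)
    mu = res.beta

    ebv = {}
    combined = np.zeros(len(ids))
    Vinv_resid = res.Vinv @ res.resid
    for K in kernels:
        sig = res.theta[K.kind]
        g_all = sig * K.values[:, codes] @ Vinv_resid
        ebv["g_" + K.kind] = g_all
        combined += g_all
    ebv["combined"] = combined
    return PredictionFit(
        model=model, mu=mu, varcomps=res.theta,
        ebv=pd.DataFrame(ebv, index=pd.Index(ids, name="genotype")),
        loglik=res.loglik, converged=res.converged,
        _ids=ids,
        _kernels={K.kind: K.values for K in kernels},
        _Vinv_resid=Vinv_resid,
        _row_geno=codes,
        _row_trait=np.zeros(n, dtype=int),
        _trait_cov={K.kind: np.array([[res.theta[K.kind]]]) for K in kernels},
    )


def fit_bivariate(y1: AdjustedMeans, y2: AdjustedMeans,
                  G: KernelMatrix | None = None,
                  H: KernelMatrix | None = None,
                  weights: pd.Series | None = None) -> PredictionFit:
    """Bivariate BLUP of DMY with a secondary trait.

    ``y1`` is the target (DMY BLUEs, possibly with masked genotypes
    absent), ``y2`` the secondary trait (typically observed for every
    genotype).  At least one kernel must be given.  Residuals are
    unweighted by default; pass ``weights`` to scale the DMY residual
    diagonal.
    """
    kernels = [k for k in (G, H) if k is not None]
    if not kernels:
        raise ValueError("at least one of G / H must be included")
    tag = {(True, True): "Bivariate_G+H", (True, False): "Bivariate_G",
           (False, True): "Bivariate_H"}[(G is not None, H is not None)]
    ids = _align(y2, kernels)
    kernels = [K.reindex(ids).psd_repaired() for K in kernels]
    pos = {g: i for i, g in enumerate(ids)}

    obs1 = [g for g in ids if g in y1.blues.index]
    obs2 = [g for g in ids if g in y2.blues.index]
    yv = np.concatenate([y1.blues.loc[obs1].to_numpy(dtype=float),
                         y2.blues.loc[obs2].to_numpy(dtype=float)])
    geno = np.concatenate([[pos[g] for g in obs1], [pos[g] for g in obs2]]).astype(int)
    trait = np.concatenate([np.zeros(len(obs1), int), np.ones(len(obs2), int)])
    n = len(yv)
    X = np.zeros((n, 2))
    X[trait == 0, 0] = 1.0
    X[trait == 1, 1] = 1.0

    terms = []
    psd_groups = []
    for K in kernels:
        Kfull = K.values[np.ix_(geno, geno)]
        m11 = np.where(trait == 0, 1.0, 0.0)
        m22 = np.where(trait == 1, 1.0, 0.0)
        A11 = Kfull * np.outer(m11, m11)
        A22 = Kfull * np.outer(m22, m22)
        A12 = Kfull * (np.outer(m11, m22) + np.outer(m22, m11))
        i0 = len(terms)
        terms += [dense_term(f"{K.kind}:c11", A11),
                  dense_term(f"{K.kind}:c12", A12, bounded=False),
                  dense_term(f"{K.kind}:c22", A22)]
        psd_groups.append((i0, i0 + 1, i0 + 2))

    same = (geno[:, None] == geno[None, :])
    d1 = np.where(trait == 0, 1.0, 0.0)
    d2 = np.where(trait == 1, 1.0, 0.0)
    if weights is not None:
        w = np.ones(n)
        w[trait == 0] = weights.loc[obs1].to_numpy(dtype=float)
        R11 = np.diag(d1 / w)
    else:
        R11 = np.diag(d1)
    i0 = len(terms)
    R12 = same * (np.outer(d1, d2) + np.outer(d2, d1))
    terms += [dense_term("R:r11", R11),
              dense_term("R:r12", R12, bounded=False),
              dense_term("R:r22", np.diag(d2))]
    psd_groups.append((i0, i0 + 1, i0 + 2))

    res = ai_reml(yv, X, terms, psd_groups=psd_groups,
                  fixed_names=["mu_dmy", "mu_secondary"])

    Vinv_resid = res.Vinv @ res.resid
    ebv = {}
    combined = np.zeros(len(ids))
    trait_cov = {}
    for K in kernels:
        C = np.array([[res.theta[f"{K.kind}:c11"], res.theta[f"{K.kind}:c12"]],
                      [res.theta[f"{K.kind}:c12"], res.theta[f"{K.kind}:c22"]]])
        trait_cov[K.kind] = C
        # Cov(g1_all, y_row) = C[0, trait_row] * K[all, geno_row]
        cov = K.values[:, geno] * C[0, trait][None, :]
        g1 = cov @ Vinv_resid
        ebv["g_" + K.kind] = g1
        combined += g1
    ebv["combined"] = combined
    return PredictionFit(
        model=tag, mu=res.beta, varcomps=res.theta,
        ebv=pd.DataFrame(ebv, index=pd.Index(ids, name="genotype")),
        loglik=res.loglik, converged=res.converged,
        _ids=ids,
        _kernels={K.kind: K.values for K in kernels},
        _Vinv_resid=Vinv_resid,
        _row_geno=geno,
        _row_trait=trait,
        _trait_cov=trait_cov,
    )


def predict_validation(fit: PredictionFit, masked_ids) -> pd.Series:
    """Predicted DMY (mu + combined breeding value) for masked genotypes.

    For bivariate fits the conditioning automatically uses the observed
    secondary-trait records of the masked genotypes, which sit in the
    training rows.
    """
    masked_ids = list(masked_ids)
    missing = set(masked_ids) - set(fit._ids)
    if missing:
        raise KeyError(f"ids outside the kernel universe: {sorted(missing)[:5]}")
    return fit.predicted(masked_ids)
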