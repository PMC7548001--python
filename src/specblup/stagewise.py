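"""Stage-wise mixed-model adjustment of multi-environment trial data.

Implements the adjustment chain of a stage-wise (weighted two/three
stage) analysis of resolvable incomplete block trials:

* an across-environment phenotype model (genotype fixed; location,
  year and their genotype interactions random; trial / replicate /
  block and residual variances heterogeneous among environments);
* a within-environment phenotype model (genotype fixed; trial,
  trial.rep, trial.rep.block random);
* a first-stage model per band and environment for repeated flight
  dates with compound-symmetric within-plot errors (implemented as a
  plot random effect plus independent residual);
* a second-stage model combining per-environment band means across
  environments with Smith weights (diagonal of the inverted
  variance-covariance matrix of the stage-1 means);
* entry-mean heritability from the mean variance of a difference,
  h2 = sigma_g^2 / (sigma_g^2 + vbar/2);
* Bonferroni-Holm outlier screening of standardized conditional
  residuals (median/MAD rescaled), with the cascade rule that a plot
  flagged for DMY also loses its spectral records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reml import (REMLResult, ai_reml, diag_term, factor_term,
                   SingularFixedEffectsError)

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelSpec",
    "MixedModelFit",
    "AdjustedMeans",
    "fit_mixed_model",
    "adjust_phenotype_across_envs",
    "adjust_phenotype_within_env",
    "adjust_band_stage1",
    "adjust_band_stage2",
    "smith_weights",
    "detect_outliers",
    "apply_outlier_cascade",
    "estimate_heritability",
    "compute_dmy",
]


@dataclass(frozen=True)
class RandomSpec:
    """One random term: interaction of ``factors``, optionally with a
    separate variance per level of ``by`` (heterogeneous groups)."""

    factors: tuple[str, ...]
    by: str | None = None


@dataclass
class MixedModelSpec:
    """Declarative model: which columns are fixed / random / residual."""

    response: str
    fixed: tuple[str, ...] = ()            # empty -> intercept only
    random: tuple[RandomSpec, ...] = ()
    residual_by: str | None = None         # heterogeneous residual groups
    weights: str | None = None             # fixed diagonal weights column

    def validate(self, table: pd.DataFrame) -> None:
        cols = ({self.response} | set(self.fixed) | {self.residual_by}
                | {self.weights} | {f for r in self.random for f in r.factors}
                | {r.by for r in self.random})
        cols.discard(None)
        missing = cols - set(table.columns)
        if missing:
            raise KeyError(f"columns not in table: {sorted(missing)}")
        overlap = set(self.fixed) & {f for r in self.random for f in r.factors
                                     if len(r.factors) == 1}
        if overlap:
            raise ValueError(f"factors both fixed and random: {sorted(overlap)}")


@dataclass
class MixedModelFit:
    """REML fit with the pieces later stages consume."""

    varcomps: dict[str, float]
    fixed_effects: pd.Series
    fixed_cov: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    result: REMLResult = field(repr=False)
    spec: MixedModelSpec | None = None


@dataclass
class AdjustedMeans:
    """Genotype BLUEs with their vcov and Smith weights."""

    trait: str
    stage: str
    blues: pd.Series                      # indexed by genotype
    vcov: pd.DataFrame
    weights: pd.Series
    varcomps: dict[str, float] = field(default_factory=dict)
    sigma_g2: float | None = None

    @property
    def genotypes(self) -> list[str]:
        return list(self.blues.index)

    def subset(self, genotypes) -> "AdjustedMeans":
        g = [x for x in genotypes if x in self.blues.index]
        return AdjustedMeans(
            trait=self.trait, stage=self.stage,
            blues=self.blues.loc[g], vcov=self.vcov.loc[g, g],
            weights=self.weights.loc[g], varcomps=self.varcomps,
            sigma_g2=self.sigma_g2,
        )


def _interaction_codes(table: pd.DataFrame, factors: tuple[str, ...]) -> np.ndarray:
    if len(factors) == 1:
        return pd.factorize(table[factors[0]])[0]
    return pd.MultiIndex.from_frame(table[list(factors)]).factorize()[0]


def _build_terms(table: pd.DataFrame, spec: MixedModelSpec):
    terms = []
    for rnd in spec.random:
        codes = _interaction_codes(table, rnd.factors)
        name = ".".join(rnd.factors)
        if rnd.by is None:
            n_lev = codes.max() + 1
            if n_lev < 2:
                logger.info("dropping random term %s (single level)", name)
                continue
            terms.append(factor_term(name, codes))
        else:
            by_vals = table[rnd.by].to_numpy()
            for lv in pd.unique(by_vals):
                sub = np.where(by_vals == lv, codes, -1)
                if len(np.unique(sub[sub >= 0])) < 2:
                    logger.info("dropping %s@%s=%s (single level)", name, rnd.by, lv)
                    continue
                terms.append(factor_term(f"{name}@{rnd.by}={lv}", sub))
    return terms


def _residual_terms(table: pd.DataFrame, spec: MixedModelSpec):
    n = len(table)
    if spec.weights is not None:
        w = table[spec.weights].to_numpy(dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        return [diag_term("residual", 1.0 / w)]
    if spec.residual_by is not None:
        terms = []
        by = table[spec.residual_by].to_numpy()
        for lv in pd.unique(by):
            d = (by == lv).astype(float)
            terms.append(diag_term(f"residual@{spec.residual_by}={lv}", d))
        return terms
    return [diag_term("residual", np.ones(n))]


def _fixed_design(table: pd.DataFrame, spec: MixedModelSpec):
    """Cell-means coding for the first fixed factor, treatment coding for
    the rest.  Returns (X, column names, level labels of factor one)."""
    if not spec.fixed:
        return np.ones((len(table), 1)), ["(intercept)"], None
    first = spec.fixed[0]
    levels, codes = np.unique(table[first].to_numpy(), return_inverse=True)
    X = np.zeros((len(table), len(levels)))
    X[np.arange(len(table)), codes] = 1.0
    names = [f"{first}[{lv}]" for lv in levels]
    for f in spec.fixed[1:]:
        lv2, c2 = np.unique(table[f].to_numpy(), return_inverse=True)
        for j, lv in enumerate(lv2[1:], start=1):
            X = np.hstack([X, (c2 == j).astype(float)[:, None]])
            names.append(f"{f}[{lv}]")
    return X, names, list(levels)


def fit_mixed_model(table: pd.DataFrame, spec: MixedModelSpec,
                    **reml_kwargs) -> MixedModelFit:
    """REML fit of a declarative mixed model on a plot/means table."""
    spec.validate(table)
    y = table[spec.response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    X, names, _ = _fixed_design(table, spec)
    terms = _build_terms(table, spec) + _residual_terms(table, spec)
    res = ai_reml(y, X, terms, fixed_names=names, **reml_kwargs)
    return MixedModelFit(
        varcomps=res.theta,
        fixed_effects=pd.Series(res.beta, index=names),
        fixed_cov=pd.DataFrame(res.beta_cov, index=names, columns=names),
        loglik=res.loglik,
        converged=res.converged,
        n_iter=res.n_iter,
        result=res,
        spec=spec,
    )


def _genotype_means(fit: MixedModelFit, table: pd.DataFrame,
                    trait: str, stage: str,
                    extra_varcomps: dict | None = None) -> AdjustedMeans:
    levels = [n[len("genotype["):-1] for n in fit.fixed_effects.index
              if n.startswith("genotype[")]
    blues = fit.fixed_effects.iloc[:len(levels)].set_axis(levels)
    vcov = fit.fixed_cov.iloc[:len(levels), :len(levels)]
    vcov = pd.DataFrame(vcov.to_numpy(), index=levels, columns=levels)
    w = smith_weights(vcov.to_numpy())
    return AdjustedMeans(
        trait=trait, stage=stage, blues=blues, vcov=vcov,
        weights=pd.Series(w, index=levels),
        varcomps=dict(fit.varcomps) | (extra_varcomps or {}),
    )


# ---------------------------------------------------------------------------
# phenotype models


def adjust_phenotype_across_envs(plot_table: pd.DataFrame, trait: str,
                                 estimate_sigma_g: bool = True,
                                 heterogeneous: bool = True) -> AdjustedMeans:
    """Across-environment genotype BLUEs (genotype fixed; location, year
    and genotype interactions random; design terms and residual
    heterogeneous among environments).

    A second fit with genotype random provides sigma_g^2 for
    heritability estimation.
    """
    for col, k in (("location", 2), ("year", 2)):
        if plot_table[col].nunique() < k:
            raise ValueError(
                f"need >= 2 {col}s for the across-environment model; "
                "use adjust_phenotype_within_env for single environments"
            )
    by = "env" if heterogeneous else None
    random = (
        RandomSpec(("location",)), RandomSpec(("year",)),
        RandomSpec(("year", "location")),
        RandomSpec(("location", "genotype")), RandomSpec(("year", "genotype")),
        RandomSpec(("location", "year", "genotype")),
        RandomSpec(("env", "trial"), by=by),
        RandomSpec(("env", "trial", "rep"), by=by),
        RandomSpec(("env", "trial", "rep", "block"), by=by),
    )
    spec = MixedModelSpec(response=trait, fixed=("genotype",), random=random,
                          residual_by="env" if heterogeneous else None)
    fit = fit_mixed_model(plot_table, spec)
    extra = {}
    if estimate_sigma_g:
        spec_g = MixedModelSpec(
            response=trait, fixed=(),
            random=(RandomSpec(("genotype",)),) + random,
            residual_by="env" if heterogeneous else None,
        )
        fit_g = fit_mixed_model(plot_table, spec_g)
        extra["sigma_g2"] = fit_g.varcomps["genotype"]
    means = _genotype_means(fit, plot_table, trait, "stage2-across-env", extra)
    means.sigma_g2 = extra.get("sigma_g2")
    return means


def adjust_phenotype_within_env(plot_table: pd.DataFrame, trait: str,
                                env: str,
                                estimate_sigma_g: bool = False) -> AdjustedMeans:
    """Within-environment genotype BLUEs (trial, trial.rep,
    trial.rep.block random)."""
    sub = plot_table[plot_table["env"] == env]
    if len(sub) == 0:
        raise ValueError(f"environment {env!r} not present in the table")
    random = (RandomSpec(("trial",)), RandomSpec(("trial", "rep")),
              RandomSpec(("trial", "rep", "block")))
    spec = MixedModelSpec(response=trait, fixed=("genotype",), random=random)
    if sub["genotype"].nunique() == len(sub):
        # saturated: one plot per genotype -> BLUE is the plot value
        blues = pd.Series(sub[trait].to_numpy(), index=sub["genotype"].to_numpy())
        blues = blues.sort_index()
        vcov = pd.DataFrame(np.eye(len(blues)) * float(np.var(sub[trait])),
                            index=blues.index, columns=blues.index)
        return AdjustedMeans(trait=trait, stage="stage1-per-env",
                             blues=blues, vcov=vcov,
                             weights=pd.Series(1.0, index=blues.index))
    fit = fit_mixed_model(sub, spec)
    extra = {}
    if estimate_sigma_g:
        spec_g = MixedModelSpec(response=trait, fixed=(),
                                random=(RandomSpec(("genotype",)),) + random)
        extra["sigma_g2"] = fit_mixed_model(sub, spec_g).varcomps["genotype"]
    means = _genotype_means(fit, sub, trait, "stage1-per-env", extra)
    means.sigma_g2 = extra.get("sigma_g2")
    return means


# ---------------------------------------------------------------------------
# spectral stage 1 / stage 2


def _merge_band(spectral: pd.DataFrame, design: pd.DataFrame, band: str):
    if band not in spectral.columns:
        raise KeyError(f"band {band!r} not present in the spectral table")
    sub = spectral[["plot_id", "date", band]].merge(design, on="plot_id",
                                                    how="inner")
    return sub.rename(columns={band: "value"})


def adjust_band_stage1(spectral: pd.DataFrame, design: pd.DataFrame,
                       band: str, env: str,
                       dates: str = "all") -> AdjustedMeans:
    """Per-environment band BLUEs across repeated flight dates.

    ``dates`` is ``"all"`` (compound-symmetric errors via a plot random
    effect), ``"first"`` or ``"second"`` (single date, date terms
    dropped).  Environments with a single recorded date are analysed
    like a single-date model.
    """
    sub = _merge_band(spectral, design, band)
    sub = sub[sub["env"] == env]
    if len(sub) == 0:
        raise ValueError(f"band {band!r} has no records in env {env!r}")
    date_levels = sorted(sub["date"].unique())
    if dates in ("first", "second"):
        idx = 0 if dates == "first" else 1
        if idx >= len(date_levels):
            raise ValueError(f"env {env!r} has no {dates} flight date")
        sub = sub[sub["date"] == date_levels[idx]]
    elif dates != "all":
        raise ValueError("dates must be 'all', 'first' or 'second'")

    multi_date = sub["date"].nunique() > 1
    random = [RandomSpec(("trial",)), RandomSpec(("trial", "rep")),
              RandomSpec(("trial", "rep", "block"))]
    if multi_date:
        random = [RandomSpec(("date",)), RandomSpec(("date", "genotype")),
                  *random,
                  RandomSpec(("date", "trial")),
                  RandomSpec(("date", "trial", "rep")),
                  RandomSpec(("date", "trial", "rep", "block")),
                  RandomSpec(("plot_id",))]   # CS device: shared plot deviation
    if sub.groupby("plot_id").size().max() == 1 and sub["genotype"].nunique() == len(sub):
        blues = pd.Series(sub["value"].to_numpy(), index=sub["genotype"].to_numpy())
        blues = blues.sort_index()
        vcov = pd.DataFrame(np.eye(len(blues)) * max(float(np.var(sub["value"])), 1e-12),
                            index=blues.index, columns=blues.index)
        return AdjustedMeans(trait=band, stage="stage1-per-env", blues=blues,
                             vcov=vcov, weights=pd.Series(1.0, index=blues.index))
    spec = MixedModelSpec(response="value", fixed=("genotype",),
                          random=tuple(random))
    fit = fit_mixed_model(sub, spec)
    return _genotype_means(fit, sub, band, "stage1-per-env")


def adjust_band_stage2(stage1_means: dict[str, AdjustedMeans],
                       band: str,
                       estimate_sigma_g: bool = False) -> AdjustedMeans:
    """Across-environment band BLUEs from per-environment stage-1 means.

    Genotype fixed, environment and genotype-by-environment random;
    residuals weighted by the stage-1 Smith weights with one estimated
    scale.
    """
    if len(stage1_means) < 2:
        raise ValueError("stage 2 needs stage-1 means from >= 2 environments")
    rows = []
    for env, am in stage1_means.items():
        for g in am.blues.index:
            rows.append((g, env, am.blues[g], am.weights[g]))
    tab = pd.DataFrame(rows, columns=["genotype", "env", "value", "w"])
    counts = tab.groupby("genotype")["env"].nunique()
    single = counts[counts == 1]
    if len(single):
        logger.info("%d genotype(s) observed in a single environment", len(single))
    spec = MixedModelSpec(response="value", fixed=("genotype",),
                          random=(RandomSpec(("env",)),
                                  RandomSpec(("genotype", "env"))),
                          weights="w")
    fit = fit_mixed_model(tab, spec)
    extra = {}
    if estimate_sigma_g:
        spec_g = MixedModelSpec(response="value", fixed=(),
                                random=(RandomSpec(("genotype",)),
                                        RandomSpec(("env",)),
                                        RandomSpec(("genotype", "env"))),
                                weights="w")
        extra["sigma_g2"] = fit_mixed_model(tab, spec_g).varcomps["genotype"]
    means = _genotype_means(fit, tab, band, "stage2-across-env", extra)
    means.sigma_g2 = extra.get("sigma_g2")
    return means


# ---------------------------------------------------------------------------
# weights, outliers, heritability


def smith_weights(vcov: np.ndarray, ridge_frac: float = 1e-8) -> np.ndarray:
    """Diagonal elements of the inverted vcov of adjusted means."""
    V = np.asarray(vcov, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError("vcov must be square")
    if not np.allclose(V, V.T, atol=1e-8 * (np.abs(V).max() or 1.0)):
        raise ValueError("vcov must be symmetric")
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        ridge = ridge_frac * float(np.mean(np.diagonal(V)))
        logger.warning("singular vcov: applying ridge %.3g", ridge)
        Vi = np.linalg.inv(V + ridge * np.eye(V.shape[0]))
    return np.diagonal(Vi).copy()


def detect_outliers(plot_table: pd.DataFrame, trait: str,
                    alpha: float = 0.05) -> list[str]:
    """Bonferroni-Holm screen of robustly standardized residuals.

    Conditional residuals from the across-environment model (or the
    within-environment model when only one environment is present) are
    centred by the median, scaled by 1.4826*MAD, converted to two-sided
    normal p-values and tested at familywise level ``alpha``.
    """
    n = len(plot_table)
    if n < 10:
        logger.warning("fewer than 10 plots: outlier screening skipped")
        return []
    multi = (plot_table["location"].nunique() >= 2
             and plot_table["year"].nunique() >= 2) \
        if {"location", "year"} <= set(plot_table.columns) else False
    if multi:
        spec = MixedModelSpec(
            response=trait, fixed=(),
            random=(RandomSpec(("genotype",)),
                    RandomSpec(("location",)), RandomSpec(("year",)),
                    RandomSpec(("year", "location")),
                    RandomSpec(("location", "genotype")),
                    RandomSpec(("year", "genotype")),
                    RandomSpec(("location", "year", "genotype")),
                    RandomSpec(("env", "trial")),
                    RandomSpec(("env", "trial", "rep")),
                    RandomSpec(("env", "trial", "rep", "block"))),
        )
    else:
        spec = MixedModelSpec(
            response=trait, fixed=(),
            random=(RandomSpec(("genotype",)), RandomSpec(("trial",)),
                    RandomSpec(("trial", "rep")),
                    RandomSpec(("trial", "rep", "block"))),
        )
    fit = fit_mixed_model(plot_table, spec)
    res = fit.result
    # conditional residuals e_hat = R V^-1 (y - X beta) = R * Py
    r_name = [t for t in res.term_names if t.startswith("residual")]
    rdiag = np.zeros(n)
    tab_env = plot_table["env"].to_numpy() if "env" in plot_table else None
    for name in r_name:
        if "@" in name:
            lv = name.split("=", 1)[1]
            rdiag[tab_env == lv] = res.theta[name]
        else:
            rdiag[:] = res.theta[name]
    ehat = rdiag * res.Py
    med = np.median(ehat)
    mad = stats.median_abs_deviation(ehat, scale="normal")
    if mad == 0:
        return []
    z = (ehat - med) / mad
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    # Bonferroni-Holm step-down
    order = np.argsort(pvals)
    flagged = np.zeros(n, dtype=bool)
    for rank, i in enumerate(order):
        if pvals[i] <= alpha / (n - rank):
            flagged[i] = True
        else:
            break
    return list(plot_table.loc[flagged, "plot_id"])


def apply_outlier_cascade(plot_table: pd.DataFrame,
                          spectral: pd.DataFrame | None,
                          flagged: list[str], trait: str):
    """Remove flagged plots; for DMY, also drop their spectral records."""
    plots = plot_table[~plot_table["plot_id"].isin(flagged)].copy()
    if spectral is not None and trait.upper() == "DMY":
        spectral = spectral[~spectral["plot_id"].isin(flagged)].copy()
    return plots, spectral


def estimate_heritability(means_vcov: np.ndarray | pd.DataFrame,
                          sigma_g2: float) -> float:
    """Entry-mean heritability h2 = sg^2 / (sg^2 + vbar/2), with vbar the
    mean variance of a difference between two adjusted genotype means."""
    if sigma_g2 < 0:
        raise ValueError("sigma_g2 must be non-negative")
    V = np.asarray(means_vcov, dtype=float)
    n = V.shape[0]
    if n < 2:
        raise ValueError("need vcov for >= 2 genotypes")
    vbar = (n * np.trace(V) - V.sum()) / (n * (n - 1) / 2.0)
    denom = sigma_g2 + vbar / 2.0
    if denom == 0:
        raise ZeroDivisionError("sigma_g2 and vbar are both zero: h2 undefined")
    return float(sigma_g2 / denom)


def compute_dmy(fmy, dmc):
    """DMY = FMY * DMC / 100 (dt/ha from dt/ha and percent)."""
    fmy = np.asarray(fmy, dtype=float)
    dmc = np.asarray(dmc, dtype=float)
    if np.any(fmy < 0):
        raise ValueError("FMY must be non-negative")
    if np.any((dmc < 0) | (dmc > 100)):
        raise ValueError("DMC must lie in [0, 100] percent")
    out = fmy * dmc / 100.0
    return float(out) if out.ndim == 0 else out
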