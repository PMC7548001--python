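"""Cross-validation schemes for the prediction models.

Scheme S1 evaluates models across the full environment series by
repeated k-fold cross-validation and by training sets of fixed size;
scheme S2 evaluates the transfer of a spectral-kernel model fitted on
E training environments to one held-out environment, with the band
means re-adjusted from the training environments only (no leakage).
Prediction ability is the Pearson correlation between predicted and
observed genotype BLUEs.

Validation genotypes' target-trait records never enter the training
inputs: the response is subset to the training genotypes before any
model sees it, and every iteration asserts the training / validation
partition is disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .kernels import KernelMatrix, spectral_h
from .predict import (PredictionFit, fit_bivariate, fit_multi_kernel,
                      fit_single_kernel, predict_validation)
from .stagewise import AdjustedMeans, adjust_band_stage2

logger = logging.getLogger(__name__)

__all__ = [
    "DataBundle",
    "CVResult",
    "prediction_ability",
    "run_s1_cv",
    "run_trn_size_experiment",
    "selected_fraction_eval",
    "run_s2_env_transfer",
]


@dataclass
class DataBundle:
    """Everything scheme S1 needs, plus per-environment pieces for S2."""

    dmy: AdjustedMeans                       # across-env DMY BLUEs
    ph: AdjustedMeans | None = None          # across-env PH BLUEs
    G: KernelMatrix | None = None
    H: dict[str, KernelMatrix] = field(default_factory=dict)  # by kind
    # S2 inputs
    dmy_per_env: dict[str, AdjustedMeans] = field(default_factory=dict)
    band_stage1: dict[str, dict[str, AdjustedMeans]] = field(default_factory=dict)
    # band -> {env -> stage-1 means}

    @property
    def genotypes(self) -> list[str]:
        return list(self.dmy.blues.index)

    def kernel_for(self, model: str, h_kind: str) -> list[KernelMatrix]:
        if model in ("GBLUP", "Bivariate_G"):
            return [self.G]
        if model in ("HBLUP", "Bivariate_H"):
            return [self.H[h_kind]]
        return [self.G, self.H[h_kind]]


@dataclass
class CVResult:
    scheme: str
    model: str
    records: pd.DataFrame            # rep, fold/size/env columns, r
    predictions: list[dict] = field(default_factory=list, repr=False)

    def summary(self, by=None) -> pd.DataFrame:
        by = by or [c for c in ("size", "E", "val_env") if c in self.records]
        grp = self.records.groupby(by)["r"] if by else self.records["r"]
        if by:
            out = grp.agg(["mean", "std", "count"]).reset_index()
        else:
            out = pd.DataFrame([[grp.mean(), grp.std(), grp.count()]],
                               columns=["mean", "std", "count"])
        out["se"] = out["std"] / np.sqrt(out["count"])
        return out


def prediction_ability(predicted, observed) -> float:
    """Pearson correlation between predictions and observed BLUEs."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.size != o.size or p.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(p) == 0 or np.std(o) == 0:
        return float("nan")
    return float(np.corrcoef(p, o)[0, 1])


def _fit_and_predict(bundle: DataBundle, model: str, trn: list[str],
                     val: list[str], h_kind: str) -> pd.Series:
    assert not set(trn) & set(val), "training/validation sets overlap"
    y_trn = bundle.dmy.subset(trn)
    assert set(y_trn.blues.index) <= set(trn), "validation DMY leaked into training"
    kernels = bundle.kernel_for(model, h_kind)
    if model.startswith("Bivariate"):
        G = kernels[0] if model in ("Bivariate_G", "Bivariate_G+H") else None
        H = (kernels[-1] if model in ("Bivariate_H", "Bivariate_G+H") else None)
        fit = fit_bivariate(y_trn, bundle.ph, G=G, H=H)
    elif model == "G+H":
        fit = fit_multi_kernel(y_trn, kernels[0], kernels[1],
                               weights=bundle.dmy.weights.loc[trn])
    else:
        fit = fit_single_kernel(y_trn, kernels[0],
                                weights=bundle.dmy.weights.loc[trn],
                                model=model)
    return predict_validation(fit, val)


def _check_model(model: str):
    valid = ("GBLUP", "HBLUP", "G+H", "Bivariate_G", "Bivariate_H",
             "Bivariate_G+H")
    if model not in valid:
        raise ValueError(f"unknown model {model!r}; expected one of {valid}")


def run_s1_cv(bundle: DataBundle, model: str, k: int = 5, reps: int = 100,
              seed: int = 0, h_kind: str = "H_vsel") -> CVResult:
    """Scheme S1: repeated random k-fold cross-validation."""
    _check_model(model)
    ids = np.array(bundle.genotypes)
    n = len(ids)
    if k > n // 3:
        raise ValueError("k must be <= n/3 so every fold supports a correlation")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        folds = np.array_split(rng.permutation(n), k)
        for f, test in enumerate(folds):
            val = list(ids[test])
            trn = list(ids[np.setdiff1d(np.arange(n), test)])
            try:
                pred = _fit_and_predict(bundle, model, trn, val, h_kind)
            except Exception as err:     # noqa: BLE001 - fold failure logged
                logger.warning("rep %d fold %d failed: %s", rep, f, err)
                rows.append((rep, f, np.nan))
                continue
            r = prediction_ability(pred, bundle.dmy.blues.loc[val])
            rows.append((rep, f, r))
    return CVResult("S1", model, pd.DataFrame(rows, columns=["rep", "fold", "r"]))


def run_trn_size_experiment(bundle: DataBundle, model: str,
                            sizes=(55, 110, 165, 220), reps: int = 500,
                            seed: int = 0, h_kind: str = "H_vsel",
                            keep_predictions: bool = False) -> CVResult:
    """Scheme S1 with fixed training-set sizes; VAL is the remainder."""
    _check_model(model)
    ids = np.array(bundle.genotypes)
    n = len(ids)
    if max(sizes) > n - 3:
        raise ValueError("training size leaves fewer than 3 validation genotypes")
    rng = np.random.default_rng(seed)
    rows, preds = [], []
    for rep in range(reps):
        for size in sizes:
            sel = rng.choice(n, size=size, replace=False)
            trn = list(ids[sel])
            val = list(ids[np.setdiff1d(np.arange(n), sel)])
            try:
                pred = _fit_and_predict(bundle, model, trn, val, h_kind)
            except Exception as err:     # noqa: BLE001
                logger.warning("rep %d size %d failed: %s", rep, size, err)
                rows.append((rep, size, np.nan))
                continue
            r = prediction_ability(pred, bundle.dmy.blues.loc[val])
            rows.append((rep, size, r))
            if keep_predictions and size == max(sizes):
                preds.append({"rep": rep, "size": size,
                              "predicted": pred.copy()})
    return CVResult("S1-size", model,
                    pd.DataFrame(rows, columns=["rep", "size", "r"]),
                    predictions=preds)


def selected_fraction_eval(cv_run: CVResult, dmy: AdjustedMeans,
                           ph: AdjustedMeans,
                           thresholds=(0.10, 0.20, 0.30, 0.40)) -> pd.DataFrame:
    """Observed DMY and PH of the predicted top fractions.

    Per stored CV iteration, genotypes ranked above each threshold by
    predicted DMY are extracted and their observed BLUEs averaged;
    rows aggregate over iterations.
    """
    if not cv_run.predictions:
        raise ValueError("cv_run holds no stored predictions; rerun with "
                         "keep_predictions=True")
    rows = []
    for thr in thresholds:
        vals_d, vals_p = [], []
        for rec in cv_run.predictions:
            pred = rec["predicted"]
            n_sel = int(np.floor(thr * len(pred)))
            if n_sel < 1:
                logger.warning("threshold %.2f selects no genotype; skipped", thr)
                break
            # stable sort on genotype id breaks prediction ties
            ranked = pred.sort_index().sort_values(
                ascending=False, kind="stable")
            top = list(ranked.index[:n_sel])
            vals_d.append(float(dmy.blues.loc[top].mean()))
            vals_p.append(float(ph.blues.loc[top].mean()))
        else:
            rows.append((cv_run.model, thr, float(np.mean(vals_d)),
                         float(np.mean(vals_p))))
    return pd.DataFrame(rows, columns=["model", "threshold",
                                       "mean_observed_dmy", "mean_observed_ph"])


def run_s2_env_transfer(bundle: DataBundle, E_sizes=None, seed: int = 0,
                        max_combos_per_cell: int | None = None) -> CVResult:
    """Scheme S2: train on E environments, validate on one held-out env.

    The spectral kernel (all bands) is rebuilt per combination from the
    training environments only: stage-1 band means of those
    environments are combined by the weighted stage-2 model (E >= 2) or
    used directly (E = 1).  The DMY training response is likewise
    combined from the training environments' within-environment BLUEs;
    the observed validation values are the held-out environment's
    within-environment BLUEs.
    """
    envs = sorted(bundle.dmy_per_env)
    n_envs = len(envs)
    if n_envs < 2:
        raise ValueError("scheme S2 needs >= 2 environments")
    if E_sizes is None:
        E_sizes = range(1, n_envs)
    E_sizes = list(E_sizes)
    if max(E_sizes) >= n_envs:
        raise ValueError("E must be smaller than the number of environments")
    bands = sorted(bundle.band_stage1)
    if not bands:
        raise ValueError("bundle lacks stage-1 band means for scheme S2")
    rng = np.random.default_rng(seed)
    rows = []
    for E in E_sizes:
        cells: dict[str, list] = {}
        for combo in combinations(envs, E):
            for val_env in envs:
                if val_env in combo:
                    continue
                cells.setdefault(val_env, []).append(combo)
        for val_env, combos in cells.items():
            if (max_combos_per_cell is not None
                    and len(combos) > max_combos_per_cell):
                pick = rng.choice(len(combos), max_combos_per_cell,
                                  replace=False)
                combos = [combos[i] for i in pick]
            for combo in combos:
                r = _s2_one_combo(bundle, bands, combo, val_env)
                rows.append((E, val_env, "+".join(combo), r))
    return CVResult("S2", "HBLUP",
                    pd.DataFrame(rows, columns=["E", "val_env", "trn_envs", "r"]))


def _combine_across_envs(per_env: dict[str, AdjustedMeans], envs,
                         label: str) -> AdjustedMeans:
    sub = {e: per_env[e] for e in envs}
    if len(envs) == 1:
        return sub[envs[0]]
    return adjust_band_stage2(sub, label)


def _s2_one_combo(bundle: DataBundle, bands, trn_envs, val_env) -> float:
    assert val_env not in trn_envs, "validation environment leaked into training"
    band_means = {
        b: _combine_across_envs(bundle.band_stage1[b], list(trn_envs), b)
        for b in bands
    }
    H = spectral_h(band_means, kind="H_all")
    y_trn = _combine_across_envs(bundle.dmy_per_env, list(trn_envs), "DMY")
    common = [g for g in H.ids if g in y_trn.blues.index]
    fit = fit_single_kernel(y_trn.subset(common), H,
                            weights=y_trn.weights.loc[common], model="HBLUP")
    observed = bundle.dmy_per_env[val_env].blues
    ids = [g for g in H.ids if g in observed.index]
    pred = fit.predicted(ids)
    return prediction_ability(pred, observed.loc[ids])
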