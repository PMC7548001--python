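"""End-to-end wiring: simulate -> adjust -> kernels -> selection -> bundle.

This is the convenience layer gluing the stage-wise analysis together
for a simulated study, producing the :class:`~specblup.validate.DataBundle`
that the cross-validation schemes consume.  Each step is also usable on
its own with field data read through :mod:`specblup.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import band_columns
from .kernels import (KernelMatrix, filter_markers, h2_threshold_bands,
                      spectral_h, vanraden_g)
from .selection import SelectionResult, run_band_selection
from .simulate import SimulationConfig, TruthRecord, simulate_study
from .stagewise import (AdjustedMeans, adjust_band_stage1, adjust_band_stage2,
                        adjust_phenotype_across_envs,
                        adjust_phenotype_within_env, apply_outlier_cascade,
                        detect_outliers, estimate_heritability)
from .validate import DataBundle

logger = logging.getLogger(__name__)

__all__ = ["StudyData", "run_pipeline"]


@dataclass
class StudyData:
    """All artifacts of one simulated study run through the pipeline."""

    cfg: SimulationConfig
    truth: TruthRecord
    markers: pd.DataFrame
    design: pd.DataFrame
    plots: pd.DataFrame
    spectra: pd.DataFrame
    dmy: AdjustedMeans
    ph: AdjustedMeans
    dmy_per_env: dict[str, AdjustedMeans]
    band_stage1: dict[str, dict[str, AdjustedMeans]]
    band_means: dict[str, AdjustedMeans]
    band_h2: pd.Series
    h2_dmy: float
    h2_ph: float
    G: KernelMatrix
    H: dict[str, KernelMatrix]
    selection: SelectionResult | None
    outliers: list[str] = field(default_factory=list)

    @property
    def bundle(self) -> DataBundle:
        return DataBundle(dmy=self.dmy, ph=self.ph, G=self.G, H=self.H,
                          dmy_per_env=self.dmy_per_env,
                          band_stage1=self.band_stage1)


def run_pipeline(cfg: SimulationConfig, *, screen_outliers: bool = True,
                 selection_method: str = "lasso", selection_runs: int = 50,
                 selection_threshold: float = 0.40,
                 per_env_dmy: bool = True,
                 band_h2_estimates: bool = True) -> StudyData:
    """Simulate a study and run the full stage-wise analysis on it."""
    markers, truth, design, plots, spectra = simulate_study(cfg)

    outliers: list[str] = []
    if screen_outliers:
        outliers = detect_outliers(plots, "DMY")
        if outliers:
            logger.info("removing %d outlier plot(s)", len(outliers))
        plots, spectra = apply_outlier_cascade(plots, spectra, outliers, "DMY")

    dmy = adjust_phenotype_across_envs(plots, "DMY")
    ph = adjust_phenotype_across_envs(plots, "PH")
    h2_dmy = estimate_heritability(dmy.vcov, dmy.sigma_g2)
    h2_ph = estimate_heritability(ph.vcov, ph.sigma_g2)

    envs = sorted(plots["env"].unique())
    dmy_per_env = {}
    if per_env_dmy:
        dmy_per_env = {e: adjust_phenotype_within_env(plots, "DMY", e)
                       for e in envs}

    bands = band_columns(spectra)
    band_stage1: dict[str, dict[str, AdjustedMeans]] = {}
    band_means: dict[str, AdjustedMeans] = {}
    band_h2 = {}
    for b in bands:
        per_env = {e: adjust_band_stage1(spectra, design, b, e) for e in envs}
        band_stage1[b] = per_env
        am = adjust_band_stage2(per_env, b, estimate_sigma_g=band_h2_estimates)
        band_means[b] = am
        if band_h2_estimates:
            band_h2[b] = estimate_heritability(am.vcov, am.sigma_g2)
    band_h2 = pd.Series(band_h2, dtype=float)

    G = vanraden_g(filter_markers(markers.astype(float)))
    H: dict[str, KernelMatrix] = {"H_all": spectral_h(band_means, kind="H_all")}
    if band_h2_estimates and len(band_h2):
        h2_bands = h2_threshold_bands(band_h2)
        if h2_bands:
            H["H_h2"] = spectral_h(band_means, h2_bands, kind="H_h2")

    selection = None
    if selection_runs:
        ids = sorted(dmy.blues.index)
        X = np.column_stack([
            _standardize(band_means[b].blues.loc[ids].to_numpy()) for b in bands
        ])
        y = dmy.blues.loc[ids].to_numpy(dtype=float)
        selection = run_band_selection(
            X, y, bands, method=selection_method, n_runs=selection_runs,
            threshold=selection_threshold, seed=cfg.seed + 1,
        )
        chosen = selection.selected
        if not chosen:
            top = float(selection.recovery_rate.max())
            chosen = [b for b, r in zip(bands, selection.recovery_rate)
                      if r == top]
            logger.warning("no band above the recovery threshold; falling "
                           "back to the %d most recovered band(s)", len(chosen))
        H["H_vsel"] = spectral_h(band_means, chosen, kind="H_vsel")

    return StudyData(cfg=cfg, truth=truth, markers=markers, design=design,
                     plots=plots, spectra=spectra, dmy=dmy, ph=ph,
                     dmy_per_env=dmy_per_env, band_stage1=band_stage1,
                     band_means=band_means, band_h2=band_h2,
                     h2_dmy=h2_dmy, h2_ph=h2_ph, G=G, H=H,
                     selection=selection, outliers=outliers)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / (sd if sd > 0 else 1.0)
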