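"""Genotype relationship matrices from markers (G) and band BLUEs (H).

``G`` follows VanRaden's first method, G = ZZ' / (2 sum p_i (1 - p_i))
with Z the column-centred dosage matrix.  ``H = DD'`` where D holds the
standardized (mean 0, SD 1 with denominator n-1) across-environment
BLUEs of the reflectance bands; the band subset distinguishes the
variants H_all (every band), H_vsel (penalized-selection bands) and
H_h2 (bands with above-average heritability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stagewise import AdjustedMeans

logger = logging.getLogger(__name__)

__all__ = [
    "KernelMatrix",
    "filter_markers",
    "vanraden_g",
    "spectral_h",
    "h2_threshold_bands",
]


@dataclass
class KernelMatrix:
    """Symmetric genotype x genotype relationship matrix."""

    ids: list[str]
    values: np.ndarray
    kind: str                       # "G" | "H_all" | "H_vsel" | "H_h2"
    bands: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("kernel shape does not match id count")
        if not np.allclose(v, v.T, atol=1e-8 * (np.abs(v).max() or 1.0)):
            raise ValueError("kernel must be symmetric")
        self.values = (v + v.T) / 2.0

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def psd_repaired(self, ridge_frac: float = 1e-6) -> "KernelMatrix":
        """Add a ridge proportional to the mean diagonal if needed."""
        lo = self.min_eigenvalue()
        if lo >= 0.0:
            return self
        ridge = ridge_frac * float(np.mean(np.diagonal(self.values))) - lo
        logger.info("PSD repair of %s kernel: ridge %.3g", self.kind, ridge)
        return KernelMatrix(self.ids, self.values + ridge * np.eye(len(self.ids)),
                            self.kind, self.bands)

    def reindex(self, ids: list[str]) -> "KernelMatrix":
        pos = {g: i for i, g in enumerate(self.ids)}
        idx = np.array([pos[g] for g in ids])
        return KernelMatrix(list(ids), self.values[np.ix_(idx, idx)],
                            self.kind, self.bands)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def filter_markers(markers: pd.DataFrame, max_missing: float = 0.10,
                   min_maf: float = 0.05) -> pd.DataFrame:
    """Two-pass marker QC: drop by missingness and MAF, impute missing
    dosages by the rounded per-marker mean, then re-filter MAF.

    Missing entries may be NaN.  Dosages must be in {0, 1, 2} otherwise.
    """
    M = markers.to_numpy(dtype=float)
    obs = ~np.isnan(M)
    vals = M[obs]
    if not np.isin(vals, (0.0, 1.0, 2.0)).all():
        raise ValueError("marker dosages must be 0, 1, 2 or missing")
    miss_frac = 1.0 - obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(M, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = (miss_frac <= max_missing) & (maf >= min_maf)
    M = M[:, keep]
    cols = markers.columns[keep]
    # mean imputation rounded to the nearest valid dosage
    means = np.nanmean(M, axis=0)
    rounded = np.clip(np.round(means), 0, 2)
    idx = np.where(np.isnan(M))
    M[idx] = rounded[idx[1]]
    # pass two: imputation can move the MAF across the threshold
    p2 = M.mean(axis=0) / 2.0
    keep2 = np.minimum(p2, 1.0 - p2) >= min_maf
    M = M[:, keep2]
    cols = cols[keep2]
    if M.shape[1] == 0:
        raise ValueError("all markers removed by QC filtering")
    return pd.DataFrame(M.astype(np.int64), index=markers.index, columns=cols)


def vanraden_g(markers: pd.DataFrame) -> KernelMatrix:
    """VanRaden method-1 genomic relationship matrix."""
    M = markers.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("markers must be imputed before building G")
    p = M.mean(axis=0) / 2.0
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("monomorphic markers present; filter before building G")
    Z = M - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    G = Z @ Z.T / denom
    return KernelMatrix(list(markers.index), G, "G")


def spectral_h(band_means: dict[str, AdjustedMeans],
               band_subset: list[str] | None = None,
               kind: str = "H_all") -> KernelMatrix:
    """Hyperspectral relationship matrix H = DD' from standardized BLUEs.

    ``band_means`` maps band name -> across-environment AdjustedMeans;
    all bands must cover the same genotypes.  Zero-variance bands are
    dropped with a warning.
    """
    bands = list(band_means) if band_subset is None else list(band_subset)
    if not bands:
        raise ValueError("empty band set")
    missing = [b for b in bands if b not in band_means]
    if missing:
        raise KeyError(f"bands without adjusted means: {missing}")
    ids = sorted(band_means[bands[0]].blues.index)
    cols, used = [], []
    for b in bands:
        blues = band_means[b].blues
        if set(blues.index) < set(ids):
            raise ValueError(f"band {b!r} lacks BLUEs for some genotypes")
        v = blues.loc[ids].to_numpy(dtype=float)
        sd = v.std(ddof=1)
        if sd <= 1e-12 * max(np.abs(v).max(), 1.0):
            logger.warning("dropping zero-variance band %s", b)
            continue
        cols.append((v - v.mean()) / sd)
        used.append(b)
    if not cols:
        raise ValueError("no bands with non-zero variance")
    D = np.column_stack(cols)
    return KernelMatrix(ids, D @ D.T, kind, bands=used)


def h2_threshold_bands(band_h2: dict[str, float] | pd.Series) -> list[str]:
    """Bands whose heritability strictly exceeds the spectrum mean."""
    s = pd.Series(band_h2, dtype=float).dropna()
    if s.empty:
        raise ValueError("no finite band heritabilities")
    mean = s.mean()
    selected = list(s.index[s > mean])
    logger.info("h2 threshold %.3f selects %d of %d bands",
                mean, len(selected), len(s))
    return selected
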