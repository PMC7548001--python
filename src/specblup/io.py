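"""CSV readers/writers for all tabular artifacts, reflectance
normalization, and run configuration.

All interchange is comma-separated UTF-8 with "." decimals.  Band
columns are named by wavelength (integer nanometres, or one decimal
for non-integer grids).  Marker input is CSV or PLINK-.raw-style
whitespace text with dosage columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kernels import KernelMatrix
from .stagewise import AdjustedMeans

__all__ = [
    "normalize_reflectance",
    "read_plot_table", "write_plot_table",
    "read_spectral_table", "write_spectral_table",
    "read_marker_matrix", "write_marker_matrix",
    "read_kernel", "write_kernel",
    "read_adjusted_means", "write_adjusted_means",
    "write_truth_record",
    "read_cv_result", "write_cv_result",
    "PipelineConfig",
]

PLOT_COLUMNS = ["plot_id", "env", "trial", "rep", "block", "genotype"]


class SchemaError(ValueError):
    """A required column is missing or a table is malformed."""


def normalize_reflectance(raw, panel):
    """NormHyp: raw reflectance divided by the gray-panel spectrum.

    Vectorized over arrays; the panel value(s) must be positive.
    """
    raw = np.asarray(raw, dtype=float)
    panel = np.asarray(panel, dtype=float)
    if np.any(panel <= 0):
        raise ValueError("gray-panel values must be positive")
    out = raw / panel
    return float(out) if out.ndim == 0 else out


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_plot_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, PLOT_COLUMNS, "plot table")
    dup = df["plot_id"][df["plot_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"plot table: duplicated plot_id {sorted(set(dup))[:5]}")
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    _require(df, PLOT_COLUMNS, "plot table")
    df.to_csv(path, index=False)


def read_spectral_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["plot_id", "date"], "spectral table")
    bands = band_columns(df)
    if not bands:
        raise SchemaError("spectral table: no wavelength-named band columns")
    dup = df[["plot_id", "date"]].duplicated()
    if dup.any():
        raise SchemaError("spectral table: duplicated plot_id x date records")
    return df


def write_spectral_table(df: pd.DataFrame, path) -> None:
    _require(df, ["plot_id", "date"], "spectral table")
    df.to_csv(path, index=False)


def band_columns(df: pd.DataFrame) -> list[str]:
    """Columns whose names parse as wavelengths (e.g. '750' or '751.5')."""
    out = []
    for c in df.columns:
        try:
            float(c)
        except ValueError:
            continue
        out.append(c)
    return out


def read_marker_matrix(path) -> pd.DataFrame:
    """CSV (genotype index column) or PLINK-.raw-style whitespace text."""
    path = Path(path)
    head = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if "," in head:
        df = pd.read_csv(path, index_col=0)
    else:
        raw = pd.read_csv(path, sep=r"\s+")
        id_col = "IID" if "IID" in raw.columns else raw.columns[0]
        drop = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                if c in raw.columns]
        df = raw.set_index(id_col).drop(columns=[c for c in drop if c != id_col],
                                        errors="ignore")
    df.index.name = "genotype"
    vals = df.to_numpy(dtype=float)
    obs = vals[~np.isnan(vals)]
    if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
        raise SchemaError("marker matrix: dosages must be 0/1/2 or missing")
    return df


def write_marker_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=True, index_label="genotype")


def read_kernel(path, kind: str = "G") -> KernelMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise SchemaError("kernel: row and column genotype ids differ")
    return KernelMatrix(list(df.index), df.to_numpy(dtype=float), kind)


def write_kernel(K: KernelMatrix, path) -> None:
    K.to_frame().to_csv(path, index=True)


def read_adjusted_means(path) -> AdjustedMeans:
    df = pd.read_csv(path)
    _require(df, ["genotype", "blue", "weight"], "adjusted means")
    blues = pd.Series(df["blue"].to_numpy(), index=df["genotype"])
    n = len(blues)
    vcov = pd.DataFrame(np.diag(1.0 / df["weight"].to_numpy()),
                        index=blues.index, columns=blues.index)
    return AdjustedMeans(
        trait=str(df.attrs.get("trait", "trait")), stage="loaded",
        blues=blues, vcov=vcov,
        weights=pd.Series(df["weight"].to_numpy(), index=blues.index),
    )


def write_adjusted_means(am: AdjustedMeans, path) -> None:
    pd.DataFrame({
        "genotype": am.blues.index,
        "blue": am.blues.to_numpy(),
        "weight": am.weights.to_numpy(),
    }).to_csv(path, index=False)


def write_truth_record(truth, prefix) -> None:
    """Ground truth of a simulation as two CSVs: <prefix>_bv.csv
    (genotype, bv_dmy, bv_ph) and <prefix>_loadings.csv."""
    truth.breeding_values.to_csv(f"{prefix}_bv.csv", index=False)
    truth.band_loadings.to_csv(f"{prefix}_loadings.csv", index=False)


def write_cv_result(cv, path, summary_path=None) -> None:
    """CVResult records as CSV (one row per repetition x fold/size/env);
    optional JSON summary (mean, SD, SE by grouping)."""
    cv.records.to_csv(path, index=False)
    if summary_path is not None:
        import json
        Path(summary_path).write_text(
            json.dumps({"scheme": cv.scheme, "model": cv.model,
                        "summary": cv.summary().to_dict(orient="records")},
                       indent=2))


def read_cv_result(path, scheme="S1", model="unknown"):
    """Re-load exported per-repetition records into a CVResult."""
    from .validate import CVResult
    df = pd.read_csv(path)
    _require(df, ["rep", "r"], "cv result")
    return CVResult(scheme, model, df)


@dataclass
class PipelineConfig:
    """Run settings for a full analysis, loadable from YAML."""

    seed: int
    plot_table: str | None = None
    spectral_table: str | None = None
    marker_matrix: str | None = None
    selection_method: str = "lasso"
    selection_threshold: float = 0.40
    selection_runs: int = 100
    h_kind: str = "H_vsel"
    cv_scheme: str = "s1"
    cv_k: int = 5
    cv_reps: int = 100
    trn_sizes: tuple[int, ...] = (55, 110, 165, 220)
    e_sizes: tuple[int, ...] = tuple(range(1, 8))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in data:
            raise ValueError("config must set a seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trn_sizes", "e_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
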