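"""Shared fixtures: small simulated studies reused across test modules.

The expensive pipeline runs are session-scoped so the stage-wise
adjustment chain executes once; individual tests interrogate the shared
artifacts.  Problem sizes are deliberately smaller than the emulated
study (fewer lines, bands and replicates) so the full suite stays fast;
docs/methods.md discusses what the scaled runs do and do not show.
"""

import numpy as np
import pytest

from specblup.simulate import SimulationConfig, simulate_study
from specblup.pipeline import run_pipeline


def small_grid(n_bands, lo=450.0, hi=980.0):
    return tuple(np.round(np.linspace(lo, hi, n_bands), 1))


@pytest.fixture(scope="session")
def tiny_cfg():
    """Four founders, eight RILs: enough to exercise shapes and seeds."""
    return SimulationConfig(
        n_founders=4, n_lines=8, n_markers=50, include_founders=False,
        n_envs=2, n_locations=2, n_years=1, block_size=2,
        n_bands=5, band_grid=small_grid(5), seed=1,
    )


@pytest.fixture(scope="session")
def small_study():
    """A full simulated study at small scale (raw tables only)."""
    cfg = SimulationConfig(
        n_founders=6, n_lines=48, n_markers=300, include_founders=False,
        n_envs=4, n_locations=2, n_years=2, block_size=8,
        n_bands=8, band_grid=small_grid(8), seed=42,
    )
    markers, truth, design, plots, spectra = simulate_study(cfg)
    return dict(cfg=cfg, markers=markers, truth=truth, design=design,
                plots=plots, spectra=spectra)


@pytest.fixture(scope="session")
def pipeline_study():
    """Full pipeline on a mid-sized study; shared by the heavier tests.

    12 bands over the full 410-993 nm range, 8 environments, 100
    genotypes: big enough that kernels, selection and prediction behave
    like the real analysis, small enough to fit the suite's runtime.
    """
    cfg = SimulationConfig(
        n_founders=10, n_lines=100, n_markers=600, include_founders=False,
        n_envs=8, n_locations=4, n_years=2, block_size=10,
        n_bands=12, band_grid=small_grid(12, 410.0, 993.0), seed=2024,
    )
    return run_pipeline(cfg, selection_runs=25, screen_outliers=False)
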