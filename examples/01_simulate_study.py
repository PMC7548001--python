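"""Simulate a small multi-environment testcross study and inspect it.

Generates markers for RILs from a round-robin founder scheme, an
alpha-lattice trial design over eight environments, plot-level
phenotypes (FMY, DMC, DMY, PH) and two-date reflectance spectra, then
prints the headline properties of the simulated data.
"""

import numpy as np

from specblup import SimulationConfig, simulate_study

cfg = SimulationConfig(
    n_founders=10, n_lines=100, n_markers=500, include_founders=False,
    n_envs=8, n_locations=4, n_years=2, block_size=10,
    n_bands=20, band_grid=tuple(np.round(np.linspace(410, 993, 20), 1)),
    seed=1,
)
markers, truth, design, plots, spectra = simulate_study(cfg)

print(f"genotypes: {markers.shape[0]}, polymorphic markers: {markers.shape[1]}")
print(f"plots: {len(plots)} ({cfg.n_envs} envs x {cfg.n_trials_per_env} trials"
      f" x {cfg.n_reps} reps)")
print(f"residual heterozygosity: {(markers.to_numpy() == 1).mean():.4f} "
      "(S4 lines: expected a few percent)")
print(f"DMY = FMY*DMC/100 exact: "
      f"{np.allclose(plots.DMY, plots.FMY * plots.DMC / 100)}")
print(f"target entry-mean h2 (DMY, PH): "
      f"{truth.realized_h2['DMY']:.2f}, {truth.realized_h2['PH']:.2f}")
bv = truth.breeding_values
print(f"true genetic correlation DMY-PH: "
      f"{np.corrcoef(bv.bv_dmy, bv.bv_ph)[0, 1]:.3f}")
# Band-DMY correlations peak near the red edge (~750 nm) by construction:
merged = spectra.merge(design[["plot_id", "genotype"]], on="plot_id")
bands = [c for c in spectra.columns if c not in ("plot_id", "date")]
gmeans = merged.groupby("genotype")[bands].mean()
gdmy = plots.groupby("genotype")["DMY"].mean().loc[gmeans.index]
cors = {b: np.corrcoef(gmeans[b], gdmy)[0, 1] for b in bands}
best = max(cors, key=lambda b: abs(cors[b]))
print(f"band most correlated with DMY: {best} nm (r = {cors[best]:.2f})")
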