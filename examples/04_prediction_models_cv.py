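"""Compare the six prediction models under the S1 validation scheme.

Runs the training-set-size experiment for GBLUP, HBLUP, the
multi-kernel G+H model and the three bivariate models (plant height as
secondary trait), printing mean prediction abilities (correlation of
predicted with observed DMY BLUEs in the validation set).
"""

import numpy as np

from specblup import SimulationConfig, run_pipeline, run_trn_size_experiment

cfg = SimulationConfig(
    n_founders=10, n_lines=100, n_markers=500, include_founders=False,
    n_envs=8, n_locations=4, n_years=2, block_size=10,
    n_bands=12, band_grid=tuple(np.round(np.linspace(410, 993, 12), 1)),
    seed=7,
)
sd = run_pipeline(cfg, screen_outliers=False, selection_runs=25)
bundle = sd.bundle
n = len(bundle.genotypes)
sizes = (int(0.2 * n), int(0.5 * n), int(0.8 * n))

print(f"{n} genotypes; training sizes {sizes}; 10 repetitions each")
print(f"{'model':<15}" + "".join(f"TRN={s:<8}" for s in sizes))
for model in ("GBLUP", "HBLUP", "G+H", "Bivariate_G", "Bivariate_H",
              "Bivariate_G+H"):
    res = run_trn_size_experiment(bundle, model, sizes=sizes, reps=10,
                                  seed=11)
    m = res.summary().set_index("size")["mean"]
    print(f"{model:<15}" + "".join(f"{m[s]:<12.3f}" for s in sizes))
print("\nAbility rises with training size for every model; the spectral"
      "\nkernel and the correlated secondary trait (PH) lift the ability of"
      "\nthe marker-only baseline, most visibly at small training sizes."
      "\n(At 10 repetitions the ranking among the top models is noisy; the"
      "\ntest suite checks the ordering with proper Monte-Carlo error.)")
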