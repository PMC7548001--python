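"""Stage-wise adjustment: BLUEs, Smith weights, CS errors, outliers, h2."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from specblup.simulate import SimulationConfig, simulate_study
from specblup.stagewise import (MixedModelSpec, RandomSpec, AdjustedMeans,
                                adjust_band_stage1, adjust_band_stage2,
                                adjust_phenotype_across_envs,
                                adjust_phenotype_within_env,
                                apply_outlier_cascade, compute_dmy,
                                detect_outliers, estimate_heritability,
                                fit_mixed_model, smith_weights)


class TestSmithWeights:
    def test_diagonal_inverse(self):
        np.testing.assert_allclose(smith_weights(np.diag([2.0, 4.0])),
                                   [0.5, 0.25])

    def test_2x2_by_hand(self):
        w = smith_weights(np.array([[2.0, 1.0], [1.0, 2.0]]))
        np.testing.assert_allclose(w, [2 / 3, 2 / 3])

    def test_identity(self):
        np.testing.assert_allclose(smith_weights(np.eye(4)), np.ones(4))

    def test_singular_gets_ridge(self):
        V = np.ones((3, 3))
        w = smith_weights(V)
        assert np.all(np.isfinite(w)) and np.all(w > 0)


class TestHeritability:
    def test_plugin_half(self):
        V = np.eye(3)          # vbar = 2 for identity vcov
        assert estimate_heritability(V, 1.0) == pytest.approx(0.5)

    def test_balanced_design_formula(self):
        """sigma_g2=4, sigma_e2=4, r=2: vbar = 2 sigma_e2/r = 4 and
        h2 = 4/6, the classical entry-mean value."""
        V = np.eye(5) * (4.0 / 2.0)   # var of a mean = sigma_e2/r
        assert estimate_heritability(V, 4.0) == pytest.approx(4 / 6)

    def test_zero_genetic_variance(self):
        assert estimate_heritability(np.eye(3), 0.0) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ZeroDivisionError):
            estimate_heritability(np.zeros((3, 3)), 0.0)


class TestComputeDmy:
    @pytest.mark.parametrize("fmy,dmc,expected",
                             [(400.0, 35.0, 140.0), (250.0, 100.0, 250.0),
                              (250.0, 0.0, 0.0)])
    def test_product_rule(self, fmy, dmc, expected):
        assert compute_dmy(fmy, dmc) == pytest.approx(expected)

    def test_out_of_range_dmc(self):
        with pytest.raises(ValueError):
            compute_dmy(100.0, 120.0)


def _one_env_table(g=10, reps=2, seed=0, block_sd=2.0, err_sd=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    bv = rng.normal(0, 3.0, g)
    for rep in range(reps):
        order = rng.permutation(g)
        beff = rng.normal(0, block_sd, (g + 4) // 5)
        for pos, gi in enumerate(order):
            rows.append((f"P{rep}_{pos}", "E1", "T1", f"R{rep+1}",
                         f"B{pos // 5 + 1}", f"G{gi:02d}",
                         bv[gi] + beff[pos // 5] + rng.normal(0, err_sd)))
    return pd.DataFrame(rows, columns=["plot_id", "env", "trial", "rep",
                                       "block", "genotype", "DMY"])


class TestWithinEnv:
    def test_saturated_single_plot_blue_is_plot_value(self):
        tab = _one_env_table(g=6, reps=1)
        am = adjust_phenotype_within_env(tab, "DMY", "E1")
        expected = tab.set_index("genotype")["DMY"].sort_index()
        np.testing.assert_allclose(am.blues.sort_index(), expected)

    def test_env_not_present_raises(self):
        tab = _one_env_table()
        with pytest.raises(ValueError, match="E9"):
            adjust_phenotype_within_env(tab, "DMY", "E9")

    def test_blues_match_direct_gls_oracle(self):
        """At the fitted variance components, the BLUEs must equal the
        generalized least-squares solution computed by dense algebra."""
        tab = _one_env_table(g=12, reps=2, seed=5)
        am = adjust_phenotype_within_env(tab, "DMY", "E1")
        # rebuild V from the fitted components
        n = len(tab)
        V = np.zeros((n, n))
        for name, var in am.varcomps.items():
            if name == "residual":
                V += var * np.eye(n)
            else:
                cols = name.split(".")
                codes = pd.MultiIndex.from_frame(tab[cols]).factorize()[0] \
                    if len(cols) > 1 else pd.factorize(tab[cols[0]])[0]
                Z = np.zeros((n, codes.max() + 1))
                Z[np.arange(n), codes] = 1
                V += var * Z @ Z.T
        levels, cg = np.unique(tab["genotype"], return_inverse=True)
        X = np.zeros((n, len(levels)))
        X[np.arange(n), cg] = 1
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ tab["DMY"].to_numpy())
        np.testing.assert_allclose(am.blues.loc[levels].to_numpy(), beta,
                                   rtol=1e-8)


class TestAcrossEnv:
    def test_single_environment_guard(self):
        tab = _one_env_table()
        tab["location"] = "L1"
        tab["year"] = "Y1"
        with pytest.raises(ValueError, match="within"):
            adjust_phenotype_across_envs(tab, "DMY")

    def test_more_replication_shrinks_mean_variance_of_difference(self):
        """Doubling the replicate number roughly halves the mean variance
        of a BLUE difference (fresh errors, same genotypes)."""
        def study(n_reps, seed):
            cfg = SimulationConfig(
                n_founders=5, n_lines=40, include_founders=False,
                n_markers=200, n_envs=4, n_locations=2, n_years=2,
                n_reps=n_reps, block_size=8, n_bands=3,
                band_grid=(500., 700., 900.), seed=seed,
            )
            *_, plots, _ = simulate_study(cfg)
            am = adjust_phenotype_across_envs(plots, "DMY",
                                              estimate_sigma_g=False)
            V = am.vcov.to_numpy()
            n = V.shape[0]
            return (n * np.trace(V) - V.sum()) / (n * (n - 1) / 2)

        vbar2 = study(2, 31)
        vbar4 = study(4, 31)
        assert 0.3 < vbar4 / vbar2 < 0.75

    def test_blues_track_true_breeding_values(self, pipeline_study):
        sd = pipeline_study
        bv = sd.truth.breeding_values.set_index("genotype")["bv_dmy"]
        ids = sorted(sd.dmy.blues.index)
        r = np.corrcoef(sd.dmy.blues.loc[ids], bv.loc[ids])[0, 1]
        assert r > 0.6

    def test_h2_estimates_recover_targets(self, pipeline_study):
        sd = pipeline_study
        assert abs(sd.h2_dmy - 0.5) < 0.12
        assert abs(sd.h2_ph - 0.8) < 0.12


def _spectral_env(g=12, seed=3, identical_dates=False):
    rng = np.random.default_rng(seed)
    rows_d, rows_s = [], []
    bv = rng.normal(0, 0.05, g)
    for rep in range(2):
        for pos, gi in enumerate(rng.permutation(g)):
            pid = f"P{rep}_{pos}"
            rows_d.append((pid, "E1", "T1", f"R{rep+1}", f"B{pos // 4 + 1}",
                           f"G{gi:02d}"))
            base = 0.4 + bv[gi] + rng.normal(0, 0.03)
            for d in ("D1", "D2"):
                v = base if identical_dates else base + rng.normal(0, 0.02)
                rows_s.append((pid, d, v))
    design = pd.DataFrame(rows_d, columns=["plot_id", "env", "trial", "rep",
                                           "block", "genotype"])
    spectra = pd.DataFrame(rows_s, columns=["plot_id", "date", "550"])
    return design, spectra


class TestBandStage1:
    def test_identical_dates_push_residual_to_zero(self):
        design, spectra = _spectral_env(identical_dates=True)
        am = adjust_band_stage1(spectra, design, "550", "E1")
        vc = am.varcomps
        assert vc["residual"] < 1e-6 * vc["plot_id"]

    def test_missing_band_raises(self):
        design, spectra = _spectral_env()
        with pytest.raises(KeyError):
            adjust_band_stage1(spectra, design, "999", "E1")

    def test_single_date_single_rep_blue_is_plot_value(self):
        design, spectra = _spectral_env()
        design = design[design["rep"] == "R1"]
        spectra = spectra[(spectra["date"] == "D1")
                          & spectra["plot_id"].isin(design["plot_id"])]
        am = adjust_band_stage1(spectra, design, "550", "E1")
        obs = spectra.merge(design, on="plot_id").set_index("genotype")["550"]
        np.testing.assert_allclose(am.blues.sort_index(), obs.sort_index())

    def test_cs_parameterization_matches_direct_covariance_oracle(self):
        """The plot-effect device and a direct 2x2 within-plot covariance
        parameterization reach the same maximized REML log-likelihood."""
        design, spectra = _spectral_env(seed=17)
        am = adjust_band_stage1(spectra, design, "550", "E1")

        sub = spectra.merge(design, on="plot_id").sort_values(["plot_id", "date"])
        y = sub["550"].to_numpy()
        n = len(y)
        levels, cg = np.unique(sub["genotype"], return_inverse=True)
        X = np.zeros((n, len(levels)))
        X[np.arange(n), cg] = 1.0
        Zs = {}
        for cols in (["date"], ["date", "genotype"], ["rep"],
                     ["rep", "block"], ["date", "rep"],
                     ["date", "rep", "block"]):
            codes = pd.MultiIndex.from_frame(sub[cols]).factorize()[0] \
                if len(cols) > 1 else pd.factorize(sub[cols[0]])[0]
            Z = np.zeros((n, codes.max() + 1))
            Z[np.arange(n), codes] = 1.0
            Zs[".".join(cols)] = Z
        plot_codes = pd.factorize(sub["plot_id"])[0]
        same_plot = (plot_codes[:, None] == plot_codes[None, :]).astype(float)

        def negll(params):
            # direct parameterization: within-plot Sigma = [[t, c], [c, t]]
            *vars_, t, c = np.exp(params[:-1]).tolist() + [params[-1]]
            t = np.exp(params[-2])
            c = params[-1]
            V = np.zeros((n, n))
            for v, Z in zip(np.exp(params[:-2]), Zs.values()):
                V += v * Z @ Z.T
            V += c * same_plot + (t - c) * np.eye(n)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e10
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            ld = 2 * np.sum(np.log(np.diag(L)))
            s, ldx = np.linalg.slogdet(XtViX)
            return 0.5 * (ld + ldx + r @ Vi @ r)

        x0 = np.concatenate([np.log(np.full(len(Zs), 1e-4)),
                             [np.log(2e-3), 5e-4]])
        best = optimize.minimize(negll, x0, method="Nelder-Mead",
                                 options={"maxiter": 6000, "xatol": 1e-10,
                                          "fatol": 1e-12})
        oracle_ll = -best.fun
        # engine ll for the same model (recompute from the fit)
        from specblup.stagewise import fit_mixed_model, MixedModelSpec, RandomSpec
        sub2 = sub.rename(columns={"550": "value"})
        spec = MixedModelSpec(
            response="value", fixed=("genotype",),
            random=(RandomSpec(("date",)), RandomSpec(("date", "genotype")),
                    RandomSpec(("rep",)), RandomSpec(("rep", "block")),
                    RandomSpec(("date", "rep")),
                    RandomSpec(("date", "rep", "block")),
                    RandomSpec(("plot_id",))),
        )
        fit = fit_mixed_model(sub2, spec)
        assert fit.loglik >= oracle_ll - 1e-4
        assert abs(fit.loglik - oracle_ll) < 0.05


class TestBandStage2:
    def _means(self, envs, values, weights=None):
        out = {}
        for e, vals in zip(envs, values):
            idx = [f"G{i}" for i in range(len(vals))]
            w = np.ones(len(vals)) if weights is None else weights[e]
            out[e] = AdjustedMeans(
                trait="550", stage="stage1-per-env",
                blues=pd.Series(vals, index=idx),
                vcov=pd.DataFrame(np.diag(1 / w), index=idx, columns=idx),
                weights=pd.Series(w, index=idx),
            )
        return out

    def test_equal_weights_balanced_blue_is_mean(self):
        rng = np.random.default_rng(0)
        v1, v2 = rng.normal(0.4, 0.05, 8), rng.normal(0.45, 0.05, 8)
        s1 = self._means(["E1", "E2"], [v1, v2])
        am = adjust_band_stage2(s1, "550")
        np.testing.assert_allclose(am.blues.to_numpy(),
                                   (v1 + v2) / 2, rtol=1e-6)

    def test_extreme_weight_pulls_blue_to_reliable_env(self):
        v1 = np.array([0.50] + [0.40] * 7)
        v2 = np.array([0.10] + [0.40] * 7)
        w = {"E1": np.array([1e4] + [1.0] * 7), "E2": np.array([1e-4] + [1.0] * 7)}
        s1 = self._means(["E1", "E2"], [v1, v2], w)
        am = adjust_band_stage2(s1, "550")
        assert abs(am.blues["G0"] - 0.50) < 0.02

    def test_environment_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = [rng.normal(0.4, 0.05, 8) for _ in range(3)]
        a = adjust_band_stage2(self._means(["E1", "E2", "E3"], vals), "550")
        b = adjust_band_stage2(self._means(["E3", "E1", "E2"], vals), "550")
        np.testing.assert_allclose(a.blues.to_numpy(), b.blues.to_numpy(),
                                   rtol=1e-6)

    def test_needs_two_envs(self):
        with pytest.raises(ValueError):
            adjust_band_stage2(self._means(["E1"], [np.ones(5)]), "550")


class TestOutliers:
    def test_gross_outlier_flagged(self):
        tab = _one_env_table(g=40, reps=2, seed=9)
        tab.loc[13, "DMY"] += 10 * tab["DMY"].std()
        flagged = detect_outliers(tab, "DMY")
        assert tab.loc[13, "plot_id"] in flagged

    def test_familywise_error_controlled_on_clean_data(self):
        """On null data the Bonferroni-Holm screen flags almost nothing."""
        total = 0
        n_sim = 15
        for s in range(n_sim):
            tab = _one_env_table(g=40, reps=2, seed=100 + s)
            total += len(detect_outliers(tab, "DMY"))
        assert total / n_sim <= 1.0

    def test_dmy_cascade_removes_spectral_rows(self):
        design, spectra = _spectral_env()
        plots = design.copy()
        plots["DMY"] = 100.0
        kept, spec_kept = apply_outlier_cascade(plots, spectra,
                                                [design.plot_id.iloc[0]], "DMY")
        assert design.plot_id.iloc[0] not in set(kept.plot_id)
        assert design.plot_id.iloc[0] not in set(spec_kept.plot_id)

    def test_small_sample_skips_screening(self):
        tab = _one_env_table(g=3, reps=1)
        assert detect_outliers(tab, "DMY") == []
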