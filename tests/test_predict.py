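"""BLUP prediction models: closed forms, dense-solve oracles, equivalences."""

import numpy as np
import pandas as pd
import pytest

from specblup.kernels import KernelMatrix
from specblup.predict import (fit_bivariate, fit_multi_kernel,
                              fit_single_kernel, predict_validation)
from specblup.stagewise import AdjustedMeans


def make_means(values, ids, trait="DMY"):
    s = pd.Series(np.asarray(values, dtype=float), index=ids)
    return AdjustedMeans(
        trait=trait, stage="stage2-across-env", blues=s,
        vcov=pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids),
        weights=pd.Series(1.0, index=ids),
    )


def family_kernel(n, seed=0, kind="G"):
    """A PSD kernel with real structure (random factor loadings)."""
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n, max(3, n // 3)))
    K = L @ L.T / L.shape[1] + 0.3 * np.eye(n)
    ids = [f"g{i:03d}" for i in range(n)]
    return KernelMatrix(ids, K, kind)


class TestSingleKernel:
    def test_identity_kernel_matches_ridge_closed_form(self):
        """K = I with known variance ratio: BLUPs are uniformly shrunken
        centred phenotypes, g_hat = (sg2/(sg2+se2)) (y - mu)."""
        rng = np.random.default_rng(0)
        n = 40
        ids = [f"g{i:03d}" for i in range(n)]
        K = KernelMatrix(ids, np.eye(n), "G")
        y = 10 + rng.normal(0, 2.0, n)
        fit = fit_single_kernel(make_means(y, ids), K)
        sg2 = fit.varcomps["G"]
        se2 = fit.varcomps["residual"]
        mu = fit.mu[0]
        expected = sg2 / (sg2 + se2) * (y - mu)
        np.testing.assert_allclose(fit.ebv["combined"], expected, rtol=1e-6,
                                   atol=1e-10)

    def test_pure_noise_blups_collapse_to_mean(self):
        rng = np.random.default_rng(1)
        n = 60
        ids = [f"g{i:03d}" for i in range(n)]
        K = KernelMatrix(ids, np.eye(n), "G")
        # make between-genotype variance smaller than chance: anti-signal
        y = rng.standard_normal(n) * 1e-3 + 5.0
        y[0] += 2e-3
        fit = fit_single_kernel(make_means(y, ids), K)
        if fit.varcomps["G"] < 1e-8 * np.var(y):
            np.testing.assert_allclose(fit.ebv["combined"], 0.0, atol=1e-8)

    def test_three_genotype_mme_matches_direct_solve(self):
        """Mixed-model solution equals direct GLS/conditional-expectation
        algebra on a hand-sized system at the fitted components."""
        ids = ["a", "b", "c"]
        K = KernelMatrix(ids, np.array([[1.0, 0.5, 0.2],
                                        [0.5, 1.0, 0.4],
                                        [0.2, 0.4, 1.0]]), "G")
        y = np.array([3.0, 5.0, 4.0])
        fit = fit_single_kernel(make_means(y, ids), K)
        sg2, se2 = fit.varcomps["G"], fit.varcomps["residual"]
        V = sg2 * K.values + se2 * np.eye(3)
        X = np.ones((3, 1))
        Vi = np.linalg.inv(V)
        mu = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y).item()
        g = sg2 * K.values @ Vi @ (y - mu)
        assert fit.mu[0] == pytest.approx(mu, abs=1e-8)
        np.testing.assert_allclose(fit.ebv["combined"], g, atol=1e-8)

    def test_translation_invariance(self):
        n = 30
        K = family_kernel(n, 2)
        rng = np.random.default_rng(3)
        y = rng.normal(0, 2, n)
        f0 = fit_single_kernel(make_means(y, K.ids), K)
        f1 = fit_single_kernel(make_means(y + 100.0, K.ids), K)
        np.testing.assert_allclose(f0.ebv["combined"], f1.ebv["combined"],
                                   atol=1e-6)
        assert f1.mu[0] - f0.mu[0] == pytest.approx(100.0, abs=1e-6)


class TestPredictValidation:
    def test_no_masking_returns_fitted_values(self):
        n = 20
        K = family_kernel(n, 4)
        rng = np.random.default_rng(5)
        y = rng.normal(0, 2, n)
        fit = fit_single_kernel(make_means(y, K.ids), K)
        np.testing.assert_allclose(predict_validation(fit, K.ids),
                                   fit.predicted(K.ids))

    def test_kernel_twin_gets_equal_prediction(self):
        """A masked genotype with an identical kernel row as a training
        genotype receives the same breeding value."""
        n = 12
        rng = np.random.default_rng(6)
        L = rng.standard_normal((n, 5))
        L[-1] = L[0]                       # masked twin of g000
        K = L @ L.T / 5 + 0.0 * np.eye(n)
        ids = [f"g{i:03d}" for i in range(n)]
        KM = KernelMatrix(ids, K, "H").psd_repaired()
        y = rng.normal(0, 2, n - 1)
        fit = fit_single_kernel(make_means(y, ids[:-1]), KM)
        pred = predict_validation(fit, [ids[0], ids[-1]])
        # identical covariance rows up to the tiny PSD ridge
        assert pred.iloc[0] == pytest.approx(pred.iloc[1], abs=1e-4)

    def test_masked_prediction_matches_gaussian_conditioning_oracle(self):
        """Five genotypes, one masked: the prediction equals the
        conditional expectation from joint-covariance partitioning."""
        K = family_kernel(5, 7)
        rng = np.random.default_rng(8)
        y_all = rng.normal(0, 2, 5)
        trn = K.ids[:4]
        fit = fit_single_kernel(make_means(y_all[:4], trn), K)
        sg2, se2 = fit.varcomps["G"], fit.varcomps["residual"]
        Kv = fit._kernels["G"]             # PSD-repaired kernel used inside
        V = sg2 * Kv[:4, :4] + se2 * np.eye(4)
        mu = fit.mu[0]
        cond = mu + sg2 * Kv[4, :4] @ np.linalg.solve(V, y_all[:4] - mu)
        pred = predict_validation(fit, [K.ids[4]])
        assert pred.iloc[0] == pytest.approx(cond, abs=1e-8)

    def test_unknown_id_rejected(self):
        K = family_kernel(5, 9)
        rng = np.random.default_rng(9)
        fit = fit_single_kernel(make_means(rng.normal(0, 1, 5), K.ids), K)
        with pytest.raises(KeyError):
            predict_validation(fit, ["nope"])


class TestMultiKernel:
    def test_identical_kernels_reproduce_single_kernel_fit(self):
        """With H = G the split of variance is unidentified but the sum
        of effects and the likelihood match the single-kernel fit."""
        n = 30
        G = family_kernel(n, 10, "G")
        H = KernelMatrix(G.ids, G.values.copy(), "H_vsel")
        rng = np.random.default_rng(11)
        L = np.linalg.cholesky(G.values + 1e-8 * np.eye(n))
        y = 5 + L @ rng.standard_normal(n) + rng.normal(0, 0.8, n)
        single = fit_single_kernel(make_means(y, G.ids), G)
        multi = fit_multi_kernel(make_means(y, G.ids), G, H)
        assert multi.loglik == pytest.approx(single.loglik, abs=1e-3)
        np.testing.assert_allclose(multi.ebv["combined"],
                                   single.ebv["combined"], atol=1e-3)

    def test_null_spectral_channel_recovers_gblup(self):
        """If the H channel carries no signal its variance hits the
        bound and predictions coincide with GBLUP."""
        n = 60
        G = family_kernel(n, 12, "G")
        rng = np.random.default_rng(13)
        L = np.linalg.cholesky(G.values + 1e-8 * np.eye(n))
        y = 5 + 2 * (L @ rng.standard_normal(n)) + rng.normal(0, 1, n)
        H = KernelMatrix(G.ids, np.eye(n), "H_vsel")   # pure-noise kernel
        single = fit_single_kernel(make_means(y, G.ids), G)
        multi = fit_multi_kernel(make_means(y, G.ids), G, H)
        r = np.corrcoef(single.ebv["combined"], multi.ebv["combined"])[0, 1]
        assert r > 0.99


def bivariate_data(n, seed, rg=0.6, h2=(0.5, 0.8)):
    G = family_kernel(n, seed, "G")
    rng = np.random.default_rng(seed + 1000)
    L = np.linalg.cholesky(G.values + 1e-8 * np.eye(n))
    z1, z2 = rng.standard_normal((2, n))
    g1 = L @ z1
    g2 = rg * g1 + np.sqrt(1 - rg ** 2) * (L @ z2)
    e_sd = [np.sqrt(np.var(g) * (1 - h) / h) for g, h in zip((g1, g2), h2)]
    y1 = 100 + g1 + rng.normal(0, e_sd[0], n)
    y2 = 140 + g2 + rng.normal(0, e_sd[1], n)
    return G, g1, y1, y2


class TestBivariate:
    def test_decoupled_covariances_match_univariate(self):
        """When the estimated genetic and residual covariances are tiny
        (uncorrelated traits), DMY predictions equal the univariate fit."""
        n = 50
        G, g1, y1, _ = bivariate_data(n, 20, rg=0.0)
        rng = np.random.default_rng(21)
        y2 = 140 + rng.normal(0, 2, n)     # independent secondary trait
        uni = fit_single_kernel(make_means(y1, G.ids), G)
        biv = fit_bivariate(make_means(y1, G.ids),
                            make_means(y2, G.ids, "PH"), G=G)
        r = np.corrcoef(uni.ebv["combined"], biv.ebv["combined"])[0, 1]
        assert r > 0.999

    def test_toy_system_matches_direct_gls_oracle(self):
        """2 genotypes x 2 traits: predictions equal the direct 4x4
        conditional-expectation solve at the fitted covariances."""
        ids = ["a", "b"]
        G = KernelMatrix(ids, np.array([[1.0, 0.3], [0.3, 1.0]]), "G")
        y1 = np.array([3.0, 4.0])
        y2 = np.array([10.0, 13.0])
        biv = fit_bivariate(make_means(y1, ids), make_means(y2, ids, "PH"),
                            G=G)
        th = biv.varcomps
        C = np.array([[th["G:c11"], th["G:c12"]], [th["G:c12"], th["G:c22"]]])
        R = np.array([[th["R:r11"], th["R:r12"]], [th["R:r12"], th["R:r22"]]])
        Kv = biv._kernels["G"]
        V = np.kron(C, Kv) + np.kron(R, np.eye(2))
        X = np.kron(np.eye(2), np.ones((2, 1)))
        y = np.concatenate([y1, y2])
        Vi = np.linalg.inv(V)
        mu = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - X @ mu
        cov_g1 = np.hstack([C[0, 0] * Kv, C[0, 1] * Kv])
        g1_hat = cov_g1 @ Vi @ resid
        np.testing.assert_allclose(biv.mu, mu, atol=1e-6)
        np.testing.assert_allclose(biv.ebv["combined"], g1_hat, atol=1e-6)

    def test_genetic_correlation_recovered_on_average(self):
        """Mean estimated genetic correlation over replicates lands near
        the simulated value (quick 8-replicate check)."""
        ests = []
        for s in range(8):
            n = 150
            G, g1, y1, y2 = bivariate_data(n, 30 + s)
            biv = fit_bivariate(make_means(y1, G.ids),
                                make_means(y2, G.ids, "PH"), G=G)
            th = biv.varcomps
            denom = np.sqrt(th["G:c11"] * th["G:c22"])
            if denom > 0:
                ests.append(th["G:c12"] / denom)
        assert abs(np.mean(ests) - 0.6) < 0.15

    def test_secondary_trait_helps_masked_prediction(self):
        """Masked genotypes keep their PH records; the bivariate model
        must beat random and use them (r above the G-only masked fit on
        average is checked in the acceptance suite; here: r finite)."""
        n = 80
        G, g1, y1, y2 = bivariate_data(n, 55)
        trn = G.ids[20:]
        biv = fit_bivariate(make_means(y1[20:], trn),
                            make_means(y2, G.ids, "PH"), G=G)
        pred = predict_validation(biv, G.ids[:20])
        r = np.corrcoef(pred, y1[:20])[0, 1]
        assert np.isfinite(r) and r > 0.2
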