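"""Variational inference for the G x E factorization model."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from gxepred.datamodel import SoilProfile, TrialTable
from gxepred.kbmf import (GxEFactorModel, Hyperparameters, ObservationMask,
                          compute_elbo)


def _random_kernel(n, seed, cols=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, cols or max(4, n // 2)))
    K = X @ X.T
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    return K / np.sqrt(np.sum(K.var(axis=0)))


def _dense_obs(Y, frac=1.0, seed=0):
    rng = np.random.default_rng(seed)
    mask = rng.random(Y.shape) < frac
    oi, oj = np.where(mask)
    return ObservationMask(oi, oj, Y[oi, oj], np.ones(len(oi)), *Y.shape), mask


class TestHyperparameters:
    def test_positive_validation(self):
        with pytest.raises(ValueError, match="lambda_g0"):
            Hyperparameters(lambda_g0=-1.0, sigma2_g0=0.02)
        with pytest.raises(ValueError, match="rank"):
            Hyperparameters(lambda_g0=1.0, sigma2_g0=0.02, R=-1)
        with pytest.raises(ValueError, match="sigma2_g"):
            Hyperparameters(lambda_g0=1.0, sigma2_g0=0.02, R=1, lambda_g=1.0,
                            lambda_e=1.0, sigma2_e=0.1)

    def test_calibrated_constructor_defaults(self):
        Kg = _random_kernel(40, 0)
        hyp = Hyperparameters.calibrated(Kg, R=0, var_genetic=0.4)
        assert hyp.sigma2_g0 == pytest.approx(0.02)
        assert hyp.alpha_j == 10.0 and hyp.beta_j == 1.0 and hyp.sigma2_e0 == 0.25


class TestObservationMask:
    def test_duplicate_cells_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ObservationMask([0, 0], [1, 1], [1.0, 2.0], [1, 1], 2, 2)

    def test_replicates_averaged_from_trials(self):
        d = pd.DataFrame({
            "line_id": ["a", "a", "b"], "location": ["A"] * 3,
            "year": [2010] * 3, "field_block": ["f"] * 3,
            "yield": [1.0, 3.0, 5.0]})
        obs = ObservationMask.from_trials(TrialTable(d), ["a", "b"], ["A:2010:f"])
        assert len(obs.values) == 2
        i = list(obs.geno_idx).index(0)
        assert obs.values[i] == 2.0 and obs.weights[i] == 2.0


class TestFit:
    def test_elbo_monotone_over_seeds(self):
        """Coordinate ascent must never decrease the ELBO (several seeds,
        with and without interaction terms)."""
        for seed in range(5):
            Kg = _random_kernel(30, seed)
            Ke = _random_kernel(8, seed + 50)
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((30, 8))
            obs, _ = _dense_obs(Y, 0.7, seed)
            for R in (0, 2):
                hyp = Hyperparameters.calibrated(Kg, Ke, R=R, var_genetic=0.4)
                fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=60, seed=seed)
                diffs = np.diff(fit.elbo_trace)
                assert diffs.min() > -1e-6 * np.abs(fit.elbo_trace[:-1]).max()

    def test_additive_recovery_rank_correlation(self):
        """R=0 on additive data recovers the genetic ordering (r_s > 0.9)."""
        Ng, Ne = 150, 12
        Kg = _random_kernel(Ng, 1, cols=60)
        Ke = _random_kernel(Ne, 2)
        rng = np.random.default_rng(3)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=0, var_genetic=0.6)
        g = Kg @ rng.normal(0, hyp.lambda_g0**-0.5, Ng)
        e = rng.normal(0, 0.5, Ne)
        Y = g[:, None] + e[None, :] + rng.normal(0, 0.3, (Ng, Ne))
        obs, _ = _dense_obs(Y, 1.0)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(seed=0)
        assert spearmanr(fit.genetic_effects, g).statistic > 0.9

    def test_single_cell_degenerate_input(self):
        Kg = _random_kernel(5, 0)
        Ke = _random_kernel(4, 1)
        obs = ObservationMask([2], [1], [0.7], [1.0], 5, 4)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=1, var_genetic=0.4)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=30, seed=0)
        assert np.isfinite(fit.elbo)
        assert np.isfinite(fit.genetic_effects).all()
        assert abs(fit.genetic_effects[2]) < abs(0.7)  # heavy shrinkage

    def test_permutation_equivariance(self):
        Kg = _random_kernel(20, 4)
        Ke = _random_kernel(6, 5)
        rng = np.random.default_rng(6)
        Y = rng.standard_normal((20, 6))
        obs, _ = _dense_obs(Y, 1.0)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=0, var_genetic=0.4)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=40, seed=0)
        p = rng.permutation(20)
        Kp = Kg[np.ix_(p, p)]
        obs_p, _ = _dense_obs(Y[p], 1.0)
        fit_p = GxEFactorModel(Kp, Ke, obs_p, hyp).fit(max_iter=40, seed=0)
        np.testing.assert_allclose(fit_p.genetic_effects, fit.genetic_effects[p],
                                   atol=1e-8)

    def test_elbo_decrease_raises(self, monkeypatch):
        """A corrupted update (wrong posterior moment) must trip the
        monotonicity guard rather than silently degrade."""
        import gxepred.kbmf as kbmf_mod
        Kg = _random_kernel(10, 7)
        Ke = _random_kernel(4, 8)
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((10, 4))
        obs, _ = _dense_obs(Y, 1.0)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=0, var_genetic=0.4)
        real = kbmf_mod.compute_elbo
        calls = {"n": 0}

        def corrupted(*args, **kwargs):
            calls["n"] += 1
            v = real(*args, **kwargs)
            return v - 10.0 * calls["n"]  # strictly decreasing sequence

        monkeypatch.setattr(kbmf_mod, "compute_elbo", corrupted)
        with pytest.raises(RuntimeError, match="ELBO decreased"):
            GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=10, seed=0)


class TestElboContract:
    def test_recomputed_elbo_equals_trace_tail(self):
        Kg = _random_kernel(15, 0)
        Ke = _random_kernel(5, 1)
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((15, 5))
        obs, _ = _dense_obs(Y, 0.8)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=1, var_genetic=0.4)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=40, seed=0)
        assert fit.compute_elbo() == pytest.approx(fit.elbo, abs=1e-8)

    def test_absurd_noise_prior_lowers_elbo_on_noisy_data(self):
        """Forcing near-zero residual variance on noisy data must lose to
        the calibrated noise prior in ELBO terms."""
        Kg = _random_kernel(25, 3)
        Ke = _random_kernel(6, 4)
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1.0, (25, 6))
        obs, _ = _dense_obs(Y, 1.0)
        good = Hyperparameters.calibrated(Kg, Ke, R=0, var_genetic=0.4)
        bad = Hyperparameters.calibrated(Kg, Ke, R=0, var_genetic=0.4,
                                         alpha_j=10_000.0, beta_j=0.001)
        f_good = GxEFactorModel(Kg, Ke, obs, good).fit(max_iter=50, seed=0)
        f_bad = GxEFactorModel(Kg, Ke, obs, bad).fit(max_iter=50, seed=0)
        assert f_bad.elbo < f_good.elbo


class TestGibbsOracle:
    def test_posterior_means_match_gibbs_on_tiny_instance(self):
        """Independent Gibbs sampler agrees with the variational posterior
        means on a 5 x 4 additive instance (update-equation validation)."""
        rng = np.random.default_rng(42)
        Ng, Ne = 5, 4
        Kg = _random_kernel(Ng, 10)
        Ke = np.eye(Ne)
        hyp = Hyperparameters(lambda_g0=2.0, sigma2_g0=0.02, R=0)
        g = Kg @ rng.normal(0, hyp.lambda_g0**-0.5, Ng)
        e = rng.normal(0, 0.5, Ne)
        Y = g[:, None] + e[None, :] + rng.normal(0, 0.3, (Ng, Ne))
        oi, oj = np.where(np.ones((Ng, Ne), bool))
        obs = ObservationMask(oi, oj, Y[oi, oj], np.ones(len(oi)), Ng, Ne)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=500, tol=1e-12, seed=0)

        r = np.random.default_rng(1)
        a0 = np.zeros(Ng)
        gg = Y.mean(axis=1).copy()
        ee = np.zeros(Ne)
        tau = np.full(Ne, 10.0)
        S_g = np.zeros(Ng)
        S_e = np.zeros(Ne)
        n_keep = 0
        I = np.eye(Ng)
        n_iter, burn = 8000, 2000
        for it in range(n_iter):
            for j in range(Ne):
                res = Y[:, j] - gg - ee[j]
                tau[j] = r.gamma(hyp.alpha_j + Ng / 2,
                                 1.0 / (hyp.beta_j + 0.5 * np.sum(res**2)))
            P = hyp.lambda_g0 * I + Kg @ Kg / hyp.sigma2_g0
            C = np.linalg.inv(P)
            a0 = r.multivariate_normal(C @ Kg @ gg / hyp.sigma2_g0, C)
            for i in range(Ng):
                prec = 1 / hyp.sigma2_g0 + np.sum(tau)
                m = ((Kg @ a0)[i] / hyp.sigma2_g0 + np.sum(tau * (Y[i, :] - ee))) / prec
                gg[i] = r.normal(m, prec**-0.5)
            for j in range(Ne):
                prec = 1 / hyp.sigma2_e0 + Ng * tau[j]
                m = tau[j] * np.sum(Y[:, j] - gg) / prec
                ee[j] = r.normal(m, prec**-0.5)
            if it >= burn:
                S_g += gg
                S_e += ee
                n_keep += 1
        assert np.abs(fit.genetic_effects - S_g / n_keep).max() < 0.05
        assert np.abs(fit.environment_effects - S_e / n_keep).max() < 0.05


class TestPredict:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        Kg = _random_kernel(25, 0)
        Ke = _random_kernel(8, 1)
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((25, 8))
        obs, _ = _dense_obs(Y, 0.9, seed=1)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=2, var_genetic=0.4)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=60, seed=0)
        return Kg, Ke, fit

    def test_zero_rows_predict_grand_mean(self, fitted):
        Kg, Ke, fit = fitted
        pred = fit.predict(np.zeros((1, 25)), np.zeros((1, 8)))
        assert pred[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_training_rows_reproduce_fitted_values(self, fitted):
        Kg, Ke, fit = fitted
        pred = fit.predict(Kg[3:4], Ke[5:6], env_index=[5])
        assert pred[0, 0] == pytest.approx(fit.fittedvalues[3, 5], abs=1e-10)

    def test_rank_zero_predictions_are_additive(self):
        Kg = _random_kernel(12, 2)
        Ke = _random_kernel(5, 3)
        rng = np.random.default_rng(4)
        Y = rng.standard_normal((12, 5))
        obs, _ = _dense_obs(Y, 1.0)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=0, var_genetic=0.4)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=30, seed=0)
        pred = fit.predict(Kg[:4], Ke[:3], env_index=[0, 1, 2])
        diff = pred[0] - pred[1]
        assert np.ptp(diff) < 1e-12  # column differences independent of env

    def test_dimension_mismatch_raises(self, fitted):
        _, _, fit = fitted
        with pytest.raises(ValueError, match="kg_rows"):
            fit.predict(np.zeros((1, 7)))


class TestHistoricalPrediction:
    def _setup(self, small_dataset, small_builders):
        from gxepred.datamodel import ztransform_yields
        gkb, builder, Ke = small_builders
        tz = ztransform_yields(small_dataset.trials)
        hyp = Hyperparameters.calibrated(gkb.kernel, Ke, R=1, var_genetic=0.4)
        fit = GxEFactorModel.from_trials(tz, gkb.kernel, Ke, hyp).fit(
            max_iter=40, seed=0)
        return gkb, builder, fit

    def test_median_protocol(self, small_dataset, small_builders):
        gkb, builder, fit = self._setup(small_dataset, small_builders)
        kg_rows = gkb.kernel.matrix[:5]
        loc = sorted({l for l, _ in small_dataset.weather})[0]
        hist = [ws for (l, _), ws in sorted(small_dataset.weather.items()) if l == loc]
        soil = small_dataset.soils[f"{loc}-F0"]
        zone = small_dataset.zones[loc]

        per_year = []
        from gxepred.datamodel import extract_season
        from gxepred.kbmf import builder_blocks_single
        for ws in hist:
            blocks = builder_blocks_single(builder, extract_season(ws), soil, zone)
            per_year.append(fit.predict(kg_rows, builder.composite_rows(blocks))[:, 0])
        per_year = np.stack(per_year, axis=1)

        med = fit.predict_historical(kg_rows, hist, soil, builder, zone=zone)
        np.testing.assert_allclose(med, np.median(per_year, axis=1), atol=1e-12)
        # bounded by per-year extremes
        assert (med >= per_year.min(axis=1) - 1e-12).all()
        assert (med <= per_year.max(axis=1) + 1e-12).all()

    def test_single_and_identical_years(self, small_dataset, small_builders):
        gkb, builder, fit = self._setup(small_dataset, small_builders)
        kg_rows = gkb.kernel.matrix[:3]
        loc = sorted({l for l, _ in small_dataset.weather})[0]
        ws = small_dataset.weather[(loc, 2010)]
        soil = small_dataset.soils[f"{loc}-F0"]
        one = fit.predict_historical(kg_rows, [ws], soil, builder)
        three = fit.predict_historical(kg_rows, [ws, ws, ws], soil, builder)
        np.testing.assert_allclose(one, three, atol=1e-12)

    def test_no_years_is_error(self, small_dataset, small_builders):
        gkb, builder, fit = self._setup(small_dataset, small_builders)
        with pytest.raises(ValueError, match="historical"):
            fit.predict_historical(gkb.kernel.matrix[:1], [],
                                   small_dataset.soils["L00-F0"], builder)


class TestSerialization:
    def test_fit_archive_roundtrip(self, tmp_path):
        Kg = _random_kernel(10, 0)
        Ke = _random_kernel(4, 1)
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((10, 4))
        obs, _ = _dense_obs(Y, 1.0)
        hyp = Hyperparameters.calibrated(Kg, Ke, R=1, var_genetic=0.2)
        fit = GxEFactorModel(Kg, Ke, obs, hyp).fit(max_iter=20, seed=0)
        fit.save(tmp_path / "fit.npz")
        arch = np.load(tmp_path / "fit.npz")
        np.testing.assert_allclose(arch["mu_g"], fit.genetic_effects)
        assert "elbo_trace" in arch and "mu_Hg" in arch
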