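"""Crop-stage estimation and the GBLUP / GE-BLUP mixed models."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from gxepred.baselines import (GBLUP, GEBLUP, CropStageConfig,
                               GEBlupCovariateBuilder, estimate_crop_stages,
                               _reml_single_kernel)
from gxepred.datamodel import SoilProfile, TrialTable
from gxepred.kernels import Kernel


class TestCropStages:
    def test_constant_twenty_degrees_hand_accumulation(self):
        # cumulative sum crosses 440.2 on day 23 (460) and 905.9 on day 46 (920)
        stages = estimate_crop_stages(np.full(80, 20.0))
        assert stages.heading_day == 23
        assert stages.ripening_day == 46
        assert stages.vegetative == (1, 21)
        assert stages.heading == (23 - 14, 23 + 7)
        assert stages.grain_filling == (23 + 7 + 1, 46 + 7)

    def test_single_extreme_day(self):
        stages = estimate_crop_stages(np.array([905.9, 1.0, 1.0]))
        assert stages.heading_day == 1 and stages.ripening_day == 1
        assert stages.heading[0] == 1  # clipped at sowing
        assert stages.grain_filling[0] > stages.heading[1]

    def test_threshold_unreachable_names_threshold(self):
        with pytest.raises(ValueError, match="440.2"):
            estimate_crop_stages(np.zeros(200))
        with pytest.raises(ValueError, match="905.9"):
            estimate_crop_stages(np.full(30, 20.0))

    def test_base_temperature_config(self):
        cfg = CropStageConfig(base_temperature=5.0)
        stages = estimate_crop_stages(np.full(100, 20.0), cfg)
        # effective 15 deg/day: 440.2/15 -> day 30
        assert stages.heading_day == 30

    def test_warming_never_delays_heading(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.uniform(5, 25, 120)
            warmer = t + rng.uniform(0, 3, 120)
            a = estimate_crop_stages(t).heading_day
            b = estimate_crop_stages(warmer).heading_day
            assert b <= a

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="heading_sum"):
            CropStageConfig(heading_sum=1000.0, ripening_sum=900.0)


class TestCovariateBuilder:
    def test_covariate_count_with_four_zones(self):
        cb = GEBlupCovariateBuilder()
        weather = np.column_stack([np.full(120, 20.0), np.full(120, 2.0)])
        soil = SoilProfile("f", 0.3, 0.3, 0.4, 0.1)
        v = cb.environment_vector(weather, soil, np.array([1.0, 0, 0, 0]))
        assert v.shape == (12 + 4 + 4,)

    def test_constant_weather_gives_zero_sds(self):
        cb = GEBlupCovariateBuilder()
        weather = np.column_stack([np.full(120, 20.0), np.full(120, 2.0)])
        soil = SoilProfile("f", 0.3, 0.3, 0.4, 0.1)
        v = cb.environment_vector(weather, soil, np.array([1.0]))
        sds = v[1:12:2]  # the per-stage sd entries
        np.testing.assert_allclose(sds, 0.0, atol=1e-12)

    def test_window_outside_coverage_raises(self):
        cb = GEBlupCovariateBuilder()
        weather = np.column_stack([np.full(47, 20.0), np.zeros(47)])
        soil = SoilProfile("f", 0.3, 0.3, 0.4, 0.1)
        with pytest.raises(ValueError, match="coverage"):
            cb.environment_vector(weather, soil, np.array([1.0]))

    def test_identical_environments_unit_similarity(self):
        cb = GEBlupCovariateBuilder()
        weather = np.column_stack([np.linspace(10, 22, 120), np.full(120, 2.0)])
        soil = SoilProfile("f", 0.3, 0.3, 0.4, 0.1)
        v = cb.environment_vector(weather, soil, np.array([1.0, 0.0]))
        v2 = cb.environment_vector(weather * 1.1, soil, np.array([0.0, 1.0]))
        cb.fit(np.stack([v, v, v2]), ["e0", "e1", "e2"])
        assert cb.kernel.matrix[0, 1] == pytest.approx(1.0, abs=1e-10)


def _trial_frame(lines, envs, yields):
    rows = []
    for (l, env), y in zip([(l, e) for e in envs for l in lines], yields):
        loc, yr, fb = env.split(":")
        rows.append((l, loc, int(yr), fb, y))
    return TrialTable(pd.DataFrame(
        rows, columns=["line_id", "location", "year", "field_block", "yield"]))


def _make_gblup_instance(n_lines=20, n_envs=3, seed=0, h2=0.6):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_lines, 30))
    K = X @ X.T / 30
    lines = [f"l{i}" for i in range(n_lines)]
    envs = [f"A:201{j}:f" for j in range(n_envs)]
    u = rng.multivariate_normal(np.zeros(n_lines), h2 * K)
    yields = []
    for e in range(n_envs):
        yields.extend(u + rng.normal(0, np.sqrt(1 - h2), n_lines) + 0.3 * e)
    trials = _trial_frame(lines, envs, yields)
    return trials, Kernel(K, lines, "genomic"), u


class TestGBLUP:
    def test_blup_matches_direct_mixed_model_equations(self):
        """With the variance ratio fixed at the REML estimate, the BLUP must
        equal the closed-form solve u = s2u K Z' V^-1 (y - X beta)."""
        trials, Kg, _ = _make_gblup_instance()
        model = GBLUP(trials, Kg, fixed="env")
        res = model.fit()
        Z, X, y = model.Z, model.X, model.y
        V = res.sigma2_u * Z @ Kg.matrix @ Z.T + res.sigma2_e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u_direct = res.sigma2_u * Kg.matrix @ Z.T @ Vi @ (y - X @ beta)
        np.testing.assert_allclose(res.blup, u_direct, atol=1e-8)
        np.testing.assert_allclose(res.beta, beta, atol=1e-8)

    def test_reml_matches_generic_optimizer(self):
        """The spectral REML solution agrees with brute-force optimization
        of the profiled restricted likelihood to 1e-4."""
        trials, Kg, _ = _make_gblup_instance(seed=1)
        model = GBLUP(trials, Kg, fixed="env")
        res = model.fit()
        ZKZ = model.Z @ Kg.matrix @ model.Z.T
        y, X = model.y, model.X
        n, p = X.shape

        def neg_reml(log_delta):
            d = np.exp(log_delta)
            V = ZKZ + d * np.eye(n)
            Vi = np.linalg.inv(V)
            P = Vi - Vi @ X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
            ss = float(y @ P @ y)
            sl = np.linalg.slogdet(V)[1] + np.linalg.slogdet(X.T @ Vi @ X)[1]
            return 0.5 * ((n - p) * np.log(ss) + sl)

        opt = minimize_scalar(neg_reml, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        delta_opt = np.exp(opt.x)
        assert res.sigma2_e / res.sigma2_u == pytest.approx(delta_opt, rel=1e-4)

    def test_identity_kernel_shrinks_residual_means(self):
        trials, Kg, _ = _make_gblup_instance(n_envs=1)
        eye = Kernel(np.eye(Kg.n), Kg.ids, "identity")
        res = GBLUP(trials, eye, fixed="intercept").fit()
        y = trials.data["yield"].to_numpy()
        resid = y - y.mean()
        shrink = res.sigma2_u / (res.sigma2_u + res.sigma2_e)
        np.testing.assert_allclose(res.blup, shrink * resid, atol=1e-6)

    def test_duplicated_lines_identical_blups(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 20))
        X[5] = X[4]  # duplicate genotype
        K = X @ X.T / 20
        lines = [f"l{i}" for i in range(10)]
        trials = _trial_frame(lines, ["A:2010:f"], list(rng.standard_normal(10)))
        res = GBLUP(trials, Kernel(K, lines, "g"), fixed="intercept").fit()
        # same kernel rows -> same BLUP regardless of own phenotype
        assert res.blup[4] == pytest.approx(res.blup[5], abs=1e-8)

    def test_unknown_line_rejected(self):
        trials, Kg, _ = _make_gblup_instance(n_lines=5, n_envs=1)
        with pytest.raises(ValueError, match="cover"):
            GBLUP(trials, Kernel(Kg.matrix[:4, :4], Kg.ids[:4], "g"))

    def test_prediction_for_new_lines_via_kernel_rows(self):
        trials, Kg, u = _make_gblup_instance(n_lines=40, n_envs=4, seed=3)
        # train on 30 lines, predict the 10 held-out ones
        train_lines = set(list(Kg.ids)[:30])
        mask = trials.data["line_id"].isin(train_lines).to_numpy()
        sub = trials.subset(mask)
        Kt = Kernel(Kg.matrix[:30, :30], Kg.ids[:30], "g")
        res = GBLUP(sub, Kt, fixed="env").fit()
        pred = res.predict_units(Kg.matrix[30:, :30])
        assert np.corrcoef(pred, u[30:])[0, 1] > 0.5


class TestGEBLUP:
    def test_single_environment_identity_reduces_to_gblup(self):
        trials, Kg, _ = _make_gblup_instance(n_envs=1, seed=4)
        Ke = Kernel(np.eye(1), ["A:2010:f"], "env")
        ge = GEBLUP(trials, Kg, Ke, fixed="intercept").fit()
        gb = GBLUP(trials, Kg, fixed="intercept").fit()
        # identical covariance structure -> identical variance components
        assert ge.sigma2_u == pytest.approx(gb.sigma2_u, rel=1e-6)
        assert ge.sigma2_e == pytest.approx(gb.sigma2_e, rel=1e-6)

    def test_double_identity_gives_independent_cells(self):
        trials, Kg, _ = _make_gblup_instance(n_envs=2, seed=5)
        lines = list(Kg.ids)
        envs = sorted(trials.data["env"].unique())
        ge = GEBLUP(trials, Kernel(np.eye(len(lines)), lines, "i"),
                    Kernel(np.eye(2), envs, "i"), fixed="env").fit()
        # unseen cells have zero cross-covariance -> prediction 0 (fixed only)
        pred = ge.predict_cells(np.zeros((1, len(lines))), np.zeros((1, 2)))
        assert pred[0] == pytest.approx(0.0, abs=1e-12)

    def test_restricted_cells_equal_dense_kronecker(self):
        """The observed-cell covariance assembled entrywise must equal the
        corresponding submatrix of the dense Kronecker product."""
        trials, Kg, _ = _make_gblup_instance(n_lines=6, n_envs=2, seed=6)
        lines = list(Kg.ids)
        envs = sorted(trials.data["env"].unique())
        rng = np.random.default_rng(7)
        E = rng.standard_normal((2, 2))
        KeM = E @ E.T + np.eye(2)
        d = np.sqrt(np.diag(KeM))
        KeM = KeM / np.outer(d, d)
        Ke = Kernel(KeM, envs, "env")
        m = GEBLUP(trials, Kg, Ke, fixed="env")
        C_oo = m._cell_cov(m.cell_g, m.cell_e, m.cell_g, m.cell_e)
        dense = np.kron(Kg.matrix, KeM)
        flat = m.cell_g * 2 + m.cell_e
        np.testing.assert_allclose(C_oo, dense[np.ix_(flat, flat)], atol=1e-12)

    def test_structured_environment_beats_gblup_on_held_out_cells(self):
        """10 lines x 4 environments with strong environmental kinship
        structure: GE-BLUP outranks GBLUP in held-out correlation."""
        rng = np.random.default_rng(8)
        n, ne = 10, 4
        X = rng.standard_normal((n, 15))
        K = X @ X.T / 15
        lines = [f"l{i}" for i in range(n)]
        envs = [f"A:201{j}:f" for j in range(ne)]
        # environment kinship: two pairs of near-identical environments
        KeM = np.array([[1, .95, .1, .1], [.95, 1, .1, .1],
                        [.1, .1, 1, .95], [.1, .1, .95, 1]])
        u = rng.multivariate_normal(np.zeros(n * ne), np.kron(K, KeM)).reshape(n, ne)
        Y = u + rng.normal(0, 0.3, (n, ne))
        held = [(i, j) for i in range(n) for j in range(ne) if (i + j) % 5 == 0]
        rows = []
        for i in range(n):
            for j in range(ne):
                if (i, j) in held:
                    continue
                loc, yr, fb = envs[j].split(":")
                rows.append((lines[i], loc, int(yr), fb, Y[i, j]))
        trials = TrialTable(pd.DataFrame(
            rows, columns=["line_id", "location", "year", "field_block", "yield"]))
        Kgk = Kernel(K, lines, "g")
        Kek = Kernel(KeM, envs, "e")
        ge = GEBLUP(trials, Kgk, Kek, fixed="intercept").fit()
        gb = GBLUP(trials, Kgk, fixed="intercept").fit()
        gi = np.array([i for i, j in held])
        ei = np.array([j for i, j in held])
        pred_ge = ge.predict_cells(K[gi], KeM[ei])
        pred_gb = gb.predict_units(K[gi])
        truth = np.array([Y[i, j] for i, j in held])
        r_ge = np.corrcoef(pred_ge, truth)[0, 1]
        r_gb = np.corrcoef(pred_gb, truth)[0, 1]
        assert r_ge > r_gb

    def test_memory_guard(self):
        trials, Kg, _ = _make_gblup_instance(n_lines=20, n_envs=3)
        Ke = Kernel(np.eye(3), sorted(trials.data["env"].unique()), "e")
        old = GEBLUP.MAX_CELLS
        try:
            GEBLUP.MAX_CELLS = 10
            with pytest.raises(MemoryError, match="guard"):
                GEBLUP(trials, Kg, Ke)
        finally:
            GEBLUP.MAX_CELLS = old


class TestREMLCore:
    def test_rank_deficient_fixed_design_rejected(self):
        y = np.arange(6.0)
        X = np.ones((6, 2))  # duplicated column
        with pytest.raises(ValueError, match="identifiable"):
            _reml_single_kernel(y, X, np.eye(6))
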