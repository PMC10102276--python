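import numpy as np
import pandas as pd
import pytest

import ippm.ppm_lasso as ppm
from ippm.io_core import GridSpec, PointTable, Raster
from ippm.covariates import LayerSet


def _grid(n=10, d=1.0, years=(0, 0)):
    return GridSpec(0.0, n * d, d, d, n, n, years=years)


def _presences(grid, n, seed=0, year=0):
    rng = np.random.default_rng(seed)
    return PointTable(pd.DataFrame({
        "x": grid.x0 + rng.random(n) * (grid.x1 - grid.x0),
        "y": grid.y1 + rng.random(n) * (grid.y0 - grid.y1),
        "year": year, "stream": "nest"}), grid=grid)


class TestBuildQuadrature:
    def test_uniform_weight_construction(self):
        grid = _grid(10)  # |A| = 100
        pres = _presences(grid, 50)
        s = ppm.build_quadrature(grid, 1000, seed=0, presences=pres)
        np.testing.assert_allclose(s.w, 100.0 / 1050)
        assert s.w.sum() == pytest.approx(100.0)
        assert s.n_presence == 50

    def test_two_years_weight_sums(self):
        grid = _grid(10, years=(2000, 2001))
        s = ppm.build_quadrature(grid, 1000, seed=1)
        for yr in (2000, 2001):
            assert s.w[s.year == yr].sum() == pytest.approx(grid.area)

    def test_seed_determinism(self):
        grid = _grid(10)
        a = ppm.build_quadrature(grid, 500, seed=7)
        b = ppm.build_quadrature(grid, 500, seed=7)
        np.testing.assert_array_equal(a.x, b.x)

    def test_epsilon_mode_conserves_area(self):
        grid = _grid(10)
        pres = _presences(grid, 50)
        s = ppm.build_quadrature(grid, 1000, presences=pres,
                                 presence_weight="epsilon")
        assert s.w.sum() == pytest.approx(grid.area, rel=1e-6)
        assert np.all(s.w[s.z == 1] < 1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            ppm.build_quadrature(_grid(5), 10)


class TestDwprFit:
    def test_homogeneous_intercept_closed_form(self):
        # n = 50 presences on |A| = 100 -> intercept = log(0.5)
        grid = _grid(10)
        pres = _presences(grid, 50, seed=3)
        s = ppm.build_quadrature(grid, 5000, seed=3, presences=pres)
        fit = ppm.dwpr_fit(np.empty((len(s), 0)), s)
        assert fit.intercept == pytest.approx(np.log(50 / 100.0), abs=1e-9)

    def test_constant_zero_covariate(self):
        grid = _grid(10)
        pres = _presences(grid, 50, seed=4)
        s = ppm.build_quadrature(grid, 2000, seed=4, presences=pres)
        X = np.zeros((len(s), 1))
        fit = ppm.dwpr_fit(X, s)
        assert fit.coef[0] == 0.0
        assert fit.intercept == pytest.approx(np.log(0.5), abs=1e-8)

    def test_huge_penalty_zeroes_slopes(self):
        grid = _grid(10)
        pres = _presences(grid, 80, seed=5)
        s = ppm.build_quadrature(grid, 2000, seed=5, presences=pres)
        rng = np.random.default_rng(5)
        X = rng.standard_normal((len(s), 3))
        fit = ppm.dwpr_fit(X, s, penalty=1e9)
        np.testing.assert_array_equal(fit.coef, 0.0)

    def test_lambda_max_zeroes_all_slopes(self):
        grid = _grid(10)
        pres = _presences(grid, 60, seed=6)
        s = ppm.build_quadrature(grid, 1500, seed=6, presences=pres)
        rng = np.random.default_rng(6)
        X = rng.standard_normal((len(s), 4))
        lmax = ppm.lambda_max(X, s)
        fit = ppm.dwpr_fit(X, s, penalty=lmax * (1 + 1e-9))
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-10)
        fit2 = ppm.dwpr_fit(X, s, penalty=lmax * 0.5)
        assert np.any(fit2.coef != 0.0)

    def test_matches_statsmodels_glm_oracle(self):
        # penalty 0 must equal the weighted Poisson GLM solution
        import statsmodels.api as sm

        grid = _grid(10)
        pres = _presences(grid, 100, seed=7)
        s = ppm.build_quadrature(grid, 1000, seed=7, presences=pres)
        rng = np.random.default_rng(7)
        X = rng.standard_normal((len(s), 2))
        fit = ppm.dwpr_fit(X, s, penalty=0.0)
        y = s.z / s.w
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson(),
                     var_weights=s.w).fit()
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef], glm.params, atol=1e-6)

    def test_misaligned_design_errors(self):
        grid = _grid(5)
        s = ppm.build_quadrature(grid, 200, seed=1)
        with pytest.raises(ValueError, match="align"):
            ppm.dwpr_fit(np.zeros((3, 1)), s)

    def test_coefficient_recovery_from_known_truth(self):
        # inhomogeneous process on a covariate surface; beta recovered
        grid = _grid(32, d=1.0)
        X_sfc, Y_sfc = grid.cell_centers()
        cov_vals = np.sin(X_sfc / 5.0) + 0.3 * (Y_sfc / 32.0)
        beta_true, b0_true = 0.8, np.log(3.0)
        rng = np.random.default_rng(8)
        lam = np.exp(b0_true + beta_true * cov_vals) * grid.cell_area
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(grid.n_cells), counts.ravel())
        i, j = idx % 32, idx // 32
        pres = PointTable(pd.DataFrame({
            "x": grid.x0 + (i + rng.random(len(i))) * grid.dx,
            "y": grid.y0 - (j + rng.random(len(j))) * grid.dy,
            "year": 0, "stream": "nest"}), grid=grid)
        assert len(pres) > 2000
        s = ppm.build_quadrature(grid, 20 * len(pres), seed=8, presences=pres,
                                 presence_weight="epsilon")
        ii, jj = grid.cell_of(s.x, s.y)
        ii = np.clip(ii, 0, 31); jj = np.clip(jj, 0, 31)
        Xd = cov_vals[jj, ii][:, None]
        fit = ppm.dwpr_fit(Xd, s)
        # asymptotic SE from the weighted information matrix
        v = s.w * np.exp(fit.intercept + Xd[:, 0] * fit.coef[0])
        info = np.array([[v.sum(), (v * Xd[:, 0]).sum()],
                         [(v * Xd[:, 0]).sum(), (v * Xd[:, 0] ** 2).sum()]])
        se_beta = np.sqrt(np.linalg.inv(info)[1, 1])
        assert abs(fit.coef[0] - beta_true) < 3 * se_beta

    def test_quadrature_refinement_stability(self):
        # doubling m changes the coefficient by < 0.5 %
        grid = _grid(24, d=1.0)
        X_sfc, _ = grid.cell_centers()
        cov_vals = X_sfc / 24.0
        rng = np.random.default_rng(9)
        lam = np.exp(np.log(4.0) + 1.0 * cov_vals) * grid.cell_area
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(grid.n_cells), counts.ravel())
        i, j = idx % 24, idx // 24
        pres = PointTable(pd.DataFrame({
            "x": grid.x0 + (i + rng.random(len(i))) * grid.dx,
            "y": grid.y0 - (j + rng.random(len(j))) * grid.dy,
            "year": 0, "stream": "nest"}), grid=grid)
        coefs = []
        for m in (20_000, 40_000):
            s = ppm.build_quadrature(grid, m, seed=10, presences=pres,
                                     presence_weight="epsilon",
                                     method="stratified")
            ii, jj = grid.cell_of(s.x, s.y)
            ii = np.clip(ii, 0, 23); jj = np.clip(jj, 0, 23)
            fit = ppm.dwpr_fit(cov_vals[jj, ii][:, None], s)
            coefs.append(fit.coef[0])
        assert abs(coefs[1] - coefs[0]) / abs(coefs[0]) < 0.005


def _layer_world(grid, seed=0, gen_scale="r90"):
    """Layers where the truth acts at a specific smoothing scale."""
    from ippm import covariates as cov
    from ippm import random_field as rf

    op = rf.spatial_precision(grid, rho=4 * grid.dx, sigma=1.0)
    base = Raster(grid, op.sample(np.random.default_rng(seed)).reshape(
        grid.ny, grid.nx))
    truth_layer = cov.moving_window(base, gen_scale)
    return LayerSet({"noisy": base}), truth_layer


class TestSelectScale:
    def test_recovers_generating_scale(self):
        from ippm import covariates as covm

        grid = _grid(32, d=30.0)
        hits = 0
        for seed in range(6):
            layers, truth_layer = _layer_world(grid, seed=seed)
            rng = np.random.default_rng(seed + 100)
            vals = truth_layer.values
            lam = np.exp(np.log(2.0) + 1.2 * (vals - vals.mean()) / vals.std())
            lam = lam / lam.mean() * 2.0  # ~2 points per cell
            counts = rng.poisson(lam)
            idx = np.repeat(np.arange(grid.n_cells), counts.ravel())
            i, j = idx % 32, idx // 32
            pres = PointTable(pd.DataFrame({
                "x": grid.x0 + (i + 0.5) * grid.dx,
                "y": grid.y0 - (j + 0.5) * grid.dy,
                "year": 0, "stream": "nest"}), grid=grid)
            s = ppm.build_quadrature(grid, 4000, seed=seed, presences=pres)
            best, _ = ppm.select_scale("noisy", ["pixel30", "r90", "r750"], s,
                                       layers, folds=5, seed=seed)
            hits += best == "r90"
        assert hits >= 4

    def test_single_candidate(self, small_world):
        truth = small_world["truth"]
        grid = truth.grid
        pres = small_world["points"].stream("nest")
        s = ppm.build_quadrature(grid, 500, seed=0, presences=pres)
        best, table = ppm.select_scale("slope", ["r150"], s,
                                       small_world["layers"], folds=4, seed=0)
        assert best == "r150"
        assert len(table) == 1

    def test_identical_layers_tie_to_smaller_scale(self):
        grid = _grid(16, d=30.0)
        const = Raster(grid, np.tile(np.linspace(0, 1, 16), (16, 1)))
        # constant-in-window layer: all scales give identical columns
        layers = LayerSet({"flat": Raster(grid, np.zeros((16, 16)) + const.values * 0
                                          + np.linspace(0, 1, 256).reshape(16, 16) * 0
                                          + 1.0)})
        # a constant layer cannot be standardized -> use unstandardized path
        pres = _presences(grid, 40, seed=2)
        s = ppm.build_quadrature(grid, 500, seed=2, presences=pres)
        best, _ = ppm.select_scale("flat", ["pixel30", "r90"], s, layers,
                                   folds=4, seed=2)
        assert best == "pixel30"


class TestLassoCV:
    def _noise_world(self, seed, n_target=2000):
        grid = _grid(24, d=1.0)
        rng = np.random.default_rng(seed)
        X_sfc, Y_sfc = grid.cell_centers()
        strong = np.sin(X_sfc / 4.0) * np.cos(Y_sfc / 5.0)
        lam = np.exp(1.3 * strong)
        lam *= n_target / lam.sum()
        counts = rng.poisson(lam)
        idx = np.repeat(np.arange(grid.n_cells), counts.ravel())
        i, j = idx % 24, idx // 24
        pres = PointTable(pd.DataFrame({
            "x": grid.x0 + (i + rng.random(len(i))) * grid.dx,
            "y": grid.y0 - (j + rng.random(len(j))) * grid.dy,
            "year": 0, "stream": "nest"}), grid=grid)
        s = ppm.build_quadrature(grid, 4000, seed=seed, presences=pres)
        ii, jj = grid.cell_of(s.x, s.y)
        ii = np.clip(ii, 0, 23); jj = np.clip(jj, 0, 23)
        cols = {"strong": strong[jj, ii]}
        for k in range(5):
            cols[f"noise{k}"] = rng.standard_normal(len(s))
        X = pd.DataFrame(cols)
        X = (X - X.mean()) / X.std(ddof=1)
        return X, s

    def test_head_of_path_all_zero(self):
        X, s = self._noise_world(0)
        lmax = ppm.lambda_max(X, s)
        fit = ppm.dwpr_fit(X.to_numpy(), s, penalty=lmax)
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-9)

    def test_noise_zeroed_majority_of_seeds(self):
        wins = 0
        for seed in range(5):
            X, s = self._noise_world(seed)
            fit = ppm.lasso_cv(X, s, folds=5, seed=seed, n_penalties=25)
            nz = set(fit.nonzero)
            if "strong" in nz and not any(c.startswith("noise") for c in nz):
                wins += 1
        assert wins >= 4

    def test_loo_equals_brute_force(self):
        grid = _grid(6, d=1.0)
        pres = _presences(grid, 5, seed=11)
        s = ppm.build_quadrature(grid, 100, seed=11, presences=pres)
        rng = np.random.default_rng(11)
        X = pd.DataFrame({"a": rng.standard_normal(len(s))})
        n = len(s)
        fit = ppm.lasso_cv(X, s, folds=n, seed=11, n_penalties=5)
        # brute-force LOO at the selected penalty
        from ippm.ppm_lasso import _make_folds, presence_score

        lab = _make_folds(s, n, 11)
        errs = []
        for f in range(n):
            tr = lab != f
            sub = ppm.dwpr_fit(X.to_numpy()[tr], s.subset(tr),
                               penalty=fit.penalty)
            te = lab == f
            p_hat = presence_score(sub.linpred(X.to_numpy()[te]), s.subset(te))
            errs.append(np.sqrt(np.mean((s.z[te] - p_hat) ** 2)))
        assert fit.cv_rmse is not None
        row = fit.path[np.isclose(fit.path["penalty"], fit.penalty)]
        assert row["cv_rmse"].iloc[0] == pytest.approx(np.mean(errs), abs=1e-10)


class TestCompareModels:
    def test_duplicate_candidates_identical(self):
        grid = _grid(12, d=1.0)
        pres = _presences(grid, 60, seed=12)
        s = ppm.build_quadrature(grid, 800, seed=12, presences=pres)
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"a": rng.standard_normal(len(s))})
        t = ppm.compare_models({"m1": X, "m2": X.copy()}, s, folds=4, seed=12,
                               n_penalties=8)
        assert t.loc[0, "rmse"] == pytest.approx(t.loc[1, "rmse"], abs=1e-12)

    def test_needs_two_candidates(self):
        grid = _grid(6)
        s = ppm.build_quadrature(grid, 200, seed=0)
        with pytest.raises(ValueError):
            ppm.compare_models({"only": pd.DataFrame({"a": np.zeros(len(s))})},
                               s, folds=3)

    def test_true_form_beats_wrong_form(self):
        # truth uses the saturating distance kernel; candidates: kernel vs raw
        from ippm import covariates as covm

        wins = 0
        for seed in range(5):
            grid = _grid(24, d=30.0)
            rng = np.random.default_rng(seed + 40)
            mask = np.zeros((24, 24))
            mask[rng.integers(0, 24, 3), rng.integers(0, 24, 3)] = 1
            d = covm.distance_to(Raster(grid, mask), grid)
            # small mu -> the kernel saturates: steep near features, flat far
            kern = covm.exp_distance(d, 0.15 * float(d.values.mean()))
            v = kern.values
            lam = np.exp(-3.0 * (v - v.mean()) / v.std(ddof=1))
            lam *= 1200 / lam.sum()
            counts = rng.poisson(lam)
            idx = np.repeat(np.arange(grid.n_cells), counts.ravel())
            i, j = idx % 24, idx // 24
            pres = PointTable(pd.DataFrame({
                "x": grid.x0 + (i + rng.random(len(i))) * grid.dx,
                "y": grid.y0 - (j + rng.random(len(j))) * grid.dy,
                "year": 0, "stream": "nest"}), grid=grid)
            s = ppm.build_quadrature(grid, 3000, seed=seed, presences=pres)
            ii, jj = grid.cell_of(s.x, s.y)
            ii = np.clip(ii, 0, 23); jj = np.clip(jj, 0, 23)
            cand = {}
            for name, ras in (("exp_kernel", kern), ("raw_distance", d)):
                col = ras.values[jj, ii]
                cand[name] = pd.DataFrame(
                    {name: (col - col.mean()) / col.std(ddof=1)})
            t = ppm.compare_models(cand, s, folds=5, seed=seed, n_penalties=8)
            wins += t.loc[0, "model"] == "exp_kernel"
        assert wins >= 4
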