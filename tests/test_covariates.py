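import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import LineString, Point

import ippm.covariates as cov
from ippm.io_core import GridSpec, PointTable, Raster


def _grid(n=5, d=30.0):
    return GridSpec(0.0, n * d, d, d, n, n)


def _ebird_row(x=10.0, y=10.0, year=2000, dist=1.0, dur=1.0, obs=2,
               time="08:00", complete=True):
    return {"x": x, "y": y, "year": year, "stream": "ebird",
            "effort_distance": dist, "effort_duration": dur,
            "n_observers": obs, "start_time": time, "complete": complete}


class TestFilterChecklists:
    def _table(self, rows):
        return PointTable(pd.DataFrame(rows))

    @pytest.mark.parametrize("field,value,kept", [
        ("dist", 6.0, False), ("dist", 4.9, True), ("dist", 5.0, False),
        ("dur", 5.0, False), ("dur", 4.9, True),
        ("obs", 10, True), ("obs", 11, False),
        ("time", "04:30", False), ("time", "05:00", True),
        ("time", "21:00", True), ("time", "21:01", False),
    ])
    def test_boundaries(self, field, value, kept):
        kw = {{"dist": "dist", "dur": "dur", "obs": "obs", "time": "time"}[field]: value}
        t = self._table([_ebird_row(**kw)])
        out = cov.filter_checklists(t)
        assert (len(out) == 1) == kept

    def test_incomplete_checklists_kept(self):
        out = cov.filter_checklists(self._table([_ebird_row(complete=False)]))
        assert len(out) == 1

    def test_nest_rows_untouched(self):
        rows = [{"x": 0.0, "y": 0.0, "year": 2000, "stream": "nest"},
                _ebird_row(dist=9.0)]
        out = cov.filter_checklists(self._table(rows))
        assert list(out.df["stream"]) == ["nest"]

    def test_missing_effort_dropped(self):
        df = pd.DataFrame([_ebird_row()])
        df.loc[0, "start_time"] = np.nan
        out = cov.filter_checklists(PointTable(df))
        assert len(out) == 0

    def test_idempotent_and_subset(self):
        rows = [_ebird_row(dist=d) for d in (0.5, 3.0, 5.5, 7.0)]
        t = self._table(rows)
        once = cov.filter_checklists(t)
        twice = cov.filter_checklists(once)
        assert len(once) == 2
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestDswe:
    def _seq(self, codes):
        g = _grid(1)
        return [Raster(g, np.array([[c]], dtype=float)) for c in codes]

    def test_any_high_confidence_water(self):
        assert cov.reclassify_dswe(self._seq([0, 2, 1])).values[0, 0] == 1.0

    def test_partial_water_codes_do_not_count(self):
        assert cov.reclassify_dswe(self._seq([3, 4, 2])).values[0, 0] == 0.0

    def test_all_missing_stays_missing(self):
        g = _grid(1)
        seq = [Raster(g, np.array([[np.nan]]))] * 3
        assert np.isnan(cov.reclassify_dswe(seq).values[0, 0])

    def test_out_of_range_code(self):
        with pytest.raises(ValueError, match="DSWE"):
            cov.reclassify_dswe(self._seq([5]))


class TestMaxComposite:
    def test_max(self):
        g = _grid(1)
        seq = [Raster(g, np.array([[v]])) for v in (0.1, 0.7, 0.3)]
        assert cov.max_composite(seq).values[0, 0] == pytest.approx(0.7)

    def test_single_identity(self):
        g = _grid(2)
        r = Raster(g, np.arange(4.0).reshape(2, 2))
        np.testing.assert_array_equal(cov.max_composite([r]).values, r.values)

    def test_missing_ignored(self):
        g = _grid(1)
        seq = [Raster(g, np.array([[np.nan]])), Raster(g, np.array([[0.2]]))]
        assert cov.max_composite(seq).values[0, 0] == pytest.approx(0.2)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cov.max_composite([Raster(_grid(2), np.zeros((2, 2))),
                               Raster(_grid(3), np.zeros((3, 3)))])


class TestSlope:
    def test_flat_is_zero(self):
        r = Raster(_grid(6), np.full((6, 6), 7.0))
        np.testing.assert_allclose(cov.slope_degrees(r).values, 0.0)

    def test_unit_plane_is_45deg(self):
        # elevation rises 1 m per 1 m easting
        g = GridSpec(0, 6.0, 1.0, 1.0, 6, 6)
        X, _ = g.cell_centers()
        out = cov.slope_degrees(Raster(g, X))
        np.testing.assert_allclose(out.values[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_plane_one_meter_per_cell(self):
        # 1 m rise per 30 m cell -> arctan(1/30) = 1.90915 degrees
        g = _grid(6)
        X, _ = g.cell_centers()
        out = cov.slope_degrees(Raster(g, X / 30.0))
        expected = np.degrees(np.arctan(1.0 / 30.0))
        assert expected == pytest.approx(1.9091, abs=1e-4)
        np.testing.assert_allclose(out.values[1:-1, 1:-1], expected, rtol=1e-9)

    def test_single_cell_errors(self):
        with pytest.raises(ValueError):
            cov.slope_degrees(Raster(_grid(1), np.zeros((1, 1))))


class TestDistance:
    def test_adjacent_cell_distance(self):
        g = _grid(5)
        mask = np.zeros((5, 5))
        mask[2, 2] = 1
        d = cov.distance_to(Raster(g, mask), g)
        assert d.values[2, 2] == 0.0
        assert d.values[2, 3] == pytest.approx(30.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for n in (5, 17, 50):
            g = _grid(n)
            mask = (rng.random((n, n)) < 0.05).astype(float)
            if not mask.any():
                mask[0, 0] = 1.0
            d = cov.distance_to(Raster(g, mask), g)
            X, Y = g.cell_centers()
            fx, fy = X[mask > 0], Y[mask > 0]
            brute = np.min(np.hypot(X.ravel()[:, None] - fx[None, :],
                                    Y.ravel()[:, None] - fy[None, :]), axis=1)
            np.testing.assert_allclose(d.values.ravel(), brute, atol=1e-9)

    def test_vector_feature_distance(self):
        g = _grid(5)
        d = cov.distance_to([Point(75.0, 75.0)], g)  # center of cell (2, 2)
        assert d.values[2, 2] == pytest.approx(0.0)
        assert d.values[2, 4] == pytest.approx(60.0)

    def test_empty_features_error(self):
        g = _grid(3)
        with pytest.raises(ValueError, match="empty"):
            cov.distance_to(Raster(g, np.zeros((3, 3))), g)


class TestExpDistance:
    def test_zero(self):
        g = _grid(1)
        assert cov.exp_distance(Raster(g, np.array([[0.0]])), 10.0).values[0, 0] == 0.0

    def test_at_mu(self):
        g = _grid(1)
        out = cov.exp_distance(Raster(g, np.array([[250.0]])), 250.0)
        assert out.values[0, 0] == pytest.approx(1 - np.exp(-1), abs=1e-9)
        assert out.values[0, 0] == pytest.approx(0.63212, abs=1e-5)

    def test_monotone_bounded(self):
        g = GridSpec(0, 10, 10, 10, 10, 1)
        d = Raster(g, np.linspace(0, 500.0, 10).reshape(1, 10))
        v = cov.exp_distance(d, 100.0).values.ravel()
        assert np.all(np.diff(v) > 0)
        assert v[0] == 0.0 and v[-1] < 1.0

    def test_bad_mu(self):
        with pytest.raises(ValueError):
            cov.exp_distance(Raster(_grid(1), np.array([[1.0]])), 0.0)


class TestBinarize:
    @pytest.mark.parametrize("d,expected", [(150.0, 1.0), (50.0, 0.0), (100.0, 1.0)])
    def test_threshold_rule(self, d, expected):
        g = _grid(1)
        out = cov.binarize_distance(Raster(g, np.array([[d]])), 100.0)
        assert out.values[0, 0] == expected

    def test_idempotent_composition(self):
        g = _grid(5)
        mask = np.zeros((5, 5))
        mask[0, 0] = 1
        d = cov.distance_to(Raster(g, mask), g)
        b1 = cov.binarize_distance(d, 60.0)
        b2 = cov.binarize_distance(Raster(g, b1.values * 1e6 + 1e-6), 60.0)
        # re-binarizing a scaled binary layer reproduces it
        np.testing.assert_array_equal(b1.values, b2.values)


class TestMovingWindow:
    def test_constant_mean(self):
        r = Raster(_grid(9), np.full((9, 9), 3.3))
        for scale in ("neighbor", "r90", "r300"):
            np.testing.assert_allclose(
                cov.moving_window(r, scale).values, 3.3)

    def test_neighbor_mean_hand_computed(self):
        r = Raster(_grid(3), np.arange(1.0, 10.0).reshape(3, 3))
        out = cov.moving_window(r, "neighbor")
        assert out.values[1, 1] == pytest.approx((45 - 5) / 8)
        assert out.values[1, 1] == pytest.approx(5.0)

    def test_constant_sd_zero(self):
        r = Raster(_grid(9), np.full((9, 9), 2.0))
        np.testing.assert_allclose(
            cov.moving_window(r, "r150", stat="sd").values, 0.0, atol=1e-12)

    def test_pixel30_identity(self):
        rng = np.random.default_rng(0)
        r = Raster(_grid(4), rng.random((4, 4)))
        np.testing.assert_array_equal(cov.moving_window(r, "pixel30").values,
                                      r.values)

    def test_r90_footprint_on_30m_grid(self):
        # radius 90 m on a 30 m grid: offsets with hypot <= 90 (29 cells)
        fp = cov._window_offsets("r90", _grid(9))
        assert fp.sum() == 29

    @given(a=st.floats(-5, 5), b=st.floats(0.1, 3))
    @settings(max_examples=20, deadline=None)
    def test_mean_commutes_with_affine(self, a, b):
        rng = np.random.default_rng(7)
        vals = rng.random((8, 8))
        r = Raster(_grid(8), vals)
        m1 = cov.moving_window(Raster(_grid(8), a + b * vals), "r90").values
        m2 = a + b * cov.moving_window(r, "r90").values
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_sd_invariant_to_shift(self):
        rng = np.random.default_rng(8)
        vals = rng.random((8, 8))
        s1 = cov.moving_window(Raster(_grid(8), vals + 10), "r150", stat="sd").values
        s2 = cov.moving_window(Raster(_grid(8), vals), "r150", stat="sd").values
        np.testing.assert_allclose(s1, s2, atol=1e-9)

    def test_missing_excluded(self):
        vals = np.ones((3, 3))
        vals[0, 0] = np.nan
        out = cov.moving_window(Raster(_grid(3), vals), "neighbor")
        assert out.values[1, 1] == pytest.approx(1.0)


class TestLandcover:
    def test_crop_codes(self):
        g = _grid(2)
        lc = Raster(g, np.array([[82.0, 11.0], [81.0, 41.0]]))
        out = cov.crop_binary(lc)
        np.testing.assert_array_equal(out.values, [[1, 0], [1, 0]])

    def test_trees_codes(self):
        g = _grid(2)
        lc = Raster(g, np.array([[41.0, 42.0], [43.0, 82.0]]))
        np.testing.assert_array_equal(cov.trees_mask(lc).values,
                                      [[1, 1], [1, 0]])

    def test_all_crop(self):
        g = _grid(2)
        out = cov.crop_binary(Raster(g, np.full((2, 2), 82.0)))
        assert out.values.sum() == 4

    def test_unknown_code(self):
        with pytest.raises(ValueError, match="99"):
            cov.crop_binary(Raster(_grid(1), np.array([[99.0]])))


class TestRoadDensity:
    def test_no_roads_zero(self):
        out = cov.road_density([], _grid(4), radius=100.0)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_full_chord_through_center(self):
        # straight road through a cell center, crossing the whole disc:
        # length = 2 r, density = 2r / (pi r^2)
        g = GridSpec(0, 2000.0, 1000.0, 1000.0, 2, 2)
        road = LineString([(-1e5, 1500.0), (1e5, 1500.0)])  # through row-0 centers
        r = 400.0
        out = cov.road_density([road], g, radius=r)
        expected = (2 * r / 1000.0) / (np.pi * (r / 1000.0) ** 2)
        np.testing.assert_allclose(out.values[0, :], expected, rtol=1e-4)

    def test_linearity_in_multiplicity(self):
        g = _grid(4)
        road = LineString([(0, 60.0), (150.0, 60.0)])
        one = cov.road_density([road], g, radius=80.0).values
        two = cov.road_density([road, LineString([(0, 61.0), (150.0, 61.0)])],
                               g, radius=80.0).values
        np.testing.assert_allclose(two, 2 * one, rtol=0.05, atol=1e-9)


class TestStandardize:
    def test_hand_computed(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out, scaler = cov.standardize(df)
        np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])  # sample sd
        assert scaler.means["a"] == 2.0
        assert scaler.sds["a"] == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.standard_normal(500)})
        once, _ = cov.standardize(df)
        twice, _ = cov.standardize(once)
        np.testing.assert_allclose(once["a"], twice["a"] * once["a"].std(ddof=1)
                                   + once["a"].mean(), atol=1e-9)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            cov.standardize(pd.DataFrame({"c": [1.0, 1.0, 1.0]}))

    def test_scaler_round_trip(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 9.0], "b": [0.0, 1.0, 4.0]})
        _, scaler = cov.standardize(df)
        back = cov.Standardizer.from_dict(scaler.to_dict())
        pd.testing.assert_frame_equal(scaler.transform(df), back.transform(df))


class TestCorrelationScreen:
    def test_duplicate_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(100)
        rep = cov.correlation_screen(pd.DataFrame({"a": a, "b": a}))
        assert len(rep) == 1
        assert rep.iloc[0]["r"] == pytest.approx(1.0)

    def test_negation_flagged(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        rep = cov.correlation_screen(pd.DataFrame({"a": a, "b": -a}))
        assert abs(rep.iloc[0]["r"]) == pytest.approx(1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.standard_normal((10_000, 4)),
                          columns=list("abcd"))
        assert len(cov.correlation_screen(df)) == 0

    def test_quadratic_partner_exempt(self):
        x = np.linspace(2, 3, 50)
        rep = cov.correlation_screen(pd.DataFrame({"x": x, "x_sq": x**2}))
        assert len(rep) == 0


class TestAssembleDesign:
    def test_quadratic_expansion_counts(self, small_world):
        truth = small_world["truth"]
        d = cov.assemble_design(truth.grid, small_world["layers"],
                                truth.eco_specs, year=2000)
        # 5 specs with one quadratic pair -> 6 columns
        assert d.shape[1] == 6

    def test_point_at_cell_center_exact(self, small_world):
        layers = small_world["layers"]
        g = small_world["truth"].grid
        spec = [cov.CovariateSpec("slope", "slope")]
        pts = pd.DataFrame({"x": [3 * 30.0 + 15.0], "y": [g.y0 - (2 * 30.0 + 15.0)],
                            "year": [2000]})
        d = cov.assemble_design(pts, layers, spec)
        assert d["slope"][0] == pytest.approx(layers["slope"].values[2, 3])

    def test_deterministic(self, small_world):
        truth = small_world["truth"]
        d1 = cov.assemble_design(truth.grid, small_world["layers"],
                                 truth.eco_specs, year=2001)
        d2 = cov.assemble_design(truth.grid, small_world["layers"],
                                 truth.eco_specs, year=2001)
        pd.testing.assert_frame_equal(d1, d2)

    def test_missing_layer_errors(self, small_world):
        with pytest.raises(KeyError, match="nope"):
            cov.assemble_design(small_world["truth"].grid,
                                small_world["layers"],
                                [cov.CovariateSpec("nope", "nope")], year=2000)
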