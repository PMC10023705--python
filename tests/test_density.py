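"""SSU conversion, county responses, screening, density model, CV layer, PDP."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from grazemap.density import (
    DensityModel,
    DensitySamples,
    _metrics,
    county_response,
    fit_density_model,
    partial_dependence,
    predict_pixel_density,
    prune_by_importance,
    screen_correlated,
    to_ssu,
)
from grazemap.geodata import GridSpec, Raster, pixel_area_km2
from grazemap.synth import generate_census, generate_landscape

from conftest import SMALL_LANDSCAPE, make_raster


class TestToSsu:
    @pytest.mark.parametrize("cattle,sheep,expect", [(1, 0, 5), (0, 0, 0), (10, 20, 70)])
    def test_stated_rule(self, cattle, sheep, expect):
        assert to_ssu(cattle, sheep) == expect

    def test_linearity(self, rng):
        c1, s1, c2, s2 = rng.integers(0, 1000, size=4)
        assert to_ssu(c1 + c2, s1 + s2) == to_ssu(c1, s1) + to_ssu(c2, s2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            to_ssu(-1, 0)


def _one_county_setup(ssu, nrows=4, ncols=4):
    spec = GridSpec(92.0, 35.0, 0.01, nrows, ncols)
    mask = Raster(spec, np.ones((nrows, ncols), dtype=np.int8))
    county = Raster(spec, np.ones((nrows, ncols), dtype=np.int64))
    pred = {"DEM": Raster(spec, np.full((nrows, ncols), 4500.0))}
    census = pd.DataFrame(
        [{"unit_id": "C", "cattle_head": 0, "sheep_head": ssu, "is_agricultural": False}]
    )
    return census, mask, county, {"C": 1}, pred


class TestCountyResponse:
    def test_ln_density_formula(self):
        census, mask, county, codes, pred = _one_county_setup(1000)
        s = county_response(census, mask, county, codes, pred, ("DEM",))
        area = s.table.loc[0, "area_km2"]
        assert s.table.loc[0, "y"] == pytest.approx(np.log(1000.0 / area))

    def test_density_one_gives_zero(self):
        census, mask, county, codes, pred = _one_county_setup(1)
        s = county_response(census, mask, county, codes, pred, ("DEM",))
        area = s.table.loc[0, "area_km2"]
        census.loc[0, "sheep_head"] = int(round(area))
        s = county_response(census, mask, county, codes, pred, ("DEM",))
        assert s.table.loc[0, "y"] == pytest.approx(
            np.log(round(area) / area), abs=1e-9)

    def test_area_matches_pixel_loop(self, small_truth):
        # county masked areas equal a brute-force per-pixel area summation
        from grazemap.mask import build_mask

        pm = build_mask(small_truth.landcover)
        census = generate_census(small_truth, level="county")
        s = county_response(census, pm.raster, small_truth.county_raster,
                            small_truth.county_codes, small_truth.predictors)
        spec = small_truth.spec
        for rec in s.table.itertuples():
            code = small_truth.county_codes[rec.county_id]
            total = 0.0
            for r in range(spec.n_rows):
                for c in range(spec.n_cols):
                    if (small_truth.county_raster.values[r, c] == code
                            and pm.raster.values[r, c] == 1):
                        total += pixel_area_km2(spec, r)
            assert rec.area_km2 == pytest.approx(total, rel=1e-9)

    def test_agricultural_and_empty_counties_excluded(self):
        census, mask, county, codes, pred = _one_county_setup(100)
        census.loc[0, "is_agricultural"] = True
        s = county_response(census, mask, county, codes, pred, ("DEM",))
        assert len(s.table) == 0
        assert s.excluded["C"] == "agricultural county"


class TestScreenCorrelated:
    def test_identical_columns_keep_one(self, rng):
        x = rng.normal(size=50)
        tab = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        y = x + rng.normal(size=50)
        retained, dropped = screen_correlated(tab, y)
        assert sorted(retained)[-1] == "c"
        assert len(retained) == 2
        assert len(dropped) == 1

    def test_independent_columns_survive(self, rng):
        tab = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        y = rng.normal(size=200)
        retained, dropped = screen_correlated(tab, y)
        assert retained == list("abcd")
        assert dropped == []

    def test_weaker_partner_dropped(self, rng):
        # planted r(A,B) ~ 0.9; response built from A -> B must be dropped
        n = 500
        a = rng.normal(size=n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = rng.normal(size=n)
        y = a + 0.1 * rng.normal(size=n)
        tab = pd.DataFrame({"A": a, "B": b, "C": c})
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.7
        retained, dropped = screen_correlated(tab, y)
        assert "A" in retained and "B" not in retained and "C" in retained
        assert dropped[0][:2] == ("A", "B")

    def test_constant_column_dropped_first(self, rng):
        tab = pd.DataFrame({"const": np.ones(30), "x": rng.normal(size=30)})
        retained, dropped = screen_correlated(tab, rng.normal(size=30))
        assert retained == ["x"]


class TestMetricsAndFit:
    def test_perfect_fit_limits(self, rng):
        y = rng.normal(size=40)
        r2, mae, mse = _metrics(y, y.copy())
        assert (r2, mae, mse) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self, rng):
        y = rng.normal(size=40)
        r2, _, _ = _metrics(y, np.full_like(y, y.mean()))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def _samples(self, sigma_y, seed=0):
        cfg = dataclasses.replace(SMALL_LANDSCAPE, seed=seed,
                                  n_county_rows=4, n_county_cols=6,
                                  spec=dataclasses.replace(SMALL_LANDSCAPE.spec,
                                                           n_rows=120, n_cols=120),
                                  sigma_y=sigma_y)
        truth = generate_landscape(cfg)
        from grazemap.mask import build_mask

        pm = build_mask(truth.landcover)
        census = generate_census(truth, level="county")
        return county_response(census, pm.raster, truth.county_raster,
                               truth.county_codes, truth.predictors)

    def test_noise_dominated_fit_has_no_skill(self):
        s = self._samples(sigma_y=10.0)
        model = fit_density_model(s, seed=0, n_folds=10, n_estimators=100)
        assert model.oof_r2 <= 0.2

    def test_recovery_improves_as_noise_falls(self):
        r2 = [fit_density_model(self._samples(sig), seed=0, n_folds=10,
                                n_estimators=100).oof_r2
              for sig in (1.0, 0.5, 0.25)]
        assert r2[0] <= r2[1] <= r2[2]

    def test_too_few_counties_rejected(self):
        s = self._samples(sigma_y=0.3)
        s.table = s.table.iloc[:5]
        with pytest.raises(ValueError, match="folds"):
            fit_density_model(s, n_folds=10)


class TestPruneLadder:
    def _samples(self, rng, names=("a", "b", "c"), n=40):
        X = rng.normal(size=(n, len(names)))
        y = X[:, 0] * 2 + 0.2 * rng.normal(size=n)
        tab = pd.DataFrame(X, columns=list(names))
        tab.insert(0, "county_id", [f"C{i}" for i in range(n)])
        tab["ssu"] = 1.0
        tab["area_km2"] = 1.0
        tab["y"] = y
        return DensitySamples(tab, tuple(names), {})

    def test_ladder_lengths(self, rng):
        s = self._samples(rng)
        ladder = prune_by_importance(s, seed=0, n_estimators=50)
        assert [len(m.predictor_names) for m in ladder] == [3, 2, 1]

    def test_single_predictor_ladder(self, rng):
        s = self._samples(rng, names=("only",))
        ladder = prune_by_importance(s, seed=0, n_estimators=50)
        assert len(ladder) == 1

    def test_noise_predictor_dropped_first(self, rng):
        # a pure-noise column must have the least importance almost always
        hits = 0
        for trial in range(20):
            t_rng = np.random.default_rng(1000 + trial)
            s = self._samples(t_rng, names=("signal", "helper", "noise"), n=80)
            s.table["helper"] = s.table["y"] * 0.5 + 0.5 * t_rng.normal(size=len(s.table))
            model = fit_density_model(s, seed=trial, n_folds=5, n_estimators=200)
            if min(model.importances, key=model.importances.get) == "noise":
                hits += 1
        assert hits >= 18


class _ConstModel:
    def __init__(self, value):
        self._v = value

    def predict(self, X):
        return np.full(len(X), self._v)


def _toy_density_model(fold_values):
    return DensityModel(
        fold_models=[_ConstModel(np.log(v)) for v in fold_values],
        predictor_names=("DEM",),
        oof_r2=0.0, oof_mae=0.0, oof_mse=0.0,
        fold_r2=[], fold_mae=[], fold_mse=[],
        importances={"DEM": 1.0}, seed=0,
    )


class TestPixelPrediction:
    def _inputs(self):
        pred = {"DEM": make_raster(np.linspace(4000, 5000, 16).reshape(4, 4))}
        mask = make_raster(np.ones((4, 4), dtype=np.int8))
        return pred, mask

    def test_identical_folds_zero_cv(self):
        pred, mask = self._inputs()
        model = _toy_density_model([2.0] * 10)
        out = predict_pixel_density(model, pred, mask)
        assert np.allclose(out.cv.values, 0.0)
        assert np.allclose(out.mean_density.values, 2.0)

    def test_two_fold_toy_cv(self):
        # fold densities {1, 3}: mean 2, sample SD sqrt(2), CV = sqrt(2)/2
        pred, mask = self._inputs()
        model = _toy_density_model([1.0, 3.0])
        out = predict_pixel_density(model, pred, mask)
        assert np.allclose(out.mean_density.values, 2.0)
        assert np.allclose(out.cv.values, np.sqrt(2) / 2)

    def test_off_mask_nodata_and_nonnegative(self):
        pred, _ = self._inputs()
        mask_vals = np.zeros((4, 4), dtype=np.int8)
        mask_vals[0, 0] = mask_vals[1, 0] = 1
        mask = make_raster(mask_vals)
        model = _toy_density_model([1.0, 3.0])
        out = predict_pixel_density(model, pred, mask)
        assert not out.mean_density.valid_mask()[0, 1]
        assert not out.cv.valid_mask()[3, 3]
        sel = out.mean_density.valid_mask()
        assert (out.mean_density.values[sel] >= 0).all()


class TestPartialDependence:
    def test_monotone_effect_recovered(self, rng):
        n = 60
        x = np.sort(rng.uniform(0, 10, size=n))
        tab = pd.DataFrame({"county_id": [f"C{i}" for i in range(n)],
                            "ssu": 1.0, "area_km2": 1.0,
                            "y": 2.0 * x + 0.1 * rng.normal(size=n), "x": x})
        s = DensitySamples(tab, ("x",), {})
        model = fit_density_model(s, seed=0, n_folds=5, n_estimators=100)
        pdp = partial_dependence(model, s, "x", n_grid=20)
        steps = np.diff(pdp["mean_prediction"].to_numpy())
        assert (steps >= 0).sum() >= 18

    def test_constant_response_flat(self, rng):
        n = 30
        tab = pd.DataFrame({"county_id": [f"C{i}" for i in range(n)],
                            "ssu": 1.0, "area_km2": 1.0,
                            "y": 1.0, "x": rng.normal(size=n)})
        s = DensitySamples(tab, ("x",), {})
        model = fit_density_model(s, seed=0, n_folds=5, n_estimators=50)
        pdp = partial_dependence(model, s, "x")
        assert np.allclose(pdp["mean_prediction"], 1.0)

    def test_grid_endpoints_are_observed_range(self, rng):
        n = 30
        x = rng.normal(size=n)
        tab = pd.DataFrame({"county_id": [f"C{i}" for i in range(n)],
                            "ssu": 1.0, "area_km2": 1.0, "y": x, "x": x})
        s = DensitySamples(tab, ("x",), {})
        model = fit_density_model(s, seed=0, n_folds=5, n_estimators=20)
        pdp = partial_dependence(model, s, "x", n_grid=7)
        assert pdp["x"].iloc[0] == pytest.approx(x.min())
        assert pdp["x"].iloc[-1] == pytest.approx(x.max())

    def test_unknown_predictor_rejected(self, rng):
        tab = pd.DataFrame({"county_id": ["C0"] * 25, "ssu": 1.0, "area_km2": 1.0,
                            "y": rng.normal(size=25), "x": rng.normal(size=25)})
        s = DensitySamples(tab, ("x",), {})
        model = fit_density_model(s, seed=0, n_folds=5, n_estimators=20)
        with pytest.raises(ValueError):
            partial_dependence(model, s, "absent")
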