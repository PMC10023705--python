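"""Raster I/O, resampling, rasterization, zonal statistics and pixel areas."""

import math

import numpy as np
import pytest
import shapely
from shapely.geometry import box

from grazemap.geodata import (
    EARTH_RADIUS_KM,
    AdminPolygon,
    GridMismatchError,
    GridSpec,
    area_raster,
    pixel_area_km2,
    rasterize,
    read_raster,
    resample,
    write_raster,
    zonal_stat,
)

from conftest import make_raster


class TestRoundTrip:
    @pytest.mark.parametrize("dtype", [np.float32, np.float64, np.int16])
    def test_write_read_identity(self, tmp_path, dtype, rng):
        vals = rng.normal(size=(7, 5)).astype(dtype)
        if np.issubdtype(dtype, np.integer):
            vals = rng.integers(-100, 100, size=(7, 5)).astype(dtype)
        r = make_raster(vals)
        back = read_raster(write_raster(r, tmp_path / "a.tif"))
        assert np.array_equal(back.values, vals)
        assert back.values.dtype == vals.dtype
        assert back.spec.same_grid(r.spec, tol=1e-9)
        assert back.spec.nodata == r.spec.nodata

    def test_nodata_sentinel_preserved(self, tmp_path):
        vals = np.arange(9, dtype=np.float32).reshape(3, 3)
        vals[0, 0] = -9999.0
        back = read_raster(write_raster(make_raster(vals), tmp_path / "n.tif"))
        assert not back.valid_mask()[0, 0]
        assert back.valid_mask()[1, 1]

    def test_product_scale_roundtrip(self, tmp_path, rng):
        # round trip at the published product array size
        vals = rng.normal(size=(2130, 4800)).astype(np.float32)
        back = read_raster(write_raster(make_raster(vals, pixel_size=15 / 3600),
                                        tmp_path / "big.tif"))
        assert np.array_equal(back.values, vals)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_raster(tmp_path / "absent.tif")

    def test_multiband_rejected(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "rgb.tif", np.zeros((4, 4, 3), dtype=np.uint8),
                         photometric="rgb")
        with pytest.raises(ValueError, match="multiband"):
            read_raster(tmp_path / "rgb.tif")


class TestResample:
    def test_nearest_identity(self, rng):
        r = make_raster(rng.integers(0, 5, size=(6, 6)))
        out = resample(r, r.spec, "nearest")
        assert np.array_equal(out.values, r.values)

    def test_bilinear_midpoint(self):
        # 2x2 source of 0,0 / 10,10; a single target pixel whose center sits
        # exactly between the four source centers interpolates to 5
        src = make_raster(np.array([[0.0, 0.0], [10.0, 10.0]]), pixel_size=0.01)
        target = GridSpec(92.0, 35.0, 0.02, 1, 1)
        out = resample(src, target, "bilinear")
        assert out.values[0, 0] == pytest.approx(5.0)

    def test_majority_matches_blockwise_count(self, rng):
        # 4x4 categorical to 2x2: brute-force per-block modes
        vals = rng.integers(0, 3, size=(4, 4))
        src = make_raster(vals, pixel_size=0.01)
        target = GridSpec(92.0, 35.0, 0.02, 2, 2)
        out = resample(src, target, "majority")
        for bi in range(2):
            for bj in range(2):
                block = vals[2 * bi:2 * bi + 2, 2 * bj:2 * bj + 2].ravel()
                counts = {c: (block == c).sum() for c in np.unique(block)}
                best = max(counts.values())
                expect = min(c for c, n in counts.items() if n == best)
                assert out.values[bi, bj] == expect

    def test_empty_overlap_raises(self):
        src = make_raster(np.zeros((4, 4)), origin=(92.0, 35.0))
        far = GridSpec(120.0, 10.0, 0.01, 4, 4)
        with pytest.raises(ValueError, match="overlap"):
            resample(src, far, "nearest")


class TestRasterize:
    def _grid(self, n=4):
        return GridSpec(92.0, 35.0, 0.01, n, n)

    def test_full_cover(self):
        spec = self._grid()
        poly = AdminPolygon("A", "county", box(91.9, 34.9, 92.2, 35.1))
        out, codes = rasterize([poly], spec)
        assert (out.values == codes["A"]).all()

    def test_west_half(self):
        spec = self._grid(4)
        west = AdminPolygon("W", "county", box(92.0, 34.9, 92.02, 35.0))
        out, codes = rasterize([west], spec)
        assert (out.values == codes["W"]).sum() == 8

    def test_matches_brute_force_containment(self, rng):
        spec = GridSpec(92.0, 35.0, 0.01, 32, 32)
        polys = []
        for i in range(3):  # one random rectangle per horizontal third: disjoint
            x0 = 92.0 + 0.11 * i + rng.uniform(0, 0.02)
            y0 = rng.uniform(34.78, 34.95)
            polys.append(
                AdminPolygon(f"P{i}", "county",
                             box(x0, y0, x0 + rng.uniform(0.02, 0.08),
                                 y0 + rng.uniform(0.02, 0.05)))
            )
        out, codes = rasterize(polys, spec)
        lon, lat = spec.center_coords()
        for r in range(32):
            for c in range(32):
                expect = int(spec.nodata)
                for p in polys:
                    if p.geometry.contains(shapely.Point(lon[r, c], lat[r, c])):
                        expect = codes[p.unit_id]
                        break
                assert out.values[r, c] == expect

    def test_overlap_names_both_units(self):
        spec = self._grid()
        a = AdminPolygon("A", "county", box(91.9, 34.9, 92.2, 35.1))
        b = AdminPolygon("B", "county", box(91.9, 34.9, 92.2, 35.1))
        with pytest.raises(ValueError, match="'A'.*'B'"):
            rasterize([a, b], spec)


class TestZonalStat:
    def test_mean_sum_count(self):
        vals = make_raster(np.array([[1.0, 2.0], [3.0, 4.0]]))
        zone = make_raster(np.ones((2, 2), dtype=int))
        full = make_raster(np.ones((2, 2), dtype=np.int8))
        assert zonal_stat(vals, zone, full, "mean").value("1", "value") == 2.5
        assert zonal_stat(vals, zone, full, "sum").value("1", "value") == 10
        assert zonal_stat(vals, zone, full, "count").value("1", "value") == 4

    def test_mask_excludes(self):
        vals = make_raster(np.array([[1.0, 2.0], [3.0, 4.0]]))
        zone = make_raster(np.ones((2, 2), dtype=int))
        mask = make_raster(np.array([[1, 1], [0, 0]], dtype=np.int8))
        assert zonal_stat(vals, zone, mask, "mean").value("1", "value") == 1.5

    def test_empty_zone_flagged_not_dropped(self):
        vals = make_raster(np.array([[1.0, 2.0], [3.0, 4.0]]))
        zone = make_raster(np.array([[1, 1], [1, 2]]))
        mask = make_raster(np.array([[1, 1], [1, 0]], dtype=np.int8))
        t = zonal_stat(vals, zone, mask, "mean")
        assert t.counts["2"] == 0
        assert "2" in t.empty_units
        assert math.isnan(t.value("2", "value"))

    def test_grid_mismatch(self):
        a = make_raster(np.zeros((2, 2)))
        b = make_raster(np.zeros((3, 3)))
        with pytest.raises(GridMismatchError):
            zonal_stat(a, b, None, "mean")

    def test_sum_over_zones_equals_global_sum(self, rng):
        # accounting conservation: zone sums add to the global masked sum
        vals = make_raster(rng.normal(size=(20, 20)))
        zone = make_raster(rng.integers(1, 6, size=(20, 20)))
        t = zonal_stat(vals, zone, None, "sum")
        total = sum(t.data[u]["value"] for u in t.data if t.counts[u] > 0)
        assert total == pytest.approx(vals.values.sum(), rel=1e-12)


class TestPixelArea:
    def test_equator_closed_form(self):
        # pixel-center latitude 0 requires origin_lat = pixel_size/2
        px = 15.0 / 3600.0
        spec = GridSpec(0.0, px / 2, px, 1, 1)
        delta = math.radians(px)
        expected = (EARTH_RADIUS_KM * delta) ** 2  # cos(0) = 1
        assert pixel_area_km2(spec, 0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2146, abs=2e-4)

    def test_sixty_degrees_half_equatorial(self):
        px = 15.0 / 3600.0
        eq = GridSpec(0.0, px / 2, px, 1, 1)
        sixty = GridSpec(0.0, 60.0 + px / 2, px, 1, 1)
        assert pixel_area_km2(sixty, 0) == pytest.approx(pixel_area_km2(eq, 0) / 2, rel=1e-12)

    def test_vanishes_approaching_pole(self):
        # pixel-center latitude -> 90 as pixel size -> 0 with origin at 90
        areas = []
        for px in (1e-2, 1e-4, 1e-6):
            spec = GridSpec(0.0, 90.0, px, 1, 1)
            areas.append(float(pixel_area_km2(spec, 0)) / px**2)  # remove Delta^2 scale
        assert areas[0] > areas[1] > areas[2] > 0
        assert pixel_area_km2(GridSpec(0.0, 90.0, 1e-6, 1, 1), 0) < 1e-12

    def test_monotone_decreasing_in_abs_latitude(self):
        spec = GridSpec(0.0, 80.0, 0.5, 320, 1)
        areas = np.asarray(pixel_area_km2(spec, np.arange(320)))
        lats = spec.row_center_lat(np.arange(320))
        order = np.argsort(np.abs(lats))
        assert (np.diff(areas[order]) <= 1e-15).all()

    def test_symmetric_about_equator(self):
        spec = GridSpec(0.0, 10.0, 1.0, 20, 1)
        lats = spec.row_center_lat(np.arange(20))
        areas = np.asarray(pixel_area_km2(spec, np.arange(20)))
        for i, li in enumerate(lats):
            j = np.argmin(np.abs(lats + li))
            assert areas[i] == pytest.approx(areas[j], rel=1e-12)

    def test_area_raster_constant_along_rows(self):
        spec = GridSpec(90.0, 40.0, 0.1, 5, 7)
        ar = area_raster(spec)
        assert (np.diff(ar.values, axis=1) == 0).all()
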