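"""Raster/vector data model, GeoTIFF I/O, resampling, rasterization and zonal statistics.

All rasters are single-band, north-up, geographic (WGS84 lon/lat) grids with
square pixels. Pixel (0, 0) is the upper-left pixel; ``origin_lon/origin_lat``
is the *corner* of that pixel (GeoTIFF RasterPixelIsArea convention). Row 0 is
the northernmost row. Polygon-to-pixel assignment is by pixel-center
containment.

Areas use a spherical Earth of radius 6371.0088 km, so a pixel of angular size
Delta (radians) centred at latitude phi has area (R*Delta)^2 * cos(phi).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088
#: 15 arc-seconds in degrees, the native product resolution.
DEFAULT_PIXEL_SIZE = 15.0 / 3600.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113
# GeoKey ids / values
_KEY_MODEL_TYPE = 1024
_KEY_RASTER_TYPE = 1025
_KEY_GEOGRAPHIC_TYPE = 2048
_MODEL_GEOGRAPHIC = 2
_RASTER_PIXEL_IS_AREA = 1
_GCS_WGS84 = 4326


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up geographic raster grid.

    ``origin_lon``/``origin_lat`` locate the upper-left corner of pixel
    (0, 0) in degrees; ``pixel_size`` is the square pixel edge in degrees.
    """

    origin_lon: float
    origin_lat: float
    pixel_size: float = DEFAULT_PIXEL_SIZE
    n_rows: int = 1
    n_cols: int = 1
    crs_tag: str = "EPSG:4326"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not -90.0 <= self.origin_lat <= 90.0:
            raise ValueError(f"origin_lat out of range: {self.origin_lat}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def row_center_lat(self, row) -> float | np.ndarray:
        return self.origin_lat - (np.asarray(row) + 0.5) * self.pixel_size

    def col_center_lon(self, col) -> float | np.ndarray:
        return self.origin_lon + (np.asarray(col) + 0.5) * self.pixel_size

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of all pixel centers, each shaped (n_rows, n_cols)."""
        lon = self.col_center_lon(np.arange(self.n_cols))
        lat = self.row_center_lat(np.arange(self.n_rows))
        return np.meshgrid(lon, lat)

    def same_grid(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
            and abs(self.pixel_size - other.pixel_size) <= tol
        )

    @staticmethod
    def from_extent(
        lon_min: float,
        lat_min: float,
        lon_max: float,
        lat_max: float,
        pixel_size: float = DEFAULT_PIXEL_SIZE,
        nodata: float = -9999.0,
    ) -> "GridSpec":
        """Derive shape from a bounding box; rows/cols round up to cover it."""
        n_cols = max(1, int(math.ceil((lon_max - lon_min) / pixel_size - 1e-9)))
        n_rows = max(1, int(math.ceil((lat_max - lat_min) / pixel_size - 1e-9)))
        return GridSpec(lon_min, lat_max, pixel_size, n_rows, n_cols, nodata=nodata)


@dataclass
class Raster:
    """A single-band value array bound to a :class:`GridSpec`."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape != self.spec.shape:
            raise ValueError(
                f"value array shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    @property
    def nodata(self) -> float:
        return self.spec.nodata

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the pixel holds data."""
        v = self.values
        with np.errstate(invalid="ignore"):
            ok = v != self.nodata
        if np.issubdtype(v.dtype, np.floating):
            ok &= ~np.isnan(v)
        return ok

    def with_values(self, values: np.ndarray) -> "Raster":
        return Raster(self.spec, values)

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy())


def _require_same_grid(*rasters: Raster) -> GridSpec:
    spec = rasters[0].spec
    for r in rasters[1:]:
        if not spec.same_grid(r.spec):
            raise GridMismatchError("rasters are not on the same grid")
    return spec


@dataclass
class AdminPolygon:
    """A county or township with geometry in lon/lat and census attributes."""

    unit_id: str
    level: Literal["county", "township"]
    geometry: BaseGeometry
    parent_id: str | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("county", "township"):
            raise ValueError(f"level must be county or township, got {self.level!r}")
        if not self.geometry.is_valid:
            raise ValueError(f"invalid geometry for unit {self.unit_id!r}")
        if self.level == "township" and not self.parent_id:
            raise ValueError(f"township {self.unit_id!r} lacks a parent county")


def check_hierarchy(counties: Sequence[AdminPolygon], townships: Sequence[AdminPolygon]) -> None:
    """Every township's parent_id must name an existing county."""
    county_ids = {c.unit_id for c in counties}
    orphans = [t.unit_id for t in townships if t.parent_id not in county_ids]
    if orphans:
        raise ValueError(f"townships with unknown parent county: {orphans}")


@dataclass
class ZonalTable:
    """Per-zone statistics; one row per unit, one column per variable."""

    stat: str
    data: dict[str, dict[str, float]]  # unit_id -> variable -> value
    counts: dict[str, int]  # unit_id -> qualifying pixel count
    empty_units: list[str] = field(default_factory=list)

    def value(self, unit_id: str, variable: str) -> float:
        return self.data[unit_id][variable]

    def to_frame(self):
        import pandas as pd

        rows = []
        for uid, cols in self.data.items():
            for var, val in cols.items():
                rows.append(
                    {"unit_id": uid, "variable": var, "stat": self.stat,
                     "value": val, "count": self.counts[uid]}
                )
        return pd.DataFrame(rows, columns=["unit_id", "variable", "stat", "value", "count"])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(raster: Raster, path: str | Path, dtype=None) -> Path:
    """Write a single-band GeoTIFF with georeferencing and nodata tags.

    Values are written as-is unless ``dtype`` is given; georeferencing is
    stored via ModelPixelScale/ModelTiepoint and a minimal WGS84 geokey
    directory, nodata via the GDAL_NODATA ASCII tag.
    """
    path = Path(path)
    spec = raster.spec
    values = raster.values if dtype is None else raster.values.astype(dtype)
    # the nodata tag is only written when the sentinel is representable in
    # the output dtype; readers fall back to the package default otherwise
    write_nodata = True
    if np.issubdtype(values.dtype, np.integer):
        info = np.iinfo(values.dtype)
        write_nodata = (
            float(spec.nodata).is_integer() and info.min <= spec.nodata <= info.max
        )
    keys = (
        1, 1, 0, 3,
        _KEY_MODEL_TYPE, 0, 1, _MODEL_GEOGRAPHIC,
        _KEY_RASTER_TYPE, 0, 1, _RASTER_PIXEL_IS_AREA,
        _KEY_GEOGRAPHIC_TYPE, 0, 1, _GCS_WGS84,
    )
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.pixel_size, spec.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_lon, spec.origin_lat, 0.0)),
        (_TAG_GEO_KEYS, "H", len(keys), keys),
    ]
    if write_nodata:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, f"{spec.nodata:g}"))
    tifffile.imwrite(path, values, extratags=extratags, photometric="minisblack")
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a single-band geographic GeoTIFF written by :func:`write_raster`.

    Rejects multiband files and files without a geographic (lat/lon) model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, found {len(tif.pages)} pages")
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: multiband rasters are not supported")
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tie = tags.get(_TAG_TIEPOINT)
        if scale is None or tie is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        geokeys = tags.get(_TAG_GEO_KEYS)
        if geokeys is not None:
            kv = np.asarray(geokeys.value).reshape(-1, 4)
            model = {int(k): int(v) for k, _, _, v in kv[1:]}
            if model.get(_KEY_MODEL_TYPE, _MODEL_GEOGRAPHIC) != _MODEL_GEOGRAPHIC:
                raise ValueError(f"{path}: projected CRS rasters are not supported")
        nodata_tag = tags.get(_TAG_GDAL_NODATA)
        nodata = float(str(nodata_tag.value)) if nodata_tag is not None else -9999.0
        values = page.asarray()
        sx, sy = float(scale.value[0]), float(scale.value[1])
        if abs(sx - sy) > 1e-12:
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy})")
        tiev = tie.value
        spec = GridSpec(
            origin_lon=float(tiev[3]) - float(tiev[0]) * sx,
            origin_lat=float(tiev[4]) + float(tiev[1]) * sy,
            pixel_size=sx,
            n_rows=values.shape[0],
            n_cols=values.shape[1],
            nodata=nodata,
        )
    return Raster(spec, values)


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)


def read_admin_geojson(path: str | Path, level: Literal["county", "township"]) -> list[AdminPolygon]:
    """Load admin polygons from a GeoJSON FeatureCollection.

    Each feature needs a ``unit_id`` property; townships need ``parent_id``.
    Remaining properties become attributes.
    """
    with open(path) as fh:
        fc = json.load(fh)
    units = []
    for feat in fc["features"]:
        props = dict(feat.get("properties") or {})
        uid = str(props.pop("unit_id"))
        parent = props.pop("parent_id", None)
        units.append(
            AdminPolygon(uid, level, shapely_shape(feat["geometry"]),
                         parent_id=parent, attributes=props)
        )
    return units


def write_admin_geojson(units: Sequence[AdminPolygon], path: str | Path) -> Path:
    path = Path(path)
    feats = []
    for u in units:
        props = {"unit_id": u.unit_id, **u.attributes}
        if u.parent_id is not None:
            props["parent_id"] = u.parent_id
        feats.append(
            {"type": "Feature", "properties": props,
             "geometry": json.loads(shapely.to_geojson(u.geometry))}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    return path


# ---------------------------------------------------------------------------
# Resampling


def resample(
    raster: Raster,
    target: GridSpec,
    method: Literal["bilinear", "nearest", "majority"],
) -> Raster:
    """Resample onto ``target``.

    ``bilinear`` is for continuous variables (interpolates between source
    pixel centers), ``nearest``/``majority`` for categorical ones. ``majority``
    assigns each target pixel the most frequent source class whose pixel
    center falls inside the target pixel footprint, ties broken by the
    smallest class code.
    """
    src = raster.spec
    lon_overlap = min(src.origin_lon + src.n_cols * src.pixel_size,
                      target.origin_lon + target.n_cols * target.pixel_size) - max(
        src.origin_lon, target.origin_lon)
    lat_overlap = min(src.origin_lat, target.origin_lat) - max(
        src.origin_lat - src.n_rows * src.pixel_size,
        target.origin_lat - target.n_rows * target.pixel_size)
    if lon_overlap <= 0 or lat_overlap <= 0:
        raise ValueError("source and target grids do not overlap")

    if method == "nearest":
        return _resample_nearest(raster, target)
    if method == "bilinear":
        return _resample_bilinear(raster, target)
    if method == "majority":
        return _resample_majority(raster, target)
    raise ValueError(f"unknown resampling method {method!r}")


def _target_center_indices(src: GridSpec, target: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Fractional source-array indices of the target pixel centers."""
    lon, lat = target.center_coords()
    col = (lon - src.origin_lon) / src.pixel_size - 0.5
    row = (src.origin_lat - lat) / src.pixel_size - 0.5
    return row, col


def _resample_nearest(raster: Raster, target: GridSpec) -> Raster:
    src = raster.spec
    row, col = _target_center_indices(src, target)
    ri = np.clip(np.rint(row).astype(int), 0, src.n_rows - 1)
    ci = np.clip(np.rint(col).astype(int), 0, src.n_cols - 1)
    out = raster.values[ri, ci]
    inside = (row > -0.5 - 1e-9) & (row < src.n_rows - 0.5 + 1e-9) & \
             (col > -0.5 - 1e-9) & (col < src.n_cols - 0.5 + 1e-9)
    out = np.where(inside, out, target.nodata)
    return Raster(target, out.astype(raster.values.dtype, copy=False))


def _resample_bilinear(raster: Raster, target: GridSpec) -> Raster:
    src = raster.spec
    row, col = _target_center_indices(src, target)
    r0 = np.clip(np.floor(row).astype(int), 0, src.n_rows - 1)
    c0 = np.clip(np.floor(col).astype(int), 0, src.n_cols - 1)
    r1 = np.clip(r0 + 1, 0, src.n_rows - 1)
    c1 = np.clip(c0 + 1, 0, src.n_cols - 1)
    fr = np.clip(row - r0, 0.0, 1.0)
    fc = np.clip(col - c0, 0.0, 1.0)
    v = raster.values.astype(np.float64)
    valid = raster.valid_mask()
    corners = [v[r0, c0], v[r0, c1], v[r1, c0], v[r1, c1]]
    weights = [(1 - fr) * (1 - fc), (1 - fr) * fc, fr * (1 - fc), fr * fc]
    out = sum(w * c for w, c in zip(weights, corners))
    all_valid = valid[r0, c0] & valid[r0, c1] & valid[r1, c0] & valid[r1, c1]
    inside = (row > -0.5 - 1e-9) & (row < src.n_rows - 0.5 + 1e-9) & \
             (col > -0.5 - 1e-9) & (col < src.n_cols - 0.5 + 1e-9)
    out = np.where(all_valid & inside, out, target.nodata)
    return Raster(target, out)


def _resample_majority(raster: Raster, target: GridSpec) -> Raster:
    src, valid = raster.spec, raster.valid_mask()
    # target pixel index of every source pixel center
    lon, lat = src.center_coords()
    tc = np.floor((lon - target.origin_lon) / target.pixel_size).astype(int)
    tr = np.floor((target.origin_lat - lat) / target.pixel_size).astype(int)
    ok = valid & (tr >= 0) & (tr < target.n_rows) & (tc >= 0) & (tc < target.n_cols)
    out = np.full(target.shape, target.nodata)
    if not ok.any():
        return Raster(target, out)
    classes, inv = np.unique(raster.values[ok], return_inverse=True)
    flat_target = tr[ok] * target.n_cols + tc[ok]
    # counts[target_pixel, class]; classes are sorted so argmax takes the
    # smallest class code on ties
    counts = np.zeros((target.n_rows * target.n_cols, classes.size), dtype=np.int64)
    np.add.at(counts, (flat_target, inv), 1)
    hit = counts.sum(axis=1) > 0
    winner = classes[np.argmax(counts, axis=1)]
    out_flat = out.reshape(-1)
    out_flat[hit] = winner[hit]
    return Raster(target, out_flat.reshape(target.shape))


# ---------------------------------------------------------------------------
# Rasterization and zonal statistics


def rasterize(
    polygons: Sequence[AdminPolygon],
    spec: GridSpec,
    codes: Mapping[str, int] | None = None,
) -> tuple[Raster, dict[str, int]]:
    """Burn polygons into an integer code raster by pixel-center containment.

    Returns the coded raster (nodata where no polygon contains the center)
    and the unit_id -> code mapping. Two polygons claiming the same pixel
    center is an error naming both units.
    """
    if codes is None:
        codes = {p.unit_id: i + 1 for i, p in enumerate(polygons)}
    lon, lat = spec.center_coords()
    out = np.full(spec.shape, int(spec.nodata), dtype=np.int64)
    claimed_by: dict[int, str] = {}
    flat_lon, flat_lat = lon.ravel(), lat.ravel()
    for poly in polygons:
        inside = shapely.contains_xy(poly.geometry, flat_lon, flat_lat)
        idx = np.flatnonzero(inside)
        for i in idx:
            if i in claimed_by:
                raise ValueError(
                    f"pixel center claimed by both {claimed_by[i]!r} and {poly.unit_id!r}"
                )
            claimed_by[i] = poly.unit_id
        out.reshape(-1)[idx] = codes[poly.unit_id]
    return Raster(spec, out), dict(codes)


def zonal_stat(
    value_raster: Raster,
    zone_raster: Raster,
    mask_raster: Raster | None,
    stat: Literal["mean", "sum", "count"],
    zone_codes: Mapping[str, int] | None = None,
    variable: str = "value",
) -> ZonalTable:
    """Per-zone statistic over pixels where zone = unit, mask = 1 and value is data.

    Zones with zero qualifying pixels are reported with count 0 and NaN value
    (listed in ``empty_units``), never silently dropped.
    """
    if mask_raster is None:
        mask_raster = Raster(value_raster.spec, np.ones(value_raster.spec.shape, dtype=np.int8))
    _require_same_grid(value_raster, zone_raster, mask_raster)
    if stat not in ("mean", "sum", "count"):
        raise ValueError(f"unknown stat {stat!r}")

    zvals = zone_raster.values
    zone_valid = zone_raster.valid_mask()
    qual = zone_valid & (mask_raster.values == 1) & value_raster.valid_mask()

    present = np.unique(zvals[zone_valid])
    if zone_codes is None:
        zone_codes = {str(int(z)): int(z) for z in present}
    inv_codes = {int(v): k for k, v in zone_codes.items()}

    data: dict[str, dict[str, float]] = {}
    counts: dict[str, int] = {}
    empty: list[str] = []
    vals = value_raster.values.astype(np.float64)
    for code, uid in sorted(inv_codes.items()):
        sel = qual & (zvals == code)
        n = int(sel.sum())
        counts[uid] = n
        if n == 0:
            data[uid] = {variable: math.nan}
            empty.append(uid)
            continue
        if stat == "count":
            data[uid] = {variable: float(n)}
        elif stat == "sum":
            data[uid] = {variable: float(vals[sel].sum())}
        else:
            data[uid] = {variable: float(vals[sel].mean())}
    return ZonalTable(stat=stat, data=data, counts=counts, empty_units=empty)


def zonal_table(
    value_rasters: Mapping[str, Raster],
    zone_raster: Raster,
    mask_raster: Raster | None,
    stat: Literal["mean", "sum", "count"] = "mean",
    zone_codes: Mapping[str, int] | None = None,
) -> ZonalTable:
    """Multi-variable :func:`zonal_stat`; one column per named raster."""
    merged: ZonalTable | None = None
    for name, rast in value_rasters.items():
        t = zonal_stat(rast, zone_raster, mask_raster, stat, zone_codes, variable=name)
        if merged is None:
            merged = t
        else:
            for uid in t.data:
                merged.data[uid].update(t.data[uid])
    assert merged is not None
    return merged


# ---------------------------------------------------------------------------
# Pixel areas


def pixel_area_km2(spec: GridSpec, row: int | np.ndarray) -> float | np.ndarray:
    """Spherical-Earth area (km^2) of pixels in the given row(s)."""
    lat = spec.row_center_lat(row)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("pixel-center latitude outside [-90, 90]")
    delta = math.radians(spec.pixel_size)
    return (EARTH_RADIUS_KM * delta) ** 2 * np.cos(np.radians(lat))


def area_raster(spec: GridSpec) -> Raster:
    """Raster of per-pixel areas in km^2 (constant along rows)."""
    rows = np.arange(spec.n_rows)
    col_area = np.asarray(pixel_area_km2(spec, rows))
    return Raster(spec, np.repeat(col_area[:, None], spec.n_cols, axis=1))
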