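"""Synthetic study regions for the seasonal livestock-mapping pipeline.

Generates everything the real analysis consumes — a nested county/township
hierarchy, spatially autocorrelated predictor rasters, a categorical
land-cover map, a planted warm/cold-season pasture rule, a planted
log-linear density surface, county census tables and labelled seasonal
training samples — as a pure function of a seeded configuration.

The planted structure mirrors a transhumant alpine plateau: temperature
falls with elevation, greenness (NDVI) rises with growing-season rain and
falls with elevation, travel time to towns rises with elevation, and the
warm-season pastures of each township sit above a within-township elevation
quantile. True livestock density is exp(beta . standardized predictors),
rescaled to a target regional mean in standard sheep units (SSU) per km^2.
Admin units are rectangular tiles so that township-in-county nesting and
rasterization are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from .geodata import (
    AdminPolygon,
    GridSpec,
    Raster,
    area_raster,
    check_hierarchy,
    rasterize,
)

#: Land-cover class codes (GlobeLand30-like)
LANDCOVER_CODES = {
    "cropland": 10,
    "grassland": 30,
    "shrubland": 40,
    "wetland": 50,
    "water": 60,
    "bareland": 90,
}
SUITABLE_CLASSES = frozenset(
    {LANDCOVER_CODES["grassland"], LANDCOVER_CODES["shrubland"], LANDCOVER_CODES["wetland"]}
)

#: Vegetation-type codes for the grassland-type layer
VEGTYPE_CODES = {"alpine_steppe": 1, "alpine_meadow": 2, "subalpine_shrub": 3,
                 "temperate_desert": 4, "temperate_meadow": 5}

PREDICTOR_NAMES = (
    "DEM", "Tmp", "GStem", "Wtem", "GSpre", "Wpre", "SnowDays", "NDVI", "TravelTime",
)


def _default_beta() -> dict[str, float]:
    # Planted log-density effects: greenness attracts stock, elevation,
    # snow and remoteness repel it. NDVI and DEM dominate, as they do for
    # grazing systems on high plateaus.
    return {
        "DEM": -0.55,
        "Tmp": 0.25,
        "Wpre": -0.15,
        "SnowDays": -0.35,
        "NDVI": 0.95,
        "TravelTime": -0.45,
    }


@dataclass(frozen=True)
class LandscapeConfig:
    """Everything that determines a synthetic landscape, bit for bit."""

    seed: int = 0
    n_county_rows: int = 4
    n_county_cols: int = 6
    townships_per_county: int = 4
    spec: GridSpec = field(
        default_factory=lambda: GridSpec(
            origin_lon=92.0, origin_lat=35.0, pixel_size=15.0 / 3600.0,
            n_rows=200, n_cols=200,
        )
    )
    #: Gaussian correlation length of the noise fields, in pixels.
    smoothness: float = 25.0
    beta: Mapping[str, float] = field(default_factory=_default_beta)
    #: SD of multiplicative log-normal noise on county census totals.
    sigma_y: float = 0.3
    #: Within-township elevation quantile above which truth = warm season.
    warm_quantile: float = 0.5
    #: Probability that a training sample's season label is flipped.
    label_noise: float = 0.05
    #: Fraction of census SSUs attributed to cattle (1 cattle = 5 SSU).
    cattle_fraction: float = 0.55
    #: Expected fraction of pixels with a grazable land-cover class.
    suitability_fraction: float = 0.75
    #: Regional mean of planted density over suitable pixels, SSU/km^2.
    mean_density: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.warm_quantile < 1.0:
            raise ValueError("warm_quantile must lie strictly in (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0.0 <= self.cattle_fraction <= 1.0:
            raise ValueError("cattle_fraction must lie in [0, 1]")
        if self.sigma_y < 0:
            raise ValueError("sigma_y must be >= 0")
        if self.townships_per_county < 1:
            raise ValueError("townships_per_county must be >= 1")


@dataclass
class SyntheticTruth:
    """A complete generated study region with its planted ground truth."""

    config: LandscapeConfig
    predictors: dict[str, Raster]
    landcover: Raster
    vegtype: Raster
    true_density: Raster  # SSU/km^2, 0 on unsuitable pixels
    true_season: Raster  # 1 = warm, 0 = cold, nodata off the suitable mask
    counties: list[AdminPolygon]
    townships: list[AdminPolygon]
    county_raster: Raster
    township_raster: Raster
    county_codes: dict[str, int]
    township_codes: dict[str, int]
    exclusions: list = field(default_factory=list)

    @property
    def spec(self) -> GridSpec:
        return self.config.spec

    def suitable_mask(self) -> np.ndarray:
        lc = self.landcover.values
        return np.isin(lc, list(SUITABLE_CLASSES))


def _smooth_field(rng: np.random.Generator, spec: GridSpec, smoothness: float) -> np.ndarray:
    """Standardized Gaussian random field with the given correlation length."""
    noise = rng.standard_normal(spec.shape)
    f = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    return (f - f.mean()) / f.std()


def _tile_edges(n_pixels: int, n_tiles: int) -> np.ndarray:
    """Near-equal integer tile boundaries: [0, e1, ..., n_pixels]."""
    return np.round(np.linspace(0, n_pixels, n_tiles + 1)).astype(int)


def _township_grid(townships_per_county: int) -> tuple[int, int]:
    """Factor the township count into a near-square rows x cols sub-tiling."""
    r = int(math.isqrt(townships_per_county))
    while townships_per_county % r != 0:
        r -= 1
    return r, townships_per_county // r


def _build_admin(config: LandscapeConfig) -> tuple[list[AdminPolygon], list[AdminPolygon]]:
    spec = config.spec
    row_edges = _tile_edges(spec.n_rows, config.n_county_rows)
    col_edges = _tile_edges(spec.n_cols, config.n_county_cols)
    t_rows, t_cols = _township_grid(config.townships_per_county)
    if (np.diff(row_edges).min() < t_rows) or (np.diff(col_edges).min() < t_cols):
        raise ValueError(
            f"grid {spec.shape} too small for {config.n_county_rows}x{config.n_county_cols} "
            f"counties with {t_rows}x{t_cols} townships each"
        )

    def pixel_box(r0: int, r1: int, c0: int, c1: int):
        return box(
            spec.origin_lon + c0 * spec.pixel_size,
            spec.origin_lat - r1 * spec.pixel_size,
            spec.origin_lon + c1 * spec.pixel_size,
            spec.origin_lat - r0 * spec.pixel_size,
        )

    counties, townships = [], []
    for i in range(config.n_county_rows):
        for j in range(config.n_county_cols):
            cid = f"C{i * config.n_county_cols + j:02d}"
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            counties.append(AdminPolygon(cid, "county", pixel_box(r0, r1, c0, c1)))
            tr_edges = _tile_edges(r1 - r0, t_rows) + r0
            tc_edges = _tile_edges(c1 - c0, t_cols) + c0
            for ti in range(t_rows):
                for tj in range(t_cols):
                    tid = f"{cid}T{ti * t_cols + tj:d}"
                    townships.append(
                        AdminPolygon(
                            tid, "township",
                            pixel_box(tr_edges[ti], tr_edges[ti + 1],
                                      tc_edges[tj], tc_edges[tj + 1]),
                            parent_id=cid,
                        )
                    )
    check_hierarchy(counties, townships)
    return counties, townships


def generate_landscape(config: LandscapeConfig) -> SyntheticTruth:
    """Generate the full synthetic study region for a configuration.

    Identical configs give bit-identical outputs. Predictor fields are
    Gaussian-smoothed noise plus deterministic cross-variable trends; GStem
    is built as a near-duplicate of Tmp so that the collinearity screen has
    a planted |r| > 0.7 pair to remove.
    """
    spec = config.spec
    rng = np.random.default_rng(config.seed)
    counties, townships = _build_admin(config)

    f = {k: _smooth_field(rng, spec, config.smoothness) for k in
         ("relief", "t_noise", "rain", "wrain", "snow", "veg", "access", "lc")}

    dem = 4500.0 + 700.0 * f["relief"]
    dem_std = (dem - dem.mean()) / dem.std()
    # Tmp follows the lapse rate but carries enough independent weather
    # variation that distinct predictors stay below the |r| > 0.7 screen at
    # county level; GStem is the one planted near-duplicate (of Tmp).
    tmp = 2.0 - 3.5e-3 * (dem - 4500.0) + 2.2 * f["t_noise"]
    gstem = tmp + 8.0 + 0.3 * _smooth_field(rng, spec, config.smoothness)  # near-duplicate of Tmp
    wtem = tmp - 10.0 + 0.8 * _smooth_field(rng, spec, config.smoothness)
    gspre = 420.0 + 160.0 * f["rain"]
    wpre = 60.0 + 25.0 * f["wrain"]
    snow = np.clip(85.0 - 2.0 * (wtem - wtem.mean()) + 22.0 * f["snow"], 0.0, 151.0)
    ndvi = np.clip(
        0.45 + 0.12 * (gspre - gspre.mean()) / gspre.std() - 0.08 * dem_std + 0.08 * f["veg"],
        0.02, 0.95,
    )
    travel = np.clip(4.0 + 1.2 * dem_std + 1.9 * f["access"], 0.25, None)

    predictors = {
        "DEM": dem, "Tmp": tmp, "GStem": gstem, "Wtem": wtem, "GSpre": gspre,
        "Wpre": wpre, "SnowDays": snow, "NDVI": ndvi, "TravelTime": travel,
    }

    # Land cover: threshold a smooth field so the expected suitable fraction
    # matches config; suitable pixels are split grassland/shrubland/wetland.
    thresh = np.quantile(f["lc"], 1.0 - config.suitability_fraction)
    suitable = f["lc"] >= thresh
    lc = np.where(f["lc"] < thresh - 0.8, LANDCOVER_CODES["bareland"],
                  LANDCOVER_CODES["cropland"])
    lc = np.where(suitable, LANDCOVER_CODES["grassland"], lc)
    shrub = suitable & (f["veg"] > 0.9)
    wet = suitable & (f["wrain"] > 1.1)
    lc[shrub] = LANDCOVER_CODES["shrubland"]
    lc[wet] = LANDCOVER_CODES["wetland"]
    landcover = Raster(spec, lc.astype(np.int16))

    # Vegetation types on suitable land: meadow where green/wet, steppe where
    # high and dry, shrub under shrubland.
    veg = np.full(spec.shape, int(spec.nodata), dtype=np.int16)
    veg[suitable] = np.where(ndvi[suitable] > 0.45, VEGTYPE_CODES["alpine_meadow"],
                             VEGTYPE_CODES["alpine_steppe"])
    veg[shrub] = VEGTYPE_CODES["subalpine_shrub"]
    vegtype = Raster(spec, veg)

    county_raster, county_codes = rasterize(counties, spec)
    township_raster, township_codes = rasterize(townships, spec)

    # Planted seasonal truth: warm above the within-township DEM quantile,
    # among suitable pixels only.
    season = np.full(spec.shape, spec.nodata)
    tvals = township_raster.values
    for code in township_codes.values():
        sel = suitable & (tvals == code)
        if not sel.any():
            continue
        q = np.quantile(dem[sel], config.warm_quantile)
        season[sel] = (dem[sel] > q).astype(float)
    true_season = Raster(spec, season)

    # Planted log-linear density surface on suitable pixels.
    eta = np.zeros(spec.shape)
    for name, b in config.beta.items():
        x = predictors[name]
        eta += b * (x - x.mean()) / x.std()
    dens = np.exp(eta)
    if suitable.any():
        dens *= config.mean_density / dens[suitable].mean()
    dens = np.where(suitable, dens, 0.0)
    true_density = Raster(spec, dens)

    return SyntheticTruth(
        config=config,
        predictors={k: Raster(spec, v) for k, v in predictors.items()},
        landcover=landcover,
        vegtype=vegtype,
        true_density=true_density,
        true_season=true_season,
        counties=counties,
        townships=townships,
        county_raster=county_raster,
        township_raster=township_raster,
        county_codes=county_codes,
        township_codes=township_codes,
    )


def generate_census(
    truth: SyntheticTruth,
    units: list[AdminPolygon] | None = None,
    config: LandscapeConfig | None = None,
    level: str = "county",
) -> pd.DataFrame:
    """Integrate the planted density into unit census tables.

    Unit SSU total = sum(true_density * pixel_area) over the unit's suitable
    pixels, perturbed by exp(N(0, sigma_y)). Head counts follow the standard
    sheep unit rule (1 cattle = 5 SSU, 1 sheep = 1 SSU): cattle head is
    cattle_fraction of SSUs divided by 5, the sheep head the remainder, both
    integers with SSU = 5*cattle + sheep re-enforced after rounding. Units
    with no suitable pixels are flagged ``is_agricultural`` and carry zero
    stock.

    Township tables (``level="township"``) use an independent noise stream so
    they act as external validation data, as township censuses do.
    """
    config = config or truth.config
    if units is None:
        units = truth.counties if level == "county" else truth.townships
    zone = truth.county_raster if level == "county" else truth.township_raster
    codes = truth.county_codes if level == "county" else truth.township_codes
    suitable = truth.suitable_mask()
    areas = area_raster(truth.spec).values
    dens = truth.true_density.values

    stream = 1 if level == "county" else 2
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7_000_003, stream)))
    rows = []
    for u in units:
        sel = suitable & (zone.values == codes[u.unit_id])
        ssu_exact = float((dens[sel] * areas[sel]).sum())
        agricultural = not bool(sel.any())
        noise = math.exp(rng.normal(0.0, config.sigma_y)) if config.sigma_y > 0 else 1.0
        ssu = 0.0 if agricultural else ssu_exact * noise
        cattle = int(round(config.cattle_fraction * ssu / 5.0))
        sheep = max(0, int(round(ssu - 5.0 * cattle)))
        rows.append(
            {
                "unit_id": u.unit_id,
                "level": level,
                "cattle_head": cattle,
                "sheep_head": sheep,
                "ssu": 5 * cattle + sheep,
                "ssu_exact": ssu_exact,
                "is_agricultural": agricultural,
                "year": 2020,
            }
        )
    return pd.DataFrame(rows)


def generate_season_samples(
    truth: SyntheticTruth,
    n_samples: int,
    config: LandscapeConfig | None = None,
) -> pd.DataFrame:
    """Draw labelled warm/cold training samples from the suitable pixels.

    Sampling is uniform without replacement; labels are the planted truth,
    independently flipped with probability ``label_noise``. Each sample
    carries its township id and pixel location.
    """
    config = config or truth.config
    suitable = truth.suitable_mask()
    season_defined = suitable & truth.true_season.valid_mask()
    idx = np.flatnonzero(season_defined)
    if n_samples > idx.size:
        raise ValueError(f"requested {n_samples} samples but only {idx.size} suitable pixels")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7_000_019)))
    chosen = rng.choice(idx, size=n_samples, replace=False)
    rows_i, cols_i = np.unravel_index(chosen, truth.spec.shape)
    labels = truth.true_season.values[rows_i, cols_i].astype(int)
    if config.label_noise > 0:
        flips = rng.random(n_samples) < config.label_noise
        labels = np.where(flips, 1 - labels, labels)
    tw = truth.township_raster.values[rows_i, cols_i]
    code_to_id = {v: k for k, v in truth.township_codes.items()}
    return pd.DataFrame(
        {
            "row": rows_i,
            "col": cols_i,
            "lon": truth.spec.col_center_lon(cols_i),
            "lat": truth.spec.row_center_lat(rows_i),
            "label": labels,
            "township_id": [code_to_id[int(t)] for t in tw],
        }
    )
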