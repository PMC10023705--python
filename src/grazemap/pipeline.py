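"""Configuration and orchestration of the five-stage mapping workflow.

Stages — simulate, mask, classify-seasons, fit-density, disaggregate,
validate — communicate only through files in the run directory, so any stage
can be rerun in isolation. ``run_all`` executes them in order and writes a
manifest (config hash, seeds, package versions, per-stage wall time).
All randomness flows from the seeds named in the config; rerunning with the
same config reproduces byte-identical product rasters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dasymetric import SEASONS, SPECIES, build_products
from .density import (
    DENSITY_PREDICTORS,
    county_response,
    fit_density_model,
    predict_pixel_density,
    screen_correlated,
)
from .geodata import (
    GridSpec,
    Raster,
    rasterize,
    read_admin_geojson,
    read_raster,
    write_admin_geojson,
    write_raster,
)
from .mask import ExclusionZone, PastureMask, SuitabilityRule, build_mask
from .seasonal import (
    CLASSIFIER_PREDICTORS,
    fit_season_classifier,
    predict_season_map,
    relative_stack,
)
from .synth import (
    PREDICTOR_NAMES,
    LandscapeConfig,
    generate_census,
    generate_landscape,
    generate_season_samples,
)
from .validation import aggregate_to_units, score

logger = logging.getLogger(__name__)

STAGES = ("simulate", "mask", "classify-seasons", "fit-density", "disaggregate", "validate")


@dataclass
class RunConfig:
    """Everything a full run depends on; seeds are explicit, never wall-clock."""

    out_dir: Path = Path("grazemap_run")
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    n_season_samples: int = 2000
    classifier_predictors: tuple[str, ...] = CLASSIFIER_PREDICTORS
    density_predictors: tuple[str, ...] = DENSITY_PREDICTORS
    correlation_threshold: float = 0.7
    n_folds: int = 10
    model_seed: int = 0
    ssu_per_cattle: float = 5.0
    classifier_trees: int = 100
    regressor_trees: int = 200

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.ssu_per_cattle <= 0:
            raise ValueError("ssu_per_cattle must be positive")
        unknown = set(self.classifier_predictors + self.density_predictors) - set(PREDICTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown predictor names: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["landscape"]["spec"] = dataclasses.asdict(self.landscape.spec)
        d["landscape"]["beta"] = dict(self.landscape.beta)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        land = raw.pop("landscape", {})
        spec = land.pop("spec", None)
        if spec is not None:
            land["spec"] = GridSpec(**spec)
        kwargs = dict(raw)
        if land:
            kwargs["landscape"] = LandscapeConfig(**land)
        for key in ("classifier_predictors", "density_predictors"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# file-level helpers


def _load_admin(cfg: RunConfig, level: str):
    path = cfg.out_dir / f"{level[:-1] if level.endswith('s') else level}s.geojson"
    return read_admin_geojson(path, "county" if "count" in level else "township")


def _zone_raster(cfg: RunConfig, level: str) -> tuple[Raster, dict[str, int]]:
    units = _load_admin(cfg, level)
    spec = read_raster(cfg.out_dir / "landcover.tif").spec
    return rasterize(units, spec)


def _load_predictors(cfg: RunConfig, names) -> dict[str, Raster]:
    return {n: read_raster(cfg.out_dir / "predictors" / f"{n}.tif") for n in names}


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig) -> None:
    """Generate the synthetic study region and write it as pipeline inputs."""
    out = cfg.out_dir
    (out / "predictors").mkdir(parents=True, exist_ok=True)
    truth = generate_landscape(cfg.landscape)
    for name, rast in truth.predictors.items():
        write_raster(rast, out / "predictors" / f"{name}.tif")
    write_raster(truth.landcover, out / "landcover.tif")
    write_raster(truth.vegtype, out / "vegtype.tif")
    write_raster(truth.true_density, out / "true_density.tif")
    write_raster(truth.true_season, out / "true_season.tif")
    write_admin_geojson(truth.counties, out / "counties.geojson")
    write_admin_geojson(truth.townships, out / "townships.geojson")
    generate_census(truth, level="county").to_csv(out / "census_county.csv", index=False)
    generate_census(truth, level="township").to_csv(out / "census_township.csv", index=False)
    generate_season_samples(truth, cfg.n_season_samples).to_csv(
        out / "season_samples.csv", index=False
    )


def stage_mask(cfg: RunConfig, exclusions: list[ExclusionZone] | None = None) -> PastureMask:
    landcover = read_raster(cfg.out_dir / "landcover.tif")
    pm = build_mask(landcover, SuitabilityRule(), exclusions or [])
    write_raster(pm.raster, cfg.out_dir / "pasture_mask.tif", dtype=np.uint8)
    prov = pd.DataFrame(
        [{"source": s, "pixels_removed": n} for s, n in pm.provenance.items()],
        columns=["source", "pixels_removed"],
    )
    prov.to_csv(cfg.out_dir / "mask_provenance.csv", index=False)
    return pm


def stage_classify(cfg: RunConfig) -> dict:
    mask = read_raster(cfg.out_dir / "pasture_mask.tif")
    township_raster, _ = _zone_raster(cfg, "townships")
    predictors = _load_predictors(cfg, cfg.classifier_predictors)
    stack = relative_stack(predictors, township_raster, mask, cfg.classifier_predictors)
    samples = pd.read_csv(cfg.out_dir / "season_samples.csv")
    models, report = fit_season_classifier(
        samples, stack, seed=cfg.model_seed, n_folds=cfg.n_folds,
        n_estimators=cfg.classifier_trees,
    )
    season_map = predict_season_map(models, stack, mask)
    write_raster(season_map, cfg.out_dir / "season_map.tif", dtype=np.uint8)
    with open(cfg.out_dir / "classifier_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return report.to_dict()


def stage_density(cfg: RunConfig) -> dict:
    mask = read_raster(cfg.out_dir / "pasture_mask.tif")
    county_raster, county_codes = _zone_raster(cfg, "counties")
    predictors = _load_predictors(cfg, cfg.density_predictors)
    census = pd.read_csv(cfg.out_dir / "census_county.csv")
    samples = county_response(census, mask, county_raster, county_codes,
                              predictors, cfg.density_predictors)
    retained, dropped = screen_correlated(
        samples.table[list(cfg.density_predictors)], samples.y, cfg.correlation_threshold
    )
    folds = min(cfg.n_folds, len(samples.table))
    if folds < cfg.n_folds:
        logger.warning("only %d counties: density CV reduced to %d folds",
                       len(samples.table), folds)
    model = fit_density_model(samples, seed=cfg.model_seed, n_folds=folds,
                              n_estimators=cfg.regressor_trees,
                              predictor_names=tuple(retained))
    pred = predict_pixel_density(model, predictors, mask)
    write_raster(pred.mean_density, cfg.out_dir / "density_mean.tif")
    write_raster(pred.cv, cfg.out_dir / "QTP_CV_Livestock.tif")
    metrics = model.metrics_dict()
    metrics["screened_out"] = [list(map(str, p[:2])) for p in dropped]
    metrics["excluded_counties"] = samples.excluded
    with open(cfg.out_dir / "density_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    return metrics


def stage_disaggregate(cfg: RunConfig):
    mask = read_raster(cfg.out_dir / "pasture_mask.tif")
    county_raster, county_codes = _zone_raster(cfg, "counties")
    season_map = read_raster(cfg.out_dir / "season_map.tif")
    weights = read_raster(cfg.out_dir / "density_mean.tif")
    census = pd.read_csv(cfg.out_dir / "census_county.csv")
    product = build_products(census, weights, season_map, mask,
                             county_raster, county_codes, year=2020)
    for (sp, se), rast in product.rasters.items():
        write_raster(rast, cfg.out_dir / product.filename(sp, se), dtype=np.float32)
    product.audit.to_csv(cfg.out_dir / "conservation_audit.csv", index=False)
    return product


def stage_validate(cfg: RunConfig) -> dict:
    township_raster, township_codes = _zone_raster(cfg, "townships")
    census = pd.read_csv(cfg.out_dir / "census_township.csv")
    census = census[~census["is_agricultural"]]
    reports = {}
    for sp in SPECIES:
        col = {"livestock": "ssu", "cattle": "cattle_head", "sheep": "sheep_head"}[sp]
        truth_totals = census.set_index("unit_id")[col].astype(float)
        for se in SEASONS:
            fname = f"QTP_Da_2020_{sp.capitalize()}_{se.capitalize()}-season.tif"
            rast = read_raster(cfg.out_dir / fname)
            agg = aggregate_to_units(rast, township_raster, township_codes)
            rep = score(agg, truth_totals, species=sp, season=se)
            reports[f"{sp}_{se}"] = rep.to_dict()
            rep.pairs.to_csv(cfg.out_dir / f"validation_pairs_{sp}_{se}.csv", index=False)
    with open(cfg.out_dir / "validation.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    return reports


def run_all(cfg: RunConfig) -> Path:
    """Run every stage in order; returns the artifact directory."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    timings = {}
    stage_fns = {
        "simulate": stage_simulate,
        "mask": stage_mask,
        "classify-seasons": stage_classify,
        "fit-density": stage_density,
        "disaggregate": stage_disaggregate,
        "validate": stage_validate,
    }
    for name in STAGES:
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)
        try:
            stage_fns[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        timings[name] = round(time.perf_counter() - t0, 3)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seeds": {"landscape": cfg.landscape.seed, "model": cfg.model_seed},
        "versions": {"grazemap": __version__, "numpy": np.__version__},
        "stage_seconds": timings,
    }
    with open(cfg.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return cfg.out_dir
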