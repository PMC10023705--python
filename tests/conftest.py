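"""Shared fixtures: a small fast landscape and full pipeline runs.

All landscapes are generated programmatically (pure functions of their
seeded configs), so no data files ship with the repository.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from grazemap.geodata import GridSpec, Raster
from grazemap.pipeline import RunConfig, run_all
from grazemap.synth import LandscapeConfig, generate_landscape

logging.getLogger("grazemap").setLevel(logging.ERROR)

#: Small fixture: 64x64 grid, 4 counties x 4 townships, fixed seed.
SMALL_LANDSCAPE = LandscapeConfig(
    seed=0,
    n_county_rows=2,
    n_county_cols=2,
    townships_per_county=4,
    spec=GridSpec(92.0, 35.0, 15.0 / 3600.0, 64, 64),
)


def small_run_config(out_dir) -> RunConfig:
    return RunConfig(out_dir=out_dir, landscape=SMALL_LANDSCAPE, n_season_samples=600)


@pytest.fixture(scope="session")
def small_truth():
    return generate_landscape(SMALL_LANDSCAPE)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Full pipeline artifacts on the small fixture."""
    out = tmp_path_factory.mktemp("small_run")
    cfg = small_run_config(out)
    run_all(cfg)
    return cfg


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Full pipeline at the default study conditions (200x200, 24 counties)."""
    out = tmp_path_factory.mktemp("study_run")
    cfg = RunConfig(out_dir=out)
    run_all(cfg)
    return cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_raster(values, origin=(92.0, 35.0), pixel_size=0.01, nodata=-9999.0) -> Raster:
    values = np.asarray(values)
    spec = GridSpec(origin[0], origin[1], pixel_size,
                    values.shape[0], values.shape[1], nodata=nodata)
    return Raster(spec, values)
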