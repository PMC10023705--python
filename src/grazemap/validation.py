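"""Cross-scale validation of disaggregated products.

The products are fitted from county censuses; validation re-aggregates the
pixel values to the finer township level and scores them against independent
township census tables with the coefficient of determination
R^2 = 1 - SS_res/SS_tot (which can go negative) and the mean absolute error,
both on raw totals (head or SSU), not densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geodata import Raster, zonal_stat

logger = logging.getLogger(__name__)


@dataclass
class ValidationReport:
    species: str
    season: str
    n_units: int
    r_squared: float
    mae: float
    pairs: pd.DataFrame  # unit_id, aggregated, census
    unmatched: list[str]

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "season": self.season,
            "n_units": self.n_units,
            "r_squared": self.r_squared,
            "mae": self.mae,
            "unmatched": self.unmatched,
        }


def aggregate_to_units(
    product_raster: Raster,
    unit_raster: Raster,
    unit_codes: dict[str, int],
) -> pd.Series:
    """Per-unit pixel sums of a product raster.

    Units with zero product pixels report 0 (their absence from the raster
    is logged, not an error).
    """
    table = zonal_stat(product_raster, unit_raster, None, "sum", unit_codes)
    sums = {}
    for uid in unit_codes:
        if uid in table.empty_units:
            logger.info("unit %s has no product pixels; aggregate set to 0", uid)
            sums[uid] = 0.0
        else:
            sums[uid] = table.data[uid]["value"]
    return pd.Series(sums, name="aggregated")


def score(
    aggregated: pd.Series,
    census: pd.Series,
    species: str = "livestock",
    season: str = "warm",
) -> ValidationReport:
    """Score aggregated totals against census totals paired by unit id.

    Unmatched ids on either side are reported and excluded. R^2 is the
    coefficient of determination on raw totals; a constant census makes it
    undefined (NaN, flagged in the log).
    """
    common = sorted(set(aggregated.index) & set(census.index))
    unmatched = sorted(set(aggregated.index) ^ set(census.index))
    if len(common) < 2:
        raise ValueError("need at least 2 paired units to score")
    if unmatched:
        logger.warning("%d unmatched unit ids excluded from scoring", len(unmatched))
    a = aggregated.loc[common].to_numpy(dtype=float)
    c = census.loc[common].to_numpy(dtype=float)
    resid = c - a
    ss_res = float((resid**2).sum())
    ss_tot = float(((c - c.mean()) ** 2).sum())
    if ss_tot == 0:
        logger.warning("constant census totals: R^2 undefined")
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    mae = float(np.abs(resid).mean())
    pairs = pd.DataFrame({"unit_id": common, "aggregated": a, "census": c})
    return ValidationReport(species, season, len(common), r2, mae, pairs, unmatched)
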