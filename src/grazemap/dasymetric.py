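"""Mass-conserving dasymetric disaggregation of county census totals.

Each county's census total (in head or SSU) is spread over the pixels of one
seasonal pasture class in proportion to the model-predicted density weights:

    v_ij = total_c * w_ij / sum(w over the county's season pixels),

so the pixel sum returns the census total exactly (the last target pixel
absorbs the residual float error). Livestock are assumed to sit entirely on
warm-season pastures in the warm season and on cold-season pastures in the
cold season, so the warm and cold products have disjoint support while both
conserve the same county totals.

Degenerate counties follow a fallback ladder: zero total weight on the
season's pixels -> uniform weights over those pixels; no pixels of that
season's class -> spread over the county's full mask for that season (with a
warning); no mask pixels at all -> excluded (agricultural-type) and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import GridMismatchError, Raster
from .seasonal import COLD, WARM

logger = logging.getLogger(__name__)

SEASONS = ("warm", "cold")
SPECIES = ("livestock", "cattle", "sheep")

#: Conservation tolerance, relative to max(total, 1).
CONSERVATION_RTOL = 1e-9


def disaggregate_county(
    total: float,
    weights: np.ndarray,
    target: np.ndarray,
) -> np.ndarray:
    """Spread ``total`` over ``target`` pixels proportionally to ``weights``.

    ``weights`` and ``target`` (boolean) are flat arrays of equal length.
    Zero total weight on a non-empty target falls back to uniform weights.
    Returns a float64 array, zero off-target, summing exactly to ``total``.
    """
    if total < 0:
        raise ValueError(f"census total must be nonnegative, got {total}")
    weights = np.asarray(weights, dtype=np.float64)
    if np.any(~np.isfinite(weights[target])) or np.any(weights[target] < 0):
        raise ValueError("weights must be finite and nonnegative on the target set")
    out = np.zeros(weights.shape, dtype=np.float64)
    idx = np.flatnonzero(target)
    if idx.size == 0 or total == 0:
        return out
    w = weights[idx]
    wsum = w.sum()
    if wsum <= 0:
        w = np.ones_like(w)
        wsum = w.sum()
    vals = total * (w / wsum)
    # pin the pixel sum to the census total exactly
    vals[-1] += total - vals.sum()
    out[idx] = vals
    return out


@dataclass
class SeasonalLivestockProduct:
    """Six disaggregated rasters, {livestock, cattle, sheep} x {warm, cold}."""

    rasters: dict[tuple[str, str], Raster]  # (species, season) -> raster
    audit: pd.DataFrame  # county x season x species conservation audit
    skipped_counties: dict[str, str] = field(default_factory=dict)
    year: int | None = None

    def raster(self, species: str, season: str) -> Raster:
        return self.rasters[(species, season)]

    def filename(self, species: str, season: str) -> str:
        yr = self.year if self.year is not None else "XXXX"
        return f"QTP_Da_{yr}_{species.capitalize()}_{season.capitalize()}-season.tif"


def build_products(
    census: pd.DataFrame,
    weights: Raster | dict[str, Raster],
    season_map: Raster,
    mask: Raster,
    county_raster: Raster,
    county_codes: dict[str, int],
    year: int | None = None,
) -> SeasonalLivestockProduct:
    """Disaggregate county census totals into the six seasonal rasters.

    ``census`` needs unit_id, cattle_head, sheep_head (+ optional
    is_agricultural); totals are SSU for livestock (5*cattle + sheep) and
    head for cattle/sheep. ``weights`` is the predicted mean-density raster,
    or a per-species dict of weight rasters. An audit row records the census
    total, pixel sum and relative error for every (county, season, species).
    """
    from .density import to_ssu

    if isinstance(weights, Raster):
        weights = {sp: weights for sp in SPECIES}
    spec = mask.spec
    for r in (season_map, county_raster, *weights.values()):
        if not r.spec.same_grid(spec):
            raise GridMismatchError("all rasters must share the analysis grid")

    masked = (mask.values == 1).ravel()
    season_vals = season_map.values.ravel()
    county_vals = county_raster.values.ravel()
    season_target = {"warm": masked & (season_vals == WARM),
                     "cold": masked & (season_vals == COLD)}

    out = {
        (sp, se): np.zeros(spec.shape, dtype=np.float64).ravel()
        for sp in SPECIES for se in SEASONS
    }
    audit_rows = []
    skipped: dict[str, str] = {}
    known = {str(r.unit_id) for r in census.itertuples(index=False)}
    for cid in county_codes:
        if cid not in known:
            logger.warning("county %s absent from the census table; skipped", cid)
            skipped[cid] = "absent from census"
    for rec in census.itertuples(index=False):
        cid = str(rec.unit_id)
        if cid not in county_codes:
            logger.warning("census county %s not in the county raster; skipped", cid)
            skipped[cid] = "not in county raster"
            continue
        if getattr(rec, "is_agricultural", False):
            skipped[cid] = "agricultural county"
            continue
        in_county = county_vals == county_codes[cid]
        if not (in_county & masked).any():
            skipped[cid] = "no pasture mask pixels"
            logger.warning("county %s has no mask pixels; excluded", cid)
            continue
        totals = {
            "livestock": float(to_ssu(rec.cattle_head, rec.sheep_head)),
            "cattle": float(rec.cattle_head),
            "sheep": float(rec.sheep_head),
        }
        for se in SEASONS:
            target = in_county & season_target[se]
            if not target.any():
                logger.warning(
                    "county %s has no %s-season pixels; falling back to its full mask", cid, se
                )
                target = in_county & masked
            for sp in SPECIES:
                w = weights[sp].values.ravel()
                vals = disaggregate_county(totals[sp], np.where(masked, w, 0.0), target)
                out[(sp, se)] += vals
                pix_sum = float(vals.sum())
                audit_rows.append(
                    {
                        "county_id": cid, "season": se, "species": sp,
                        "census_total": totals[sp], "pixel_sum": pix_sum,
                        "rel_error": abs(pix_sum - totals[sp]) / max(totals[sp], 1.0),
                    }
                )

    rasters = {k: Raster(spec, v.reshape(spec.shape)) for k, v in out.items()}
    audit = pd.DataFrame(
        audit_rows,
        columns=["county_id", "season", "species", "census_total", "pixel_sum", "rel_error"],
    )
    bad = audit[audit["rel_error"] > CONSERVATION_RTOL]
    if len(bad):  # pragma: no cover - conservation is enforced by construction
        raise AssertionError(f"conservation violated for {len(bad)} county/season/species rows")
    return SeasonalLivestockProduct(rasters, audit, skipped, year=year)
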