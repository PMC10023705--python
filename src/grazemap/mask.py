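"""Suitable-pasture masking.

A pixel is grazable iff its land-cover class is one of the suitable classes
(grassland, shrubland, wetland by default) and its center lies outside every
exclusion polygon (nature-reserve core zones, grazing-ban areas). Removal
provenance is tracked per exclusion source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .geodata import Raster, ZonalTable, zonal_stat
from .synth import SUITABLE_CLASSES


@dataclass(frozen=True)
class SuitabilityRule:
    """Set of land-cover codes deemed grazable."""

    suitable_class_codes: frozenset[int] = SUITABLE_CLASSES

    def __post_init__(self) -> None:
        if not self.suitable_class_codes:
            raise ValueError("suitability rule must name at least one land-cover class")
        object.__setattr__(self, "suitable_class_codes", frozenset(self.suitable_class_codes))


@dataclass
class ExclusionZone:
    """An area where grazing is banned, with a provenance label."""

    source: str
    geometry: BaseGeometry


@dataclass
class PastureMask:
    raster: Raster  # 1 = suitable, 0 = not
    provenance: dict[str, int] = field(default_factory=dict)  # source -> pixels removed

    @property
    def suitable_count(self) -> int:
        return int((self.raster.values == 1).sum())


def build_mask(
    landcover: Raster,
    rule: SuitabilityRule | None = None,
    exclusions: Sequence[ExclusionZone] = (),
) -> PastureMask:
    """Binary suitability mask from land cover minus exclusion polygons.

    Removals are attributed to the first exclusion (in input order) whose
    polygon contains the pixel center, so provenance is deterministic when
    exclusion polygons overlap.
    """
    rule = rule or SuitabilityRule()
    valid = landcover.valid_mask()
    if not valid.any():
        raise ValueError("land-cover raster holds no data")
    suitable = valid & np.isin(landcover.values, list(rule.suitable_class_codes))

    provenance: dict[str, int] = {}
    if exclusions:
        lon, lat = landcover.spec.center_coords()
        flat_lon, flat_lat = lon.ravel(), lat.ravel()
        unattributed = suitable.copy().ravel()
        for zone in exclusions:
            inside = shapely.contains_xy(zone.geometry, flat_lon, flat_lat)
            removed_here = unattributed & inside
            provenance[zone.source] = provenance.get(zone.source, 0) + int(removed_here.sum())
            unattributed &= ~inside
        suitable = unattributed.reshape(suitable.shape)

    out = np.where(valid, suitable.astype(np.int8), np.int8(0))
    return PastureMask(Raster(landcover.spec, out), provenance)


def vegetation_fractions(
    vegtype: Raster,
    zone_raster: Raster,
    mask: PastureMask | Raster,
    zone_codes: dict[str, int] | None = None,
) -> ZonalTable:
    """Per-zone fraction of masked pixels in each vegetation class.

    Fractions over the classes present in a zone sum to 1; zones with zero
    masked pixels are flagged with NaN fractions.
    """
    mask_raster = mask.raster if isinstance(mask, PastureMask) else mask
    classes = np.unique(vegtype.values[vegtype.valid_mask() & (mask_raster.values == 1)])
    table: ZonalTable | None = None
    for cls in classes:
        indicator = Raster(
            vegtype.spec,
            np.where(vegtype.valid_mask(), (vegtype.values == cls).astype(float),
                     vegtype.spec.nodata),
        )
        t = zonal_stat(indicator, zone_raster, mask_raster, "mean", zone_codes,
                       variable=f"class_{int(cls)}")
        if table is None:
            table = t
        else:
            for uid in t.data:
                table.data[uid].update(t.data[uid])
    if table is None:
        raise ValueError("no vegetation classes found under the mask")
    table.stat = "fraction"
    return table
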