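"""Prescribed-fire candidate polygons from per-date binary burned rasters.

Burned-area products arrive as one binary raster per acquisition date
(1 = burned). The dates of a year are merged with a logical OR, burned cells
are vectorized (8-connected), and the same filtering ledger as for
mechanical treatments is applied: slivers (< 1 ha) out, anything intersecting
a mapped wildfire perimeter out, polygons mostly over non-forest out. What
survives has a high chance of being a prescribed-fire unit in forested land.
"""

from __future__ import annotations

import numpy as np

from .polygons import filter_polygons, threshold_polygonize
from .raster_core import MultibandRaster, PolygonSet, assert_same_grid

__all__ = ["merge_burned", "prescribed_fire_polygons"]


def merge_burned(rasters: list[MultibandRaster]) -> MultibandRaster:
    """Logical OR of binary burned rasters; nodata only where all are nodata."""
    if not rasters:
        raise ValueError("need at least one burned raster")
    first = rasters[0]
    for other in rasters[1:]:
        assert_same_grid(first, other)
    planes = np.stack([r.values[0] for r in rasters])
    finite = np.isfinite(planes)
    vals = np.unique(planes[finite])
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("burned rasters must be binary (0/1/nodata)")
    any_burn = np.any(np.where(finite, planes, 0.0) == 1.0, axis=0)
    any_finite = finite.any(axis=0)
    out = np.where(any_finite, any_burn.astype(float), np.nan)
    return MultibandRaster(first.grid, ["burned"], out[None])


def prescribed_fire_polygons(merged: MultibandRaster, wildfires: PolygonSet,
                             forest_mask: MultibandRaster,
                             min_area_ha: float = 1.0
                             ) -> tuple[PolygonSet, PolygonSet]:
    """Vectorize burned cells and filter; survivors typed ``prescribed_fire``.

    Returns (accepted, removed-audit) sets, sharing the filtering rules of
    the mechanical-treatment pipeline.
    """
    vals = np.unique(merged.values[0][np.isfinite(merged.values[0])])
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("merged raster must be binary")
    candidates = threshold_polygonize(merged, 0.5)
    accepted, removed = filter_polygons(candidates, wildfires, forest_mask,
                                        min_area_ha)
    if len(accepted):
        accepted.attributes["type"] = "prescribed_fire"
    return accepted, removed
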