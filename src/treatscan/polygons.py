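"""Candidate treatment polygons: thresholding, filtering ledger, density.

Cells of the segment-mean-vote surface above a threshold are vectorized into
8-connected polygons (unions of cell-boundary squares). Candidates then pass
a filtering ledger applied in order:

1. slivers — polygons smaller than 1 ha are removed,
2. wildfire overlap — any polygon intersecting a wildfire perimeter of the
   target period is removed (boundary contact counts as intersecting),
3. non-forest — polygons with more than half their area over non-forest
   cells are removed (a deterministic surrogate for the visual deletion of
   agricultural/non-forested false positives),
4. optional user-supplied exclusion polygons (clouds, shadows, snow, ...).

Removed polygons are retained in an audit set with their removal reason, so
every filter stage is machine-checkable. A kernel-density summary of
accepted treatments (quartic kernel, 1-km radius on a 100-m grid, densities
in points per square km) reproduces the treatment-density mapping step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import convolve, label as cc_label

from .raster_core import Grid, MultibandRaster, PolygonSet, rasterize_polygons

__all__ = ["threshold_polygonize", "filter_polygons", "kernel_density",
           "suggest_threshold"]

_EIGHT = np.ones((3, 3), dtype=int)
_SQM_PER_HA = 10_000.0


def _cells_to_geometry(rows: np.ndarray, cols: np.ndarray, grid: Grid):
    """Union of cell-boundary squares for one connected component."""
    x0 = grid.origin_x + cols * grid.cell_size
    y1 = grid.origin_y - rows * grid.cell_size
    boxes = shapely.box(x0, y1 - grid.cell_size, x0 + grid.cell_size, y1)
    return shapely.union_all(boxes)


def threshold_polygonize(segvals: MultibandRaster, threshold: float) -> PolygonSet:
    """Polygons of 8-connected cells with value strictly above the threshold.

    Each polygon row carries ``mean_vote`` (mean cell value over its cells)
    and ``area_ha``. Nothing above the threshold yields an empty set.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    band = segvals.values[0]
    above = np.isfinite(band) & (band > threshold)
    labeled, n = cc_label(above, structure=_EIGHT)
    geoms, votes, areas = [], [], []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(labeled == k)
        geoms.append(_cells_to_geometry(rows, cols, segvals.grid))
        votes.append(float(band[rows, cols].mean()))
        areas.append(rows.size * segvals.grid.cell_area_ha)
    attrs = pd.DataFrame({
        "mean_vote": votes,
        "area_ha": areas,
        "type": ["candidate"] * n,
        "removal_reason": ["none"] * n,
    })
    return PolygonSet(geoms, attrs, segvals.grid.crs_id)


def filter_polygons(candidates: PolygonSet, wildfires: PolygonSet,
                    forest_mask: MultibandRaster, min_area_ha: float = 1.0,
                    exclusions: PolygonSet | None = None
                    ) -> tuple[PolygonSet, PolygonSet]:
    """Apply the filtering ledger; return (accepted, removed-audit) sets.

    Filters run in order (sliver, wildfire overlap, >50% non-forest, user
    exclusions); each removed polygon records the first reason that fired.
    Accepted ∪ removed equals the input.
    """
    n = len(candidates)
    reasons = np.array(["none"] * n, dtype=object)
    areas = candidates.attributes["area_ha"].to_numpy() if n else np.array([])

    for i in range(n):
        if areas[i] < min_area_ha:
            reasons[i] = "sliver"
    if len(wildfires):
        fire_union = shapely.union_all(wildfires.geometries)
        for i in range(n):
            if reasons[i] == "none" and candidates.geometries[i].intersects(fire_union):
                reasons[i] = "wildfire_overlap"
    forest = forest_mask.values[0] == 1.0
    grid = forest_mask.grid
    for i in range(n):
        if reasons[i] != "none":
            continue
        cells = rasterize_polygons([candidates.geometries[i]], grid)
        total = int(cells.sum())
        if total == 0 or (cells & ~forest).sum() / total > 0.5:
            reasons[i] = "nonforest"
    if exclusions is not None and len(exclusions):
        excl_union = shapely.union_all(exclusions.geometries)
        for i in range(n):
            if reasons[i] == "none" and candidates.geometries[i].intersects(excl_union):
                reasons[i] = "user"

    attrs = candidates.attributes.copy()
    attrs["removal_reason"] = reasons
    full = PolygonSet(candidates.geometries, attrs, candidates.crs_id)
    keep = reasons == "none"
    return full.subset(keep), full.subset(~keep)


def suggest_threshold(segvals: MultibandRaster, known: PolygonSet,
                      percentile: float = 5.0) -> float:
    """Threshold suggestion: the 5th percentile of segment-mean values
    sampled inside known-treatment polygons."""
    if len(known) == 0:
        raise ValueError("need at least one known-treatment polygon")
    cells = rasterize_polygons(known, segvals.grid)
    vals = segvals.values[0][cells]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("known polygons cover no finite cells")
    return float(np.percentile(vals, percentile))


def kernel_density(treatments: PolygonSet, grid: Grid | None = None,
                   cell_size: float = 100.0, radius: float = 1000.0
                   ) -> MultibandRaster:
    """Quartic-kernel density of treated ground, in points per km².

    Treatments are rasterized to a binary coarse grid (default 100-m cells),
    treated-cell centers become points, and a quartic (biweight) kernel of
    the given search radius is summed over them: K(d) = 3/(πR²)(1-(d/R)²)²
    for d < R. The output grid is padded by one radius so the kernel mass is
    conserved at scene edges. An empty input yields an all-zero raster.
    """
    if grid is None:
        if len(treatments) == 0:
            raise ValueError("need a grid to rasterize an empty treatment set onto")
        minx, miny, maxx, maxy = shapely.union_all(treatments.geometries).bounds
    else:
        minx, miny, maxx, maxy = grid.bounds
    pad = radius
    n_cols = int(np.ceil((maxx - minx + 2 * pad) / cell_size))
    n_rows = int(np.ceil((maxy - miny + 2 * pad) / cell_size))
    coarse = Grid(minx - pad, maxy + pad, cell_size, n_rows, n_cols,
                  treatments.crs_id)
    binary = rasterize_polygons(treatments, coarse).astype(float)

    r_cells = int(np.floor(radius / cell_size))
    dr = np.arange(-r_cells, r_cells + 1)
    dx, dy = np.meshgrid(dr * cell_size, dr * cell_size)
    d = np.hypot(dx, dy)
    r_km = radius / 1000.0
    kern = np.where(d < radius, 3.0 / (np.pi * r_km**2)
                    * (1.0 - (d / radius) ** 2) ** 2, 0.0)
    density = convolve(binary, kern, mode="constant", cval=0.0)
    return MultibandRaster(coarse, ["treatment_density"], density[None])
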