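"""Synthetic paired-year scenes with planted, georeferenced treatment truth.

Real treatment mapping starts from two co-registered multiband satellite
images (bands B, G, R, NIR, SWIR) taken one year apart. This module fabricates
such a pair plus every ancillary input the pipeline needs — forest mask,
treatment truth polygons, wildfire perimeters, per-date burned-area rasters —
so that every downstream stage is testable without real imagery.

What is emulated
----------------
* spatially autocorrelated forest reflectance (Gaussian-filtered noise shared
  between years, plus independent per-year pixel noise),
* healthy-vegetation band structure (NIR >> Red),
* clearcut footprints: strong post-year NIR drop with Red/SWIR rise,
* thinning footprints: the same signature at reduced amplitude,
* prescribed-fire and wildfire footprints: NIR drop + SWIR rise so the
  post-year NBR falls below the pre-year NBR,
* confusers: an agricultural green-to-plowed patch outside the forest mask
  and a cloud-shadow patch (all bands scaled down).

Reflectance is unitless surface-reflectance-like [0, 1]; footprints are
random rotated ellipses rasterized through cell centers. All randomness flows
through named child streams of one seed, in a fixed draw order, so adding
confusers never perturbs treatment placement for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely import affinity
from shapely.geometry import Point

from .raster_core import Grid, MultibandRaster, PolygonSet, rasterize_polygons

__all__ = ["SceneSpec", "SceneTruth", "GenerationError", "generate_scene",
           "scene_to_training_truth", "BAND_NAMES"]

BAND_NAMES = ["B", "G", "R", "NIR", "SWIR"]

# Band means for mature conifer forest and for non-forest (grass/agriculture),
# surface-reflectance-like units.
_FOREST_MEANS = {"B": 0.04, "G": 0.07, "R": 0.05, "NIR": 0.40, "SWIR": 0.18}
_NONFOREST_MEANS = {"B": 0.06, "G": 0.10, "R": 0.12, "NIR": 0.30, "SWIR": 0.26}

# Multiplicative post-year band effects per footprint kind, scaled by the
# footprint's effect size e: band *= 1 + coef * e.
_EFFECT_COEFS = {
    "mechanical": {"B": 0.1, "G": 0.3, "R": 1.0, "NIR": -1.0, "SWIR": 0.8},
    "fire": {"B": 0.0, "G": -0.2, "R": 0.3, "NIR": -1.0, "SWIR": 0.9},
}


class GenerationError(RuntimeError):
    """Footprints could not be placed without overlap after bounded retries."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; defaults define the study conditions.

    ``clearcut_effect``/``thinning_effect`` are fractional reflectance changes
    (0.5 halves the NIR inside a clearcut); ``noise_sd`` is per-pixel
    reflectance noise; ``autocorr_sigma`` the Gaussian smoothing scale of the
    shared landscape field, in cells.
    """

    seed: int = 0
    n_rows: int = 240
    n_cols: int = 240
    cell_size: float = 10.0
    forest_fraction: float = 0.7
    n_clearcut: int = 3
    n_thinning: int = 3
    n_fire: int = 2
    n_confuser: int = 2
    n_wildfire: int = 1
    clearcut_effect: float = 0.5
    thinning_effect: float = 0.2
    fire_effect: float = 0.4
    noise_sd: float = 0.03
    autocorr_sigma: float = 5.0
    min_footprint_ha: float = 2.0
    max_footprint_ha: float = 6.0
    origin_x: float = 500_000.0
    origin_y: float = 5_300_000.0
    crs_id: str = "EPSG:32610"

    def __post_init__(self) -> None:
        for name in ("n_clearcut", "n_thinning", "n_fire", "n_confuser", "n_wildfire"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("clearcut_effect", "thinning_effect", "fire_effect"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.thinning_effect >= self.clearcut_effect:
            raise ValueError("thinning_effect must be < clearcut_effect")
        if not 0 <= self.forest_fraction <= 1:
            raise ValueError("forest_fraction must be in [0, 1]")


@dataclass
class SceneTruth:
    """A generated scene plus all the truth needed to score the pipeline."""

    pre: MultibandRaster
    post: MultibandRaster
    forest_mask: MultibandRaster
    treatments: PolygonSet
    wildfire_perimeters: PolygonSet
    burned_area_rasters: list[MultibandRaster]
    spec: SceneSpec = field(default=None)  # type: ignore[assignment]


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-std spatially autocorrelated field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _random_ellipse(rng: np.random.Generator, grid: Grid, inside_mask: np.ndarray,
                    area_ha_range: tuple[float, float]):
    """One random rotated ellipse centered on a True cell of ``inside_mask``."""
    rows, cols = np.nonzero(inside_mask)
    if rows.size == 0:
        return None
    k = rng.integers(rows.size)
    cx, cy = grid.cell_center(int(rows[k]), int(cols[k]))
    area_m2 = rng.uniform(*area_ha_range) * 10_000.0
    aspect = rng.uniform(1.0, 2.5)
    # area = pi * a * b with b = a / aspect
    a = np.sqrt(area_m2 * aspect / np.pi)
    b = a / aspect
    angle = rng.uniform(0.0, 180.0)
    ell = Point(cx, cy).buffer(1.0, quad_segs=32)
    ell = affinity.scale(ell, a, b)
    return affinity.rotate(ell, angle)


def _place_footprints(rng, grid, n, candidate_mask, occupied, area_range,
                      max_tries_per=200):
    """Non-overlapping ellipses with centers on ``candidate_mask`` cells.

    ``occupied`` is a running union geometry of already-claimed ground
    (footprints buffered by two cells); mutated via return value.
    """
    minx, miny, maxx, maxy = grid.bounds
    margin = 2 * grid.cell_size
    frame = shapely.box(minx + margin, miny + margin, maxx - margin, maxy - margin)
    placed = []
    for _ in range(n):
        for _try in range(max_tries_per):
            ell = _random_ellipse(rng, grid, candidate_mask, area_range)
            if ell is None:
                raise GenerationError("no candidate cells to place footprints on")
            if not frame.contains(ell):
                continue
            if occupied is not None and ell.buffer(2 * grid.cell_size).intersects(occupied):
                continue
            placed.append(ell)
            claimed = ell.buffer(2 * grid.cell_size)
            occupied = claimed if occupied is None else occupied.union(claimed)
            break
        else:
            raise GenerationError(
                f"could not place footprint without overlap after {max_tries_per} tries"
            )
    return placed, occupied


def generate_scene(spec: SceneSpec) -> SceneTruth:
    """Deterministically generate a paired-year scene from ``spec``.

    The draw order is fixed: landscape fields, forest mask, clearcuts,
    thinnings, prescribed fires, wildfires, confusers, pixel noise.
    """
    grid = Grid(spec.origin_x, spec.origin_y, spec.cell_size,
                spec.n_rows, spec.n_cols, spec.crs_id)
    streams = np.random.SeedSequence(spec.seed).spawn(8)
    (rng_base, rng_mask, rng_cc, rng_thin, rng_fire,
     rng_wild, rng_conf, rng_noise) = [np.random.default_rng(s) for s in streams]

    shape = grid.shape
    structure = _smooth_field(rng_base, shape, spec.autocorr_sigma)
    mask_field = _smooth_field(rng_mask, shape, 2 * spec.autocorr_sigma)
    if spec.forest_fraction >= 1.0:
        forest = np.ones(shape, dtype=bool)
    elif spec.forest_fraction <= 0.0:
        forest = np.zeros(shape, dtype=bool)
    else:
        forest = mask_field < np.quantile(mask_field, spec.forest_fraction)

    # Footprint placement (fixed order; confusers last so they never perturb
    # treatment placement).
    area_range = (spec.min_footprint_ha, spec.max_footprint_ha)
    occupied = None
    clearcuts, occupied = _place_footprints(rng_cc, grid, spec.n_clearcut,
                                            forest, occupied, area_range)
    thinnings, occupied = _place_footprints(rng_thin, grid, spec.n_thinning,
                                            forest, occupied, area_range)
    fires, occupied = _place_footprints(rng_fire, grid, spec.n_fire,
                                        forest, occupied, area_range)
    wild_range = (4 * spec.min_footprint_ha, 4 * spec.max_footprint_ha)
    wildfires, occupied = _place_footprints(rng_wild, grid, spec.n_wildfire,
                                            forest, occupied, wild_range)
    nonforest = ~forest
    ag_patches, shadow_patches = [], []
    for i in range(spec.n_confuser):
        cand = nonforest if i % 2 == 0 else np.ones(shape, dtype=bool)
        if not cand.any():
            cand = np.ones(shape, dtype=bool)
        patch, occupied = _place_footprints(rng_conf, grid, 1, cand, occupied,
                                            area_range)
        (ag_patches if i % 2 == 0 else shadow_patches).extend(patch)

    # Treatments must lie inside the forest mask by construction.
    for ell in clearcuts + thinnings + fires:
        forest |= rasterize_polygons([ell], grid)

    # Reflectance planes: band mean modulated by the shared landscape field,
    # plus independent per-year pixel noise.
    pre_vals = np.empty((5,) + shape)
    post_vals = np.empty((5,) + shape)
    for bi, name in enumerate(BAND_NAMES):
        base = np.where(forest, _FOREST_MEANS[name], _NONFOREST_MEANS[name])
        base = base * (1.0 + 0.10 * structure)
        pre_vals[bi] = base + spec.noise_sd * rng_noise.standard_normal(shape)
        post_vals[bi] = base + spec.noise_sd * rng_noise.standard_normal(shape)

    def apply_effect(polys, kind, effect):
        cells = rasterize_polygons(polys, grid)
        for bi, name in enumerate(BAND_NAMES):
            coef = _EFFECT_COEFS[kind][name]
            post_vals[bi][cells] *= 1.0 + coef * effect

    apply_effect(clearcuts, "mechanical", spec.clearcut_effect)
    apply_effect(thinnings, "mechanical", spec.thinning_effect)
    apply_effect(fires, "fire", spec.fire_effect)
    apply_effect(wildfires, "fire", spec.fire_effect)
    # Agricultural confuser: green in year 1, plowed in year 2.
    apply_effect(ag_patches, "mechanical", 0.45)
    for ell in shadow_patches:
        cells = rasterize_polygons([ell], grid)
        post_vals[:, cells] *= 0.4

    np.clip(pre_vals, 0.0, 1.0, out=pre_vals)
    np.clip(post_vals, 0.0, 1.0, out=post_vals)

    pre = MultibandRaster(grid, list(BAND_NAMES), pre_vals)
    post = MultibandRaster(grid, list(BAND_NAMES), post_vals)
    forest_mask = MultibandRaster(grid, ["mask"], forest.astype(float)[None])

    geoms = clearcuts + thinnings + fires
    types = (["clearcut"] * len(clearcuts) + ["thinning"] * len(thinnings)
             + ["prescribed_fire"] * len(fires))
    treatments = PolygonSet(
        geoms,
        pd.DataFrame({"type": types, "period": ["pre-post"] * len(geoms)}),
        spec.crs_id,
    )
    perimeters = PolygonSet(
        list(wildfires),
        pd.DataFrame({"type": ["wildfire"] * len(wildfires)}),
        spec.crs_id,
    )

    # Burned-area rasters: prescribed fires alternate between two acquisition
    # dates; wildfire burned cells land on the first date.
    date1 = np.zeros(shape)
    date2 = np.zeros(shape)
    for i, ell in enumerate(fires):
        target = date1 if i % 2 == 0 else date2
        target[rasterize_polygons([ell], grid)] = 1.0
    for ell in wildfires:
        date1[rasterize_polygons([ell], grid)] = 1.0
    burned = [MultibandRaster(grid, ["burned"], d[None]) for d in (date1, date2)]

    return SceneTruth(pre, post, forest_mask, treatments, perimeters, burned, spec)


def scene_to_training_truth(truth: SceneTruth) -> PolygonSet:
    """Mechanical-treatment truth (clearcut + thinning) for training labels.

    Prescribed fire is excluded: training targets mechanical treatments only;
    fires are recovered separately from burned-area products.
    """
    return truth.treatments.filter_type({"clearcut", "thinning"})
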