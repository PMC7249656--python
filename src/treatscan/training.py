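"""Labeled training sets for the treatment classifier.

Candidate locations are drawn uniformly over forest cells (cell centers, so
predictor extraction is exact), labeled 1 if they fall inside a known
mechanical-treatment polygon and 0 otherwise. Because treatments cover only a
small share of any real landscape, the raw draw is heavily imbalanced; extra
points are placed inside treatment polygons until the treatment share reaches
approximately 30% (the 30/70 composition used for model fitting). Existing
non-treatment points are never deleted; an optional ``relocate`` variant
instead moves some 0-points into treated land.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .features import PredictorStack
from .raster_core import MultibandRaster, PolygonSet

__all__ = ["TrainingSet", "draw_candidate_points", "label_points",
           "balance_training", "extract_predictors", "build_training_set"]

TARGET_RATIO = 0.30
RATIO_TOL = 0.02  # "approximately 30%": accepted band is +/- 2 points


@dataclass
class TrainingSet:
    """Point locations with 0/1 labels and kept-band predictor vectors."""

    points: pd.DataFrame  # columns: x, y, label, plus one column per kept band
    predictor_names: list[str]

    @property
    def X(self) -> np.ndarray:
        return self.points[self.predictor_names].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.points["label"].to_numpy().astype(int)

    def treatment_fraction(self) -> float:
        return float(self.points["label"].mean())


def _forest_cells(mask: MultibandRaster) -> tuple[np.ndarray, np.ndarray]:
    m = mask.values[0]
    return np.nonzero(m == 1.0)


def draw_candidate_points(mask: MultibandRaster, n: int = 500, seed: int = 0,
                          exclusions: PolygonSet | None = None,
                          exclude_cells: np.ndarray | None = None) -> pd.DataFrame:
    """``n`` distinct cell-center locations, uniform over eligible forest cells.

    ``exclusions`` (typically the target-year wildfire perimeters) and
    ``exclude_cells`` (a boolean plane, typically known burned cells) remove
    cells from the candidate pool: they stand in for the analyst's
    verification of each candidate point, which discards locations known to
    be disturbed by something other than a mechanical treatment.
    """
    rows, cols = _forest_cells(mask)
    if exclude_cells is not None:
        ok = ~exclude_cells[rows, cols]
        rows, cols = rows[ok], cols[ok]
    if exclusions is not None and len(exclusions):
        import shapely
        xs = mask.grid.origin_x + (cols + 0.5) * mask.grid.cell_size
        ys = mask.grid.origin_y - (rows + 0.5) * mask.grid.cell_size
        union = shapely.union_all(exclusions.geometries)
        ok = ~shapely.intersects_xy(union, xs, ys)
        rows, cols = rows[ok], cols[ok]
    if rows.size < n:
        raise ValueError(f"only {rows.size} eligible forest cells, need {n}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(rows.size, size=n, replace=False)
    xs, ys = zip(*(mask.grid.cell_center(int(r), int(c))
                   for r, c in zip(rows[pick], cols[pick])))
    return pd.DataFrame({"x": xs, "y": ys})


def label_points(points: pd.DataFrame, truth: PolygonSet) -> pd.DataFrame:
    """Label 1 iff the point falls inside (or on) any truth polygon."""
    out = points.copy()
    if len(truth) == 0:
        out["label"] = 0
        return out
    union = shapely.union_all(truth.geometries)
    inside = shapely.intersects_xy(union, out["x"].to_numpy(), out["y"].to_numpy())
    out["label"] = inside.astype(int)
    return out


def _points_inside_polygons(mask: MultibandRaster, truth: PolygonSet) -> pd.DataFrame:
    """Forest cell centers inside any truth polygon."""
    rows, cols = _forest_cells(mask)
    xs = mask.grid.origin_x + (cols + 0.5) * mask.grid.cell_size
    ys = mask.grid.origin_y - (rows + 0.5) * mask.grid.cell_size
    union = shapely.union_all(truth.geometries)
    inside = shapely.intersects_xy(union, xs, ys)
    return pd.DataFrame({"x": xs[inside], "y": ys[inside]})


def balance_training(points: pd.DataFrame, truth: PolygonSet,
                     mask: MultibandRaster, target_ratio: float = TARGET_RATIO,
                     seed: int = 0, relocate: bool = False) -> pd.DataFrame:
    """Enforce the ~30% treatment / 70% non-treatment composition.

    If the treatment fraction is below ``target_ratio``, points are added
    uniformly over treated forest cells until the fraction is within
    +/- 2 percentage points of the target (solving (t+k)/(n+k) = ratio).
    With ``relocate=True`` the same number of existing 0-points is moved into
    treated cells instead of being added.
    """
    pts = points.copy()
    frac = pts["label"].mean() if len(pts) else 0.0
    if frac >= target_ratio - RATIO_TOL:
        return pts
    if len(truth) == 0:
        raise ValueError("cannot reach target ratio: no treatment polygons")
    pool = _points_inside_polygons(mask, truth)
    if len(pool) == 0:
        raise ValueError("cannot reach target ratio: no forest cells inside "
                         "treatment polygons")
    n, t = len(pts), int(pts["label"].sum())
    k = int(np.ceil((target_ratio * n - t) / (1.0 - target_ratio)))
    rng = np.random.default_rng(seed)
    if relocate:
        k = min(k, int((pts["label"] == 0).sum()))
        drop = rng.choice(np.flatnonzero(pts["label"] == 0), size=k, replace=False)
        pts = pts.drop(index=pts.index[drop]).reset_index(drop=True)
    pick = rng.choice(len(pool), size=k, replace=len(pool) < k)
    added = pool.iloc[pick].copy()
    added["label"] = 1
    out = pd.concat([pts, added], ignore_index=True)
    final = out["label"].mean()
    if abs(final - target_ratio) > RATIO_TOL:
        warnings.warn(f"treatment fraction {final:.3f} outside target band",
                      stacklevel=2)
    return out


def extract_predictors(points: pd.DataFrame, stack: PredictorStack) -> TrainingSet:
    """Kept-band raster values at each point's containing cell.

    Points landing on nodata in any kept band are dropped with a warning;
    if all points are dropped that is an error.
    """
    grid = stack.raster.grid
    names = stack.kept_names
    rows, cols = grid.index_of(points["x"].to_numpy(), points["y"].to_numpy())
    on_grid = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if not on_grid.all():
        raise ValueError("points off the predictor grid")
    vals = np.stack([stack.raster.band(n)[rows, cols] for n in names], axis=1)
    finite = np.all(np.isfinite(vals), axis=1)
    if not finite.any():
        raise ValueError("all points fall on nodata predictor cells")
    if not finite.all():
        warnings.warn(f"dropped {int((~finite).sum())} points on nodata cells",
                      stacklevel=2)
    out = points.loc[finite].reset_index(drop=True).copy()
    for j, name in enumerate(names):
        out[name] = vals[finite, j]
    return TrainingSet(out, names)


def build_training_set(stack: PredictorStack, mask: MultibandRaster,
                       truth: PolygonSet, n: int = 500, seed: int = 0,
                       relocate: bool = False,
                       exclusions: PolygonSet | None = None,
                       exclude_cells: np.ndarray | None = None) -> TrainingSet:
    """Full sampling chain: draw, label, balance, extract."""
    pts = draw_candidate_points(mask, n, seed, exclusions, exclude_cells)
    pts = label_points(pts, truth)
    pts = balance_training(pts, truth, mask, seed=seed + 1, relocate=relocate)
    return extract_predictors(pts, stack)
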