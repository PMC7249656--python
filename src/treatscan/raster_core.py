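"""Raster and vector data model, GeoTIFF/GeoJSON I/O, and grid-alignment contracts.

Every stage of the treatment-mapping pipeline exchanges data through two
containers defined here: :class:`MultibandRaster` (a georeferenced stack of
named 2-D bands on a :class:`Grid`) and :class:`PolygonSet` (shapely
geometries plus a pandas attribute table). All rasters in one pipeline run
must share a projected CRS in meters, because downstream area filters are
expressed in hectares.

Conventions
-----------
* Cell (row 0, col 0) is the top-left cell; ``origin_x``/``origin_y`` are the
  coordinates of the grid's top-left *corner*. A cell's value represents its
  full square footprint; polygon/raster conversions use cell-boundary squares.
* Bands are stored as float64 with ``nan`` marking nodata in memory; the
  grid's ``nodata`` sentinel is only used on disk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "Grid",
    "MultibandRaster",
    "PolygonSet",
    "GridAlignmentError",
    "read_raster",
    "write_raster",
    "assert_same_grid",
    "read_polygons",
    "write_polygons",
]

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113

_SQM_PER_HA = 10_000.0


class GridAlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Square-celled georeferenced lattice.

    ``origin_x``/``origin_y`` locate the top-left corner in map units (a
    projected CRS in meters); ``cell_size`` is the square cell edge length.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_id: str | None = "EPSG:32610"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size**2 / _SQM_PER_HA

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of shape (n_rows, n_cols) of cell-center coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        xs = self.origin_x + (cols + 0.5) * self.cell_size
        ys = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each map coordinate."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )


@dataclass
class MultibandRaster:
    """Named 2-D value planes sharing one :class:`Grid`.

    ``values`` has shape ``(n_bands, n_rows, n_cols)``; nodata is ``nan``.
    """

    grid: Grid
    band_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 2:
            self.values = self.values[None, :, :]
        if len(self.band_names) == 0:
            raise ValueError("raster must have at least one band")
        if len(set(self.band_names)) != len(self.band_names):
            raise ValueError("band names must be unique")
        if self.values.shape != (len(self.band_names), self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.band_names)} bands on grid {self.grid.shape}"
            )

    @property
    def n_bands(self) -> int:
        return len(self.band_names)

    def band(self, name: str) -> np.ndarray:
        """The 2-D plane of a band, by name."""
        try:
            return self.values[self.band_names.index(name)]
        except ValueError:
            raise KeyError(f"no band named {name!r}; have {self.band_names}") from None

    def select(self, names: list[str]) -> "MultibandRaster":
        return MultibandRaster(
            self.grid, list(names), np.stack([self.band(n) for n in names])
        )

    def copy(self) -> "MultibandRaster":
        return MultibandRaster(self.grid, list(self.band_names), self.values.copy())

    def finite_mask(self) -> np.ndarray:
        """Cells finite in every band."""
        return np.all(np.isfinite(self.values), axis=0)


@dataclass
class PolygonSet:
    """Planar polygons in the grid CRS with a per-geometry attribute table.

    ``attributes`` is a DataFrame aligned row-for-row with ``geometries``.
    """

    geometries: list
    attributes: pd.DataFrame = field(default_factory=pd.DataFrame)
    crs_id: str | None = "EPSG:32610"

    def __post_init__(self) -> None:
        self.geometries = [shapely.make_valid(g) for g in self.geometries]
        if len(self.attributes) == 0 and len(self.geometries) > 0:
            self.attributes = pd.DataFrame(index=range(len(self.geometries)))
        if len(self.attributes) != len(self.geometries):
            raise ValueError("attributes must align with geometries")
        self.attributes = self.attributes.reset_index(drop=True)
        if "area_ha" not in self.attributes.columns and len(self.geometries) > 0:
            self.attributes["area_ha"] = [g.area / _SQM_PER_HA for g in self.geometries]

    def __len__(self) -> int:
        return len(self.geometries)

    def subset(self, keep: np.ndarray) -> "PolygonSet":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return PolygonSet(
            [self.geometries[i] for i in idx],
            self.attributes.iloc[idx].reset_index(drop=True),
            self.crs_id,
        )

    def filter_type(self, types) -> "PolygonSet":
        if "type" not in self.attributes.columns:
            return PolygonSet([], pd.DataFrame(), self.crs_id)
        keep = self.attributes["type"].isin(list(types)).to_numpy()
        return self.subset(keep)


def assert_same_grid(a: MultibandRaster | Grid, b: MultibandRaster | Grid) -> None:
    """Raise :class:`GridAlignmentError` naming the first differing grid field."""
    ga = a.grid if isinstance(a, MultibandRaster) else a
    gb = b.grid if isinstance(b, MultibandRaster) else b
    for fld in ("origin_x", "origin_y", "cell_size", "n_rows", "n_cols", "crs_id"):
        va, vb = getattr(ga, fld), getattr(gb, fld)
        same = np.isclose(va, vb) if isinstance(va, (int, float)) else va == vb
        if not same:
            raise GridAlignmentError(f"grids differ in {fld}: {va!r} != {vb!r}")


def write_raster(raster: MultibandRaster, path) -> None:
    """Write a GeoTIFF with pixel-scale/tiepoint tags and a JSON band manifest."""
    g = raster.grid
    data = raster.values.copy()
    data[~np.isfinite(data)] = g.nodata
    desc = json.dumps(
        {"band_names": raster.band_names, "crs_id": g.crs_id, "nodata": g.nodata}
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_GDAL_NODATA, "s", 0, str(g.nodata)),
    ]
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        description=desc,
        extratags=extratags,
        metadata=None,
    )


def read_raster(path) -> MultibandRaster:
    """Read a GeoTIFF written by :func:`write_raster` (or plain TIFF).

    A missing CRS is kept as ``None`` with a warning; nodata cells come back
    as ``nan``.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray().astype(np.float64)
        if data.ndim == 2:
            data = data[None]
        tags = page.tags
        scale = tags.valueof(_MODEL_PIXEL_SCALE)
        tiepoint = tags.valueof(_MODEL_TIEPOINT)
        nodata_tag = tags.valueof(_GDAL_NODATA)
        desc = tags.valueof("ImageDescription")
    meta = {}
    if desc is not None:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    cell = float(scale[0]) if scale is not None else 1.0
    if tiepoint is not None:
        origin_x, origin_y = float(tiepoint[3]), float(tiepoint[4])
    else:
        origin_x, origin_y = 0.0, 0.0
    nodata = float(meta.get("nodata",
                            nodata_tag if nodata_tag is not None else -9999.0))
    crs_id = meta.get("crs_id")
    if crs_id is None:
        warnings.warn(f"{path}: no CRS recorded; keeping grid without CRS", stacklevel=2)
    grid = Grid(origin_x, origin_y, cell, data.shape[1], data.shape[2], crs_id, nodata)
    names = meta.get("band_names") or [f"band_{i + 1}" for i in range(data.shape[0])]
    data[data == nodata] = np.nan
    return MultibandRaster(grid, list(names), data)


def write_polygons(polys: PolygonSet, path) -> None:
    """Serialize a PolygonSet as GeoJSON (the one vector format used here)."""
    features = []
    records = polys.attributes.to_dict(orient="records") if len(polys) else []
    for geom, props in zip(polys.geometries, records or [{}] * len(polys)):
        clean = {
            k: (v.item() if isinstance(v, np.generic) else v) for k, v in props.items()
        }
        features.append(
            {"type": "Feature", "geometry": geom_mapping(geom), "properties": clean}
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "crs_id": polys.crs_id,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_polygons(path) -> PolygonSet:
    with open(path) as fh:
        doc = json.load(fh)
    geoms = [geom_shape(f["geometry"]) for f in doc.get("features", [])]
    attrs = pd.DataFrame([f.get("properties") or {} for f in doc.get("features", [])])
    return PolygonSet(geoms, attrs, doc.get("crs_id"))


def raster_like(
    reference: Grid | MultibandRaster, band_names: list[str], values: np.ndarray
) -> MultibandRaster:
    """Convenience constructor on the grid of an existing raster."""
    grid = reference.grid if isinstance(reference, MultibandRaster) else reference
    return MultibandRaster(grid, band_names, values)


def rasterize_polygons(
    polys, grid: Grid, all_touched_centers: bool = True
) -> np.ndarray:
    """Binary (bool) plane: cell centers covered by any polygon.

    Accepts a PolygonSet or a bare list of shapely geometries.
    """
    geoms = polys.geometries if isinstance(polys, PolygonSet) else list(polys)
    out = np.zeros(grid.shape, dtype=bool)
    if not geoms:
        return out
    xs, ys = grid.cell_centers()
    union = shapely.union_all([shapely.make_valid(g) for g in geoms])
    out = shapely.intersects_xy(union, xs.ravel(), ys.ravel()).reshape(grid.shape)
    return out
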