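"""Radiometric harmonization and band preparation.

Paired-year images differ in sun angle and atmospheric state; before change
metrics are computed, the earlier image of each pair is histogram-matched to
the later one (per band, monotone CDF lookup). The SWIR band, natively at a
coarser grid, is bilinearly upsampled onto the base grid, and the forest mask
is applied by turning non-forest cells to nodata.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.ndimage import map_coordinates

from .raster_core import Grid, MultibandRaster, assert_same_grid

__all__ = ["histogram_match", "upsample_bilinear", "apply_mask"]



def _match_band(src: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Monotone lookup mapping src values so its empirical CDF matches ref's.

    Exact empirical-quantile matching: each source value is sent through the
    source quantile function and the reference inverse quantile function
    (linear interpolation between order statistics). Matching a band onto
    itself is the exact identity, and a constant offset between two bands is
    undone exactly.
    """
    finite_src = src[np.isfinite(src)]
    finite_ref = ref[np.isfinite(ref)]
    if finite_src.size == 0 or finite_ref.size == 0:
        return src.copy()
    if finite_src.min() == finite_src.max():
        warnings.warn("constant source band: CDF not invertible, returned unchanged",
                      stacklevel=3)
        return src.copy()
    sorted_src = np.sort(finite_src)
    sorted_ref = np.sort(finite_ref)
    q_src = np.linspace(0.0, 1.0, sorted_src.size)
    q_ref = np.linspace(0.0, 1.0, sorted_ref.size)
    out = np.full_like(src, np.nan)
    ok = np.isfinite(src)
    q = np.interp(src[ok], sorted_src, q_src)
    out[ok] = np.interp(q, q_ref, sorted_ref)
    return out


def histogram_match(source: MultibandRaster, reference: MultibandRaster) -> MultibandRaster:
    """Per-band histogram matching of ``source`` onto ``reference``.

    Both rasters must share the grid and band count. Nodata is preserved;
    constant bands are passed through with a warning.
    """
    assert_same_grid(source, reference)
    if source.n_bands != reference.n_bands:
        raise ValueError("band count mismatch between source and reference")
    out = np.stack([
        _match_band(source.values[i], reference.values[i])
        for i in range(source.n_bands)
    ])
    return MultibandRaster(source.grid, list(source.band_names), out)


def upsample_bilinear(band: MultibandRaster, target: Grid) -> MultibandRaster:
    """Bilinear upsampling onto a finer grid aligned by cell centers.

    The target cell size must divide the source cell size (e.g. 20 m -> 10 m);
    edge cells clamp to the nearest source value.
    """
    src = band.grid
    ratio = src.cell_size / target.cell_size
    if ratio < 1:
        raise ValueError("target grid is coarser than source; this operation only upsamples")
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target cell size must divide source cell size")
    xs, ys = target.cell_centers()
    # fractional source array coordinates of target cell centers
    col = (xs - src.origin_x) / src.cell_size - 0.5
    row = (src.origin_y - ys) / src.cell_size - 0.5
    out = np.stack([
        map_coordinates(band.values[i], [row, col], order=1, mode="nearest")
        for i in range(band.n_bands)
    ])
    return MultibandRaster(target, list(band.band_names), out)


def apply_mask(raster: MultibandRaster, mask: MultibandRaster) -> MultibandRaster:
    """Set every band to nodata where the binary mask is 0."""
    assert_same_grid(raster, mask)
    m = mask.values[0]
    vals = np.unique(m[np.isfinite(m)])
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError(f"mask is not binary; values {vals[:10]}")
    out = raster.values.copy()
    out[:, m != 1.0] = np.nan
    return MultibandRaster(raster.grid, list(raster.band_names), out)
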