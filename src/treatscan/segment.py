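"""Mean-shift segmentation of the treatment-vote band.

The treatment-vote surface is smoothed by value-domain mean-shift filtering
with a flat kernel over a square spatial window (pixel positions stay fixed;
each pixel's value moves to the mean of spatially-near pixels whose values
lie within the range bandwidth, iterated to convergence). Filtered cells are
then grouped into 8-connected segments of near-equal value, and segments
smaller than the minimum size are merged into the adjacent segment with the
closest mean.

The reference tool exposes 1-20 "detail" knobs whose internal mapping is
unpublished; here they map monotonically to bandwidths (higher detail =
narrower bandwidth = finer output)::

    spatial bandwidth  h_s = 21 - spatial_detail          [cells]
    range bandwidth    h_r = (21 - spectral_detail)/20 * (max - min of the band)

and the defaults (spectral 20, spatial 10, min segment 10 px) mirror a
high-spectral-detail, moderate-spatial-detail configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .classify import VoteRaster
from .raster_core import MultibandRaster

__all__ = ["SegmentRaster", "mean_shift_segment", "segment_value_raster"]

_MAX_ITER = 100
_CONV_FRAC = 1e-4  # stop when the max shift < this fraction of the data range


@dataclass
class SegmentRaster:
    """Integer segment labels (contiguous from 1; 0 = nodata) plus summaries."""

    labels: np.ndarray
    grid: object
    segment_means: dict[int, float]
    segment_sizes: dict[int, int]

    @property
    def n_segments(self) -> int:
        return len(self.segment_sizes)


def _mean_shift_filter(values: np.ndarray, finite: np.ndarray,
                       h_s: int, h_r: float) -> np.ndarray:
    """Flat-kernel value-domain mean-shift over a (2*h_s+1)^2 window."""
    v = np.where(finite, values, np.nan)
    offsets = [(dr, dc)
               for dr in range(-h_s, h_s + 1)
               for dc in range(-h_s, h_s + 1)]
    rng_span = np.nanmax(v) - np.nanmin(v)
    if rng_span == 0:
        return v
    tol = _CONV_FRAC * rng_span
    cur = v.copy()
    nrow, ncol = cur.shape
    for _ in range(_MAX_ITER):
        total = np.zeros_like(cur)
        count = np.zeros_like(cur)
        for dr, dc in offsets:
            # overlap of the grid with itself shifted by (dr, dc)
            r0, r1 = max(0, dr), min(nrow, nrow + dr)
            c0, c1 = max(0, dc), min(ncol, ncol + dc)
            if r0 >= r1 or c0 >= c1:
                continue
            nb = cur[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
            ctr = cur[r0:r1, c0:c1]
            w = np.abs(nb - ctr) <= h_r
            w &= np.isfinite(nb)
            total[r0:r1, c0:c1] += np.where(w, nb, 0.0)
            count[r0:r1, c0:c1] += w
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(count > 0, total / count, cur)
        new[~finite] = np.nan
        shift = np.nanmax(np.abs(new - cur)) if finite.any() else 0.0
        cur = new
        if shift < tol:
            break
    return cur


def _label_components(filtered: np.ndarray, finite: np.ndarray,
                      tol: float) -> np.ndarray:
    """8-connected components of cells whose filtered values differ < tol."""
    nrow, ncol = filtered.shape
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    rows_i, rows_j = [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, dr), min(nrow, nrow + dr)
        c0, c1 = max(0, dc), min(ncol, ncol + dc)
        a = filtered[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        b = filtered[r0:r1, c0:c1]
        fa = finite[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
        fb = finite[r0:r1, c0:c1]
        link = fa & fb & (np.abs(a - b) < tol)
        rows_i.append(idx[r0 - dr:r1 - dr, c0 - dc:c1 - dc][link])
        rows_j.append(idx[r0:r1, c0:c1][link])
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    n = nrow * ncol
    adj = coo_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    comp = comp.reshape(nrow, ncol)
    comp[~finite] = -1
    return comp


def _relabel_contiguous(comp: np.ndarray, finite: np.ndarray) -> np.ndarray:
    """Ids contiguous from 1 in row-major order of first occurrence."""
    labels = np.zeros(comp.shape, dtype=np.int64)
    flat = comp[finite]
    # renumber by first occurrence among finite cells, row-major
    seen = {}
    out_flat = np.zeros(flat.size, dtype=np.int64)
    nxt = 1
    for k, c in enumerate(flat):
        if c not in seen:
            seen[c] = nxt
            nxt += 1
        out_flat[k] = seen[c]
    labels[finite] = out_flat
    return labels


def mean_shift_segment(votes: VoteRaster, spectral_detail: float = 20,
                       spatial_detail: float = 10,
                       min_size: int = 10) -> SegmentRaster:
    """Segment the treatment-vote band into homogeneous regions.

    Deterministic. Segments smaller than ``min_size`` cells are iteratively
    merged into the 8-adjacent segment with the closest mean vote; if the
    scene has fewer finite cells than ``min_size`` a single segment is
    returned with a warning.
    """
    band = votes.treatment_band
    finite = np.isfinite(band)
    grid = votes.raster.grid
    if not finite.any():
        raise ValueError("vote raster has no finite cells")
    if finite.sum() < min_size:
        warnings.warn("fewer finite cells than min_size: single segment",
                      stacklevel=2)
        labels = np.where(finite, 1, 0).astype(np.int64)
        mean = float(np.nanmean(band))
        return SegmentRaster(labels, grid, {1: mean}, {1: int(finite.sum())})

    h_s = max(1, int(round(21 - spatial_detail)))
    span = float(np.nanmax(band) - np.nanmin(band))
    h_r = (21 - spectral_detail) / 20.0 * span
    filtered = _mean_shift_filter(band, finite, h_s, h_r)
    tol = max(h_r, _CONV_FRAC * span) if span > 0 else 1.0
    comp = _label_components(filtered, finite, tol)
    labels = _relabel_contiguous(comp, finite)

    labels = _merge_small(labels, band, finite, min_size)
    ids, sizes = np.unique(labels[finite], return_counts=True)
    seg_sizes = {int(i): int(s) for i, s in zip(ids, sizes)}
    seg_means = {int(i): float(band[labels == i].mean()) for i in ids}
    return SegmentRaster(labels, grid, seg_means, seg_sizes)


def _adjacency_pairs(labels: np.ndarray) -> np.ndarray:
    """Unique (a, b) pairs of distinct 8-adjacent segment ids, a < b."""
    nrow, ncol = labels.shape
    chunks = []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0, r1 = max(0, dr), min(nrow, nrow + dr)
        c0, c1 = max(0, dc), min(ncol, ncol + dc)
        a = labels[r0 - dr:r1 - dr, c0 - dc:c1 - dc].ravel()
        b = labels[r0:r1, c0:c1].ravel()
        diff = (a != b) & (a > 0) & (b > 0)
        pair = np.stack([np.minimum(a[diff], b[diff]),
                         np.maximum(a[diff], b[diff])], axis=1)
        chunks.append(pair)
    allp = np.concatenate(chunks) if chunks else np.empty((0, 2), dtype=np.int64)
    return np.unique(allp, axis=0) if allp.size else allp


def _merge_small(labels: np.ndarray, band: np.ndarray, finite: np.ndarray,
                 min_size: int) -> np.ndarray:
    """Iteratively merge segments below min_size into the 8-adjacent
    neighbor with the closest mean vote (ties broken by lower id)."""
    labels = labels.copy()
    for _ in range(1_000):
        flat = labels[finite]
        nmax = int(flat.max()) + 1
        sizes = np.bincount(flat, minlength=nmax)
        sums = np.bincount(flat, weights=band[finite], minlength=nmax)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(sizes > 0, sums / np.maximum(sizes, 1), np.nan)
        small = np.flatnonzero((sizes > 0) & (sizes < min_size))
        live = int((sizes > 0).sum())
        if small.size == 0 or live <= 1:
            break
        pairs = _adjacency_pairs(labels)
        neighbors: dict[int, list[int]] = {}
        for a, b in pairs:
            neighbors.setdefault(int(a), []).append(int(b))
            neighbors.setdefault(int(b), []).append(int(a))
        # merge in increasing size order; one remap per pass, then re-audit
        remap = np.arange(nmax)
        merged_any = False
        for target in sorted(small, key=lambda i: (sizes[i], i)):
            nbrs = [j for j in neighbors.get(int(target), []) if remap[j] == j]
            if not nbrs:
                continue
            best = min(nbrs, key=lambda j: (abs(means[j] - means[target]), j))
            remap[target] = best
            merged_any = True
        if not merged_any:
            break  # isolated small segments: nothing to merge into
        labels = remap[labels]
    # renumber contiguous from 1
    return _relabel_contiguous(labels, finite)


def segment_value_raster(seg: SegmentRaster) -> MultibandRaster:
    """Raster whose cell value is its segment's mean treatment vote."""
    out = np.full(seg.labels.shape, np.nan)
    for sid, mean in seg.segment_means.items():
        out[seg.labels == sid] = mean
    return MultibandRaster(seg.grid, ["segment_mean_vote"], out[None])
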