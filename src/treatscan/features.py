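"""The 18-band predictor stack: PCA change metrics, focal statistics, indices.

Each year's image is reduced to four principal components (SVD on the
centered 4-band pixel matrix, fitted per image). Two per-component change
metrics are formed between the pre-treatment year ``n`` and post-treatment
year ``w``::

    PCA_sub_i = PC_i(w) - PC_i(n)          (difference)
    PCA_div_i = PC_i(n) / PC_i(w)          (ratio; note the n/w orientation)

A 3x3 focal mean and focal standard deviation of each metric band, plus the
Relativized Burn Ratio and NDVI, make up the 18 predictor bands:

====  ===================================
band  source
====  ===================================
1-4   focal mean of PCA_sub, PC1..PC4
5-8   focal STD  of PCA_sub, PC1..PC4
9-12  focal mean of PCA_div, PC1..PC4
13-16 focal STD  of PCA_div, PC1..PC4
17    RBR
18    NDVI (post-year image)
====  ===================================

Bands are ranked by position; pairs of bands with |Pearson r| above 0.75 are
pruned by dropping the lower-priority (higher-rank-number) band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

from .raster_core import MultibandRaster, assert_same_grid

__all__ = [
    "PCAModel", "ScenePair", "PredictorStack",
    "fit_pca", "pca_scores", "pca_change", "focal_stats",
    "spectral_indices", "compose_predictors", "prune_correlated",
]

_DIV_EPS = 1e-9  # guard for the ratio metric's denominator
RBR_OFFSET = 1.001  # stabilizing constant in the RBR denominator


@dataclass
class PCAModel:
    """Principal components of one multiband image.

    ``loadings`` is (bands x components) with orthonormal columns, sign-fixed
    so each column's largest-|loading| entry is positive; ``explained_variance``
    are the component variances (sample, ddof=1) summing to the total band
    variance.
    """

    band_means: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class ScenePair:
    """Pre-year (n) and post-year (w) images on one grid."""

    pre: MultibandRaster
    post: MultibandRaster
    period_label: str = ""

    def __post_init__(self) -> None:
        assert_same_grid(self.pre, self.post)


@dataclass
class PredictorStack:
    """The predictor raster plus per-band provenance and keep flags."""

    raster: MultibandRaster
    band_meta: list[dict]
    kept: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kept is None:
            self.kept = np.ones(len(self.band_meta), dtype=bool)
        ranks = [m["rank"] for m in self.band_meta]
        if len(set(ranks)) != len(ranks):
            raise ValueError("band ranks must be unique")

    @property
    def kept_names(self) -> list[str]:
        return [m["name"] for m, k in zip(self.band_meta, self.kept) if k]

    def kept_raster(self) -> MultibandRaster:
        return self.raster.select(self.kept_names)


def fit_pca(image: MultibandRaster, mask: np.ndarray | None = None) -> PCAModel:
    """Fit principal components via SVD of the centered pixel matrix.

    Optionally restrict the fit to cells where ``mask`` is True (the forest
    mask, by default upstream). All components are retained; a zero-variance
    band simply yields a zero-variance component.
    """
    if image.n_bands < 2:
        raise ValueError("PCA needs at least 2 bands")
    finite = image.finite_mask()
    if mask is not None:
        finite &= mask.astype(bool)
    X = image.values[:, finite].T  # (pixels, bands)
    if X.shape[0] < image.n_bands + 1:
        raise ValueError("PCA needs at least bands+1 finite pixels")
    means = X.mean(axis=0)
    Xc = X - means
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = vt.T
    # fix SVD sign indeterminacy: largest-|loading| entry of each column positive
    for j in range(loadings.shape[1]):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    explained = s**2 / (X.shape[0] - 1)
    return PCAModel(means, loadings, explained)


def pca_scores(image: MultibandRaster, model: PCAModel) -> MultibandRaster:
    """Per-pixel centered projection onto the component loadings."""
    if image.n_bands != model.loadings.shape[0]:
        raise ValueError("band count does not match the fitted model")
    flat = image.values.reshape(image.n_bands, -1).T
    scores = (flat - model.band_means) @ model.loadings
    out = scores.T.reshape(model.n_components, *image.grid.shape)
    names = [f"PC{i + 1}" for i in range(model.n_components)]
    return MultibandRaster(image.grid, names, out)


def pca_change(pre_scores: MultibandRaster, post_scores: MultibandRaster,
               mode: str) -> MultibandRaster:
    """Per-component change metric between the two years' PC score rasters.

    ``subtract``: PC_i(post) - PC_i(pre). ``divide``: PC_i(pre) / PC_i(post),
    with nodata where |denominator| < 1e-9. The orientations differ on
    purpose: the ratio metric relates the pre-year state to the post-year
    state while the difference runs post minus pre.
    """
    assert_same_grid(pre_scores, post_scores)
    if mode == "subtract":
        out = post_scores.values - pre_scores.values
    elif mode == "divide":
        den = post_scores.values
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(np.abs(den) < _DIV_EPS, np.nan, pre_scores.values / den)
    else:
        raise ValueError(f"mode must be 'subtract' or 'divide', got {mode!r}")
    return MultibandRaster(pre_scores.grid, list(pre_scores.band_names), out)


def focal_stats(raster: MultibandRaster, stat: str) -> MultibandRaster:
    """3x3 moving-window mean or standard deviation, nodata-aware.

    Edge cells use the neighbors that exist (>= 4 of them); nodata cells do
    not contribute, and a cell with no finite neighbor stays nodata. The STD
    uses the population denominator (the GIS focal-statistics convention).
    """
    if stat not in ("mean", "std"):
        raise ValueError(f"stat must be 'mean' or 'std', got {stat!r}")
    kernel = np.ones((3, 3))
    out = np.empty_like(raster.values)
    for i in range(raster.n_bands):
        v = raster.values[i]
        ok = np.isfinite(v)
        v0 = np.where(ok, v, 0.0)
        count = convolve(ok.astype(float), kernel, mode="constant", cval=0.0)
        total = convolve(v0, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(count > 0, total / count, np.nan)
            if stat == "mean":
                out[i] = mean
            else:
                sq = convolve(v0**2, kernel, mode="constant", cval=0.0)
                var = np.where(count > 0, sq / count - mean**2, np.nan)
                out[i] = np.sqrt(np.clip(var, 0.0, None))
        out[i][~ok] = np.nan
    return MultibandRaster(raster.grid, list(raster.band_names), out)


def spectral_indices(pair: ScenePair) -> MultibandRaster:
    """Burn and vegetation indices for one year pair.

    NBR = (NIR - SWIR) / (NIR + SWIR) per year; dNBR = NBR_pre - NBR_post;
    RBR = dNBR / (NBR_pre + 1.001); NDVI = (NIR - Red)/(NIR + Red) on the
    post-year image. Zero denominators yield nodata.
    """

    def _nd(a, b):
        den = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den == 0, np.nan, (a - b) / den)

    nbr_pre = _nd(pair.pre.band("NIR"), pair.pre.band("SWIR"))
    nbr_post = _nd(pair.post.band("NIR"), pair.post.band("SWIR"))
    dnbr = nbr_pre - nbr_post
    den = nbr_pre + RBR_OFFSET
    with np.errstate(divide="ignore", invalid="ignore"):
        rbr = np.where(den == 0, np.nan, dnbr / den)
    ndvi = _nd(pair.post.band("NIR"), pair.post.band("R"))
    return MultibandRaster(
        pair.pre.grid,
        ["NBR_pre", "NBR_post", "dNBR", "RBR", "NDVI"],
        np.stack([nbr_pre, nbr_post, dnbr, rbr, ndvi]),
    )


def compose_predictors(pair: ScenePair,
                       forest_mask: np.ndarray | None = None) -> PredictorStack:
    """Assemble the full predictor stack for one year pair.

    PCA is fitted per image on the 4 native-resolution bands (B, G, R, NIR),
    restricted to ``forest_mask`` cells when given; component correspondence
    across years is by index. RBR needs SWIR — if it is absent the stack is
    17 bands and flagged non-standard with a warning.
    """
    four = ["B", "G", "R", "NIR"]
    pre4, post4 = pair.pre.select(four), pair.post.select(four)
    scores_pre = pca_scores(pre4, fit_pca(pre4, forest_mask))
    scores_post = pca_scores(post4, fit_pca(post4, forest_mask))
    sub = pca_change(scores_pre, scores_post, "subtract")
    div = pca_change(scores_pre, scores_post, "divide")

    planes, meta = [], []

    def add(raster, source):
        for i, name in enumerate(raster.band_names):
            planes.append(raster.band(name))
            meta.append({
                "name": f"{source}_{name.lower()}",
                "source": source,
                "component": i + 1,
                "rank": len(meta) + 1,
            })

    add(focal_stats(sub, "mean"), "focal_mean_pcasub")
    add(focal_stats(sub, "std"), "focal_std_pcasub")
    add(focal_stats(div, "mean"), "focal_mean_pcadiv")
    add(focal_stats(div, "std"), "focal_std_pcadiv")

    has_swir = "SWIR" in pair.pre.band_names and "SWIR" in pair.post.band_names
    if has_swir:
        idx = spectral_indices(pair)
        planes.append(idx.band("RBR"))
        meta.append({"name": "RBR", "source": "RBR", "component": 0,
                     "rank": len(meta) + 1})
    else:
        warnings.warn("SWIR band missing: RBR omitted, stack is non-standard "
                      "with 17 bands", stacklevel=2)
        # NDVI still needs Red/NIR only
        idx = None
    red, nir = pair.post.band("R"), pair.post.band("NIR")
    den = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(den == 0, np.nan, (nir - red) / den)
    planes.append(ndvi)
    meta.append({"name": "NDVI", "source": "NDVI", "component": 0,
                 "rank": len(meta) + 1})

    raster = MultibandRaster(pair.pre.grid, [m["name"] for m in meta],
                             np.stack(planes))
    return PredictorStack(raster, meta)


def prune_correlated(stack: PredictorStack, threshold: float = 0.75) -> PredictorStack:
    """Flag one band of every highly correlated pair as not kept.

    Pearson correlation is computed over all mutually finite pixels of the
    kept bands. Pairs are visited in rank order; when |r| exceeds the
    threshold the band with the larger rank number (lower priority) is
    flagged, and already-flagged bands are skipped. A constant band has
    undefined correlation and is treated as uncorrelated, with a warning.
    """
    kept = stack.kept.copy()
    if kept.sum() < 2:
        raise ValueError("need at least 2 kept bands to prune")
    vals = stack.raster.values
    finite = np.all(np.isfinite(vals[kept]), axis=0)
    flat = vals[:, finite]
    sd = flat.std(axis=1)
    constant = sd == 0
    if constant[kept].any():
        warnings.warn("constant predictor band: correlation undefined, "
                      "treated as uncorrelated", stacklevel=2)
    order = np.argsort([m["rank"] for m in stack.band_meta])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(flat)
    for ai in range(len(order)):
        i = order[ai]
        if not kept[i] or constant[i]:
            continue
        for aj in range(ai + 1, len(order)):
            j = order[aj]
            if not kept[j] or constant[j]:
                continue
            if np.abs(corr[i, j]) > threshold:
                kept[j] = False
    return PredictorStack(stack.raster, stack.band_meta, kept)
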