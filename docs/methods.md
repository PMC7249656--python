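# Methods

This note documents the models, parameter choices and numerical conventions
behind `treatscan`, and what the synthetic-scene tests do and do not show
about real imagery.

## Data model and conventions

Rasters are square-celled lattices in a projected, metric CRS; cell
(0, 0) is top-left and a cell's value represents its full square footprint.
Geographic (degree) CRSs are rejected because every area rule downstream is
in hectares. In memory, nodata is NaN; any operation consuming a nodata cell
emits nodata, and statistics ignore nodata. GeoTIFF I/O writes the
pixel-scale/tiepoint tags plus a JSON band manifest; polygons are GeoJSON
(shapely geometries with a pandas attribute table).

## Change features

PCA is fitted **per image** (not jointly on the pair) by SVD of the centered
pixel matrix over forest-mask cells; component correspondence across years
is by index, which assumes the dominant covariance axes of a landscape are
stable between two late-summer acquisitions — reasonable when most of the
scene is unchanged, and the reason the fit is restricted to forest.
Explained variances use the sample (n−1) denominator and sum to the total
band variance. Each loading column is sign-fixed so its largest-|loading|
entry is positive; without this, arbitrary SVD sign flips would corrupt the
change metrics.

The two change metrics are intentionally asymmetric in orientation:
the difference runs post − pre while the ratio runs pre / post. The ratio's
denominator is guarded at |PC| < 1e-9 → nodata. The focal standard
deviation uses the population (÷N) denominator, the convention of GIS focal
statistics; edge cells use the ≥4 neighbors that exist. NDVI is computed on
the post-year image: change is judged against the most recent state
(configurable by passing a different pair). The RBR denominator offset
1.001 keeps the index finite for any NBR_pre > −1.001.

Correlation pruning computes Pearson r over all mutually finite pixels
(not a sample), visits band pairs in rank order (stack position = priority)
and flags the higher-rank-number band of any pair with |r| > 0.75; flagged
bands are skipped in later comparisons, so the result is deterministic and
independent of pixel traversal order. A constant band has undefined r and is
treated as uncorrelated, with a warning.

## Histogram matching

Implemented as exact empirical-quantile matching: each source value passes
through the source empirical quantile function and the reference inverse
quantile function, linearly interpolated between order statistics. This
makes matching a band onto itself the exact identity and undoes a constant
radiometric offset exactly — the two properties that matter for paired-year
harmonization. A fixed-bin variant was considered and rejected: with
desk-scale images most bins are empty and the lookup quantizes at ~2 bin
widths. A constant-valued band cannot be matched (its CDF is not
invertible) and is passed through with a warning. By default all finite
pixels participate; masked workflows can match after masking.

## Training samples

500 candidate points are drawn uniformly over forest cells (cell centers,
so predictor extraction is exact indexing rather than interpolation) and
labeled by point-in-polygon against the mechanical-treatment truth.
Prescribed fires are excluded from the truth used here: training targets
mechanical treatments; fires are recovered separately from burned-area
products. Candidate cells inside target-year wildfire perimeters or on
known burned cells are excluded from the pool — this stands in for the
analyst's per-point verification step, which discards locations known to be
disturbed by something other than a treatment; without it, burned ground
enters the non-treatment class with a strongly treatment-like spectral
signature and dominates the classifier's error.

Because treatments cover a small landscape share, the raw draw is
imbalanced; points are added uniformly inside treatment polygons until the
treatment share reaches 30% ± 2 points (solving (t+k)/(n+k) = 0.3).
Non-treatment points are never deleted; a `relocate` option instead moves
some of them, mimicking the alternative manual workflow. The ±2-point
tolerance operationalizes "approximately 30%".

## Random Forests

Each of 100 trees trains on an independent 66% subsample **without
replacement** (a fixed-ratio subsample, not a bootstrap) with ⌊√p⌋ features
per split; tree induction is delegated to
`sklearn.tree.DecisionTreeClassifier`, but the subsampling, out-of-bag
bookkeeping, error metrics and vote prediction are this package's own (the
sklearn ensemble's bootstrap/OOB machinery is deliberately not used, since
its resampling scheme differs). For sample *i* with OOB treatment-vote
fraction *p_i* and label *y_i*, let *q_i* be the vote for the true class;
then RMSE = √mean(1−q)², average relative error = mean(1−q), and the
relative classification error is the fraction with q < 0.5, counting tied
votes as errors for the treatment class (a tie classifies as non-treatment).
Determinism: all per-tree subsamples and sklearn random states derive from
one seed. Under label permutation the classification error floors at the
minority fraction (~0.30) plus a small correlated-vote excess (~0.36
observed); on separable data it is ~0.

## Segmentation

The vote band is smoothed by value-domain mean-shift filtering with a flat
kernel: pixel positions stay fixed and each pixel's value iterates to the
mean of values within a square spatial window that lie within the range
bandwidth (max 100 iterations, or until the largest shift is below 1e-4 of
the data range). The 1–20 "detail" knobs of the reference tool map
monotonically to bandwidths — spatial bandwidth h_s = 21 − spatial_detail
cells (window half-width), range bandwidth h_r = (21 − spectral_detail)/20
of the band's range — a convention fixed here so results are reproducible;
the reference implementation's internal mapping is unpublished, so outputs
are compared at the property level only (e.g. higher spectral detail never
yields fewer segments). Filtered cells are grouped by 8-connected
components of near-equal value (tolerance h_r), and segments below 10 cells
are merged, smallest first, into the adjacent segment with the closest mean
(ties to the lower id). Labels are renumbered contiguously from 1 in
row-major first-occurrence order, so ids are stable and arbitrary.

## Polygons and filtering

Cells above the vote threshold are vectorized as unions of cell-boundary
squares over 8-connected components, so rasterizing the polygons back
reproduces the thresholded cell set exactly, and corner-touching harvest
blocks form one unit. The filtering ledger runs in order — (1) area < 1 ha,
(2) any intersection with a wildfire perimeter (boundary contact counts),
(3) > 50% of area over non-forest cells, (4) optional user exclusion
polygons — and removed polygons carry the first reason that fired, with
accepted ∪ removed equal to the input. The >50% non-forest rule is a
deterministic surrogate for the manual deletion of agricultural and
non-forest false positives; cloud/shadow/snow deletions are not automated
and are exposed as the user-exclusion filter. A helper suggests a vote
threshold as the 5th percentile of segment means inside known treatments;
the driver uses it when no explicit threshold is given.

Clearcut-vs-thinning labeling of accepted polygons is user-supplied (a
`type` attribute), not automated: separating them reliably requires visual
or field context.

The kernel-density summary rasterizes accepted treatments to 100-m binary
cells, converts treated cells to points and sums a quartic (biweight)
kernel, K(d) = 3/(πR²)(1 − (d/R)²)², over a 1-km radius, in points per km²;
the output grid is padded by one radius so total kernel mass is conserved
(within ~0.5% discretization).

## Accuracy assessment

Binarization is strict ("higher than" the threshold). The chi-square is the
uncorrected n(ad − bc)²/((a+b)(c+d)(a+c)(b+d)) on one degree of freedom —
the form that reproduces the published statistics from their count tables —
and is undefined (reported as None) when a marginal is zero. The standard
error is the binomial SE of overall accuracy, √(p(1−p)/n); it is
informational output, not a validated statistic. ROC thresholds are the
distinct scores in descending order with tied scores grouped into one step;
the trapezoidal AUC is then exactly the Mann–Whitney U statistic with ties
counted one half (asserted against a pair-counting oracle in the tests).

## Synthetic scenes

The generator emulates what the method needs from real imagery: spatially
autocorrelated reflectance (Gaussian-filtered noise at scale 5 cells,
shared between years so the pair is correlated, plus independent per-pixel
noise of SD 0.03), healthy-vegetation band structure (forest means B 0.04,
G 0.07, R 0.05, NIR 0.40, SWIR 0.18 on a unitless [0, 1] reflectance
scale), and footprints as random rotated ellipses (default 2–6 ha)
rasterized through cell centers. Post-year band multipliers encode the
signatures: clearcuts scale NIR by (1 − e) and raise R/SWIR with e = 0.5 by
default, thinnings the same with e = 0.2, fires drop NIR and raise SWIR
(e = 0.4) so post NBR < pre NBR. Wildfires are larger fire-signature
patches with their perimeter polygons supplied; confusers include an
agricultural green→plowed patch outside the forest mask and a shadow patch
(all bands × 0.4). Burned-area rasters assign prescribed fires alternately
to two acquisition dates, with wildfire cells on the first. The default
scene is 240×240 cells at 10 m (576 ha, 70% forest). All randomness flows
through named child streams of one seed in a fixed draw order, so the same
seed is bit-identical and adding confusers never moves treatments.

What passing tests on these scenes shows: the pipeline recovers planted
treatments whose spectral contrast exceeds the noise, rejects
wildfire-overlapping and sub-hectare detections, and ranks clearcut >
thinning > background in vote strength. What they do not show: robustness
to atmospheric and phenological variation, misregistration, topographic
shading, cloud contamination, or the visual-interpretation steps a real
campaign needs — scene radiometry here is idealized and treatment
boundaries are crisp ellipses.

## Problem sizes and determinism

Tests run on 120–240-cell-square scenes; the reference end-to-end
configuration is a 240×240 scene with ten mechanical treatments (five
clearcuts, five thinnings, ≥ 2 ha), two prescribed fires, one wildfire and
two confusers — small enough to iterate quickly while leaving every stage
non-trivial (~600 training points, ~80 segments, ~30 candidate polygons).
Every stochastic element (scene, sampling, forest, validation) is seeded;
re-running a pipeline config reproduces all outputs bit-wise, which the
manifest (SHA-256 per artifact) makes checkable.

## Known limitations

* Vector I/O is GeoJSON only; no GeoPackage/Shapefile, no reprojection —
  inputs must already share one metric CRS and grid.
* The mean-shift detail→bandwidth mapping is this package's fixed
  convention, not a reverse-engineered match of any proprietary tool.
* OOB error metrics follow the contract above; other definitions of
  "average relative error" exist and would shift those numbers.
* The kernel-density integral is exact only up to 100-m discretization.
* Scenes are desk-scale and held in memory; there is no tiling for
  satellite-tile-sized rasters.
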