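# Methods

This note documents the models, conventions and numerical choices behind
`ecovuln`, and what the synthetic data can and cannot show.

## Data model and conventions

The analysis grid is a regular raster (`GridSpec`): row 0 is the top
(north) row, `(x_origin, y_origin)` the lower-left corner, coordinates
planar (pre-projected; great-circle distances are out of scope), cell
size in meters (default 1000 m). Invalid cells are NaN in memory and a
sentinel (default −9999) on disk. Areas convert exactly as
`cell_size² / 10⁶` km². The exchange raster format is the ESRI ASCII
grid, written with full float `repr` so write∘read round-trips
bit-exactly; station tables are `x,y,value` CSV; run configuration is
YAML, validated in one pass that reports every problem at once.

## Interpolation (IDW)

Station values are gridded by inverse-distance weighting,
z₀ = Σ zᵢ dᵢ⁻ⁿ / Σ dᵢ⁻ⁿ, over the N nearest stations. Defaults n = 2
and N = 12 — the de-facto defaults of the desktop GIS tools this
workflow is usually run in; both are configurable. Stations tied with
the N-th nearest distance are all included, making the cutoff
independent of input order. A target within ε = 1e−9 coordinate units
of a station returns that station's value exactly (the d → 0 limit)
rather than dividing by zero. Estimates are convex combinations of
station values, hence always within [min z, max z].

## Standardization and extraction

Each layer is min-max scaled over its own valid cells (not theoretical
ranges); inverse polarity maps to 1 − scaled. Every indicator defaults
to direct polarity — including ecologically ambiguous ones like NDVI and
fire frequency — with per-indicator inversion exposed in the config and
logged; this keeps the index algebra monotone and leaves the ecological
sign judgment to the analyst. A constant layer cannot be scaled and is
rejected by name. Interpolation happens before standardization. Cells
enter the observation matrix only if valid in all fifteen layers
(intersection mask); column order is fixed by the configuration, so the
matrix is independent of file load order.

Bilinear resampling interpolates each target cell center from the four
surrounding source centers; a target whose 4-point stencil touches
nodata, or which falls outside the source center extent, is nodata
(conservative propagation).

## Composite index

PCA is performed on the correlation matrix (columns centered, unit
variance, ddof = 1), without rotation. Eigenvalues are clipped at zero
and sorted descending; eigenvector signs are fixed by making the
largest-magnitude loading of each component positive, so repeated fits
are bit-identical. Retention keeps the smallest q whose cumulative
variance share reaches the threshold (default 0.80; results on
synthetic data are stable across 0.75/0.80/0.85, which the suite
checks by rank correlation > 0.9). Weights are variance ratios of the
retained eigenvalues, with the last element computed as the complement
so the sum is exactly 1.

Component scores are centered, so the raw weighted score can be
negative while classification needs [0, 1]; the raw surface is min-max
rescaled before classification and both surfaces are kept. Because
eigenvector signs are conventional, the raw composite score could point
either way; its sign is fixed so that it correlates nonnegatively with
the cell-wise mean of the standardized indicators, which under direct
polarity rises with vulnerability. This orientation step uses only the
fitted matrix and is deterministic.

## Additive index

Component indices are plain means of their standardized members; the
vulnerability index is a convex combination of exposure, sensitivity
and adaptation (exact thirds by default — a printed 0.340/0.330/0.330
split is treated as display rounding of thirds), so it stays in [0, 1]
with no rescaling. Weights are accepted at the component level only;
per-indicator reweighting inside a component is out of scope.

## Classification and areas

Five equal-width classes on [0, 1], half-open intervals [b, b+0.2) with
1.0 top-inclusive, so every value — including ones inside the printed
two-decimal gaps like 0.205 — gets exactly one class. Class areas are
cell counts times cell area; they sum to the total valid area exactly.
Comparisons report b − a per class with Inc/Reg/Stable tags.

## Spatial statistics

Contiguity weights are rook or queen on the valid mask, optionally
row-standardized (default: queen, row-standardized — the default of the
GIS tool this pipeline emulates). Global Moran's I is reported with its
closed-form expectation −1/(N−1), a normality z-score, and an optional
seeded permutation test. Gi* always uses binary contiguity plus a
self-weight of 1 (the "star" variant), whatever the row-standardize
flag of the weights passed in; confidence classes use two-sided normal
thresholds 1.645/1.960/2.576 (90/95/99 %) with no multiple-testing
correction, matching common hot-spot-mapping practice. Note an edge
effect inherent to Gi*: cells with smaller neighborhoods (borders)
have smaller denominators, so the maximal z for an isolated spike can
sit on a neighboring edge cell rather than the spike itself.

Pearson correlations flag constant columns as undefined (NaN) rather
than zero. OLS uses `numpy.linalg.lstsq` with an explicit intercept,
reports R² (and multiple R as its positive root, plus adjusted R²), and
names collinear columns on rank deficiency.

## Enhancement (best-subsets re-weighting)

The published workflow used a proprietary automatic-linear-modeling
procedure whose criterion is not reproducible from its description.
This package defines the stage precisely: every nonempty subset of the
components is fit by OLS against the observed index (2^p − 1 fits,
exhaustive for p ≤ 15), ranked by adjusted R² (AIC/BIC selectable);
ties break toward fewer predictors, then lexicographic enumeration
order, so selection is deterministic. The winning coefficients are
clamped at zero and normalized into weights (idempotent; all-nonpositive
coefficients are an error). With the default self-calibration response —
the observed EVI regressed on its own components — the recovery is exact
and the stage reproduces the observed weights, which is the intended
idempotence check; a genuinely different weighting requires an external
response surface, which the API accepts. The published enhanced weight
rows are shipped as fixtures so the area-comparison path is exercised
with realistic weights, without claiming to re-derive them.

## Synthetic country

`make_country` generates, from one seed: (a) four climate indicators as
smooth Gaussian random fields (white noise convolved with a Gaussian
kernel; "smoothing radius" is the kernel sigma in cells, default 10)
blended with a unit-variance north–south linear trend so that a fraction
g (`gradient_strength`, default 0.7) of the variance is the planted
gradient, sampled noiselessly at 30 random station cells so
exactness-at-stations is testable end to end; (b) a 12-province
partition by nearest-seed growth, with a small (1 % of area) southern
province whose density is multiplied by 200 — the "economic capital"
extreme, the same order as the ~223× provincial density contrast in the
motivating study; (c) four province-constant socio-economic layers whose
southern bias scales with g (nothing is planted at g = 0); (d) four
thematic layers on a 2× finer grid to exercise bilinear resampling, the
NDVI-like layer negatively coupled to density; (e) three patchy hazard
layers from Gaussian blobs with a g-proportional southern placement
bias. A truth table records what was planted.

What passing tests show: the pipeline recovers a planted dominant
gradient (composite |r| > 0.8 with latitude in ≥ 18 of 20 default
seeds; the additive index is diluted by province-constant layers but
stays > 0.6), distinguishes smooth from random fields by Moran's I, and
is byte-reproducible per seed. What they do not show: performance on
real data with anisotropy, measurement error at stations, non-linear
indicator relationships, or realistic geography — none of which the
generator emulates. Two quantitative caveats measured on the generator:
at g = 0 the smooth fields still align with latitude by chance (|r| up
to ~0.7 across seeds; the frozen test asserts the seed-0 value), and
the extreme province reaches the top class in ~90 % of seeds rather
than always, because min-max rescaling lets other outliers stretch the
scale — the tests assert majority behavior, and its top-percentile rank,
rather than certainty.

## Problem sizes and tolerances

The default synthetic country is 100 × 80 cells (≈ 5,600 valid); the
test suite uses 60 × 48 and smaller grids for module-level checks and
brute-force O(N²) oracles on ≤ 8 × 8 grids, keeping the full suite in a
few seconds. Numerical tolerances: eigenvalue trace and score
orthogonality 1e−8; oracle equivalences 1e−10; weight sums exact by
complement. Degenerate inputs (constant layers, rank-deficient designs,
empty masks) raise typed errors naming the offender rather than
propagating NaNs.

## Known limitations

No CRS handling or reprojection (inputs must share a projected CRS); no
GeoTIFF I/O (ESRI ASCII only); no kriging, LISA cluster typing, factor
rotation, or DEM-derived slope — the surrounding workflow is expected
to supply such layers as inputs. The published Moran's I values and
loading tables of the motivating study depend on undeposited data and
are treated as fixtures, not reproduction targets.
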