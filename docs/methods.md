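# Methods

This note documents the models and procedures implemented in `duckscape`,
the assumptions behind the synthetic study system, the parameter choices
that matter, and the known limitations.

## 1. The synthetic study system

The generator (`simdata`) is a virtual-ecologist model of a
prairie-pothole breeding-duck survey.  It exists so that every stage of
the analysis — detection correction, covariate construction, yearly
forest models, abundance surfaces, estimator reconciliation — can be
tested against a known truth.  It is not a demographic model: there is no
survival, recruitment, or movement; each year a fixed total pair
population is placed on the landscape afresh.

**Grid and geometry.** A local metric grid of 400-m square cells
(0.16 km², matching the analysis resolution of the emulated survey
products); row 0 is the north edge.  The default landscape is 290 × 200
cells (116 × 80 km).  The width is deliberately an exact multiple of the
29-km segment length (72.5 cells), so transects cut into full-length
segments only; trailing partial segments are geometrically supported but
excluded from modeling inputs (see §3).

**Static landscape.** Climate normals follow broad deterministic
gradients (degree-days DD5 increase southward, precipitation eastward)
plus smooth Gaussian-filtered noise; the annual moisture index AMI is
DD5/precipitation, and landcover is coupled to it — cropland tracks the
warmer/drier end, grassland the opposite — so land use and climate are
collinear, as in the real region.  Wetland basin counts are Poisson with
a spatially clustered, northward-increasing intensity (mean 1.8
basins/cell, ~3× range north to south); basin area is proportional with
lognormal scatter and capped at the cell area.  The binary country
indicator splits the landscape at mid-height.  Landscape fields are
smooth at 6–10-km correlation scales: structure much finer than a
segment strip would be invisible to the survey that trains the models,
and would only manifest as prediction-time extrapolation artifacts.

**Wet/dry cycle.** The moisture index M_t is a stationary spatially
correlated AR(1) field: M_t = a·M_{t−1} + √(1−a²)·σ·E_t with a = 0.6,
σ = 1, and E_t smooth unit-variance innovations (8-km scale).  Each
cell's pond count is Binomial(basins, logistic(3.5·M)) realized through a
fixed per-cell latent wet-propensity uniform, so the same basins tend to
be the wet-prone ones year after year — constant forcing reproduces the
identical pond raster every year, and the pond pattern has realistic
temporal persistence.  The steep logistic makes wetness effectively
regional: whole districts dry out or flood between years, which is what
gives the current-year pond covariate its identifiable signal against its
own lags.  NDWI and GPP are noisy monotone transforms of moisture —
deliberately noisy, as satellite proxies are, so they supplement rather
than replace the pond counts.

**Settling.** Cell weights are

    w = max(0, b0 + 1.0·s(P_t) + 0.1·s(P_{t−1}) + 0.05·s(P_{t−2}))
        · exp(0.6·grass − 0.6·crop + 0.05·M_{t−1} + 0.02·M_{t−2})

with s(x) = x/(3+x) saturating and b0 = 0.05 a baseline making all cells
habitable.  The year's population (default series 22k–50k pairs,
~2.3-fold fluctuation) is allocated multinomially with probabilities
w/Σw, so the cellwise sum equals the year total exactly.  Current-year
water dominates by construction; lags and landcover are real but
secondary — the ordering the analysis is meant to recover.

**Survey.** Strata are horizontal bands (default 8 of 10 km).  Within
each, east–west transects run at 1.2-km spacing, snapped to cell-center
rows, each cut into 29-km segments with a 200-m strip on both sides —
one row of cells by center-in-strip membership, a deterministic
partition.  Per-stratum detection probabilities are drawn once from
U(0.5, 0.9) and held fixed across years.  Aerial pair and pond counts
are independent binomial thinnings of the strip truth; ground crews on a
30 % comparison subset count perfectly, so the true VCF is 1/p.  Two
burn-in years precede the first modeled year so t−1/t−2 lags exist; they
reuse the first year's population total and contribute pond observations
only.

**Scale calibration.** The population series and landscape size were set
so the mean segment pair count is ≈117 with median below mean — the
response scale the emulated survey reports — and so stratum densities
span roughly an order of magnitude.

## 2. Detection correction and the design-based estimator

VCF(stratum, year) = Σ ground / Σ aerial over comparison segments,
separately for pairs and ponds, with a pooled-within-stratum fallback
when a stratum-year's aerial sum is zero (an all-dry year makes the pond
VCF undefined — then it is an error, reported as such).  Corrected
count = aerial × VCF.  As a ratio of sums this estimator is consistent
with O(1/total-count) small-sample bias; with comparison totals in the
hundreds the bias is far below Monte-Carlo resolution, and the
unbiasedness experiment in the acceptance suite keeps counts at that
scale.

The design-based stratum estimate is the classical strip-transect
expansion: density = Σ corrected pairs / Σ sampled area, estimate =
2 × density × stratum area (pairs → individuals; the ×2 is applied in
*both* estimators so they share units).  The standard error treats
transects as primary sampling units with the ratio-estimator variance
n/(n−1) · Σ(c_i − D·a_i)² / (Σa)², scaled by 2 × stratum area.  Note the
estimator is design-unbiased for the strip superpopulation; with
systematic transects over a deterministic habitat gradient, strip truth
can differ from stratum truth by a fixed geometric factor — the
unbiasedness experiment therefore uses a gradient-free configuration.

## 3. Covariates

All raster predictors pass through a circular focal mean of exactly
11 km² (disc radius 1.871 km; shrink-window normalization at edges), so
segment covariates (strip means of the focal rasters) and grid-cell
covariates share the same spatial support.  Topographic variation is the
elevation CV (sd/mean) in 41-km² neighborhoods (radius 3.612 km), then
strip-averaged per segment.  Corrected segment pond counts are spread
across the grid with inverse-distance weighting (power 2, k = 12 — the
common GIS defaults) from segment centroids, for the current year and
two lags; the drought index is sampled at coarse stations (every 8 km),
IDW-interpolated, and focally averaged, mirroring the station-supported
origin of real drought indices.  GPP stays at native pixel support and
is extracted at the pixel nearest the segment centroid.  Climate normals
are pruned greedily to pairwise |r| ≤ 0.65 with priority DD5 > AMI >
SSPB; everything else is always offered.  The offered set is the 18
named predictor columns (or 17 when a climate normal is pruned).

Segments shorter than half the nominal length (possible on custom grid
sizes) are excluded from the covariate matrix and the pond IDW support:
their counts reflect sampled area, not habitat, and a handful of
near-zero rows measurably distorts both the forests and the interpolated
pond surfaces.  They remain part of the survey design and the
design-based estimator.

## 4. Yearly models and selection

One `RandomForestRegressor` per year: 1000 trees, mtry = ⌊p/3⌋, minimum
node size 5 (implemented as `min_samples_split=5` — a node of five rows
may still split, matching the classical regression-forest default; using
it as a minimum *leaf* size over-smooths), bootstrap with out-of-bag
predictions.  Variance explained is 100·(1 − MSE_oob / Var(y)) with the
n−1 sample variance.  Importance is out-of-bag permutation importance:
per tree, the MSE increase on its own OOB samples when one predictor is
permuted within them, averaged over trees.  This is implemented directly
(over `estimators_samples_`) because training-set permutation importance
discriminates poorly among the strongly collinear pond covariates.

Model selection follows the model-improvement-ratio recipe: scale
importances so the top variable is 1; for thresholds 0.0, 0.1, …, 1.0
retain variables at or above the threshold and refit; pick the candidate
with the lowest OOB MSE, ties toward fewer variables.  The reported
importances are rescaled within the selected model; the stored variable
list preserves training column order, which prediction must match.
Significance: refit on B response permutations, p = (1 + #{null
variance-explained ≥ observed})/(B+1); minimum attainable p is 1/(B+1).
Goodness of fit reports count-scale RMSE and the five-number summary
plus mean of OOB residuals (predicted − observed), quantiles by linear
interpolation.  Functional-response curves use hand-rolled loess —
locally weighted quadratic regression with tricube weights, span 0.75 —
because the available lowess implementations are degree-1 only.

Per-year seeds are base_seed + year; every stochastic operation takes an
explicit seed.

## 5. Surfaces, aggregation, binning

A year model predicts, at each cell, the expected pair count of a
segment-sized window centered there; the cell contribution is
P · cell_area / 11.0 km².  The constant 11.0 matches the ~11.6 km²
sampled area of a 29-km × 400-m segment; the ~5 % mismatch inflates
landscape totals slightly and is visible in the model-vs-design percent
difference (§6).  Surfaces built from substantially different segment
lengths should pass the matching `window_area_km2` explicitly.  Negative
predictions floor at zero (moot for forests); nodata covariates yield
nodata predictions.  Aggregation across years is cellwise mean,
population SD (divisor n), and max.

Percent-population binning uses the first-crossing rule: walk cells in
decreasing density (ties by linear cell index), assigning cells to bin b
while the b % cumulative-share threshold is unmet.  The cells labeled
≤ b are then exactly the smallest decreasing-density area containing b %
of the predicted population; bins can be empty when one cell crosses
several thresholds, zero-density cells land in bin 100, and the per-bin
duck totals sum to the surface total exactly.

## 6. Estimator reconciliation

Model-based stratum estimates (2 × surface sum over the stratum's cells)
and design-based estimates are compared by OLS of design on model over
all stratum-years (a mean-over-years variant is available via the
estimates table), by standardized residuals (residual / residual SE with
n−2), flagging strata below −2 in strictly more than half the years, and
by yearly totals with the design CI = ±1.96·√(ΣSE²).  On the default
system the regression yields slope ≈ 0.95–1.05 and r² ≈ 0.96–0.99, with
the model predicting ~6–9 % more birds than the design expansion — the
net of the window-rescale inflation minus the forest's compression of
extremes.  Pond-year similarity scans all year pairs of corrected total
pond counts for the minimum absolute difference (ties to the earliest
pair).

## 7. What passing tests do and do not show

The generator reproduces the statistical *structure* the analysis
assumes — detection as binomial thinning, pond-driven settling with
lags, collinear climate/landcover, segment-supported observation — but
not real-data pathologies: observer effects and misidentification,
spatially varying detection within strata, non-stationary settling
rules, boundary effects of a non-rectangular study region, or map-scale
wetland digitization error.  Recovery of the pond-dominance ordering and
estimator concordance here demonstrates the pipeline is correct and
well-calibrated under its own assumptions, not that those assumptions
hold for any particular real survey.

Numerical conventions worth knowing: rasters use −9999 nodata; focal
windows renormalize rather than pad at edges; IDW returns the sample
value exactly at zero distance; correlation pruning drops constant
columns with a warning; model selection falls back to the full model if
a custom threshold grid strands every candidate; an all-dry stratum-year
with no pooled pond counts makes the pond VCF an explicit error rather
than a silent 1.

Default problem sizes (290 × 200 cells, 192 segments × 9 years, 1000
trees) run the full pipeline in about 1–2 minutes on one CPU; the
examples use smaller landscapes with 300-tree forests.
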