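# Methods

This note documents the models, parameter choices and numerical decisions
behind `isoprov`, and what the synthetic experiments do and do not
demonstrate about real data.

## The assignment model

A tissue isotope value `z` is modelled per map cell `c` as
`z ~ Normal(m(c), s(c))`, where `m` is the (calibrated) isoscape mean and
`s` its per-cell uncertainty. With a flat prior over the raster footprint,
the posterior probability of origin is the normalized likelihood. The Sr and
O posteriors are combined by a per-cell product (conditional independence of
the two systems given location) and renormalized. Assumptions worth keeping
in mind:

- the isoscape uncertainty is treated as the full predictive SD at a cell;
  spatial correlation of isoscape errors is ignored;
- the flat prior contains no habitat or abundance information;
- posterior mass is per *cell*, not per km². At high latitudes cell areas
  shrink with cos(latitude); an optional `area_weighting` flag multiplies
  masses by cos(latitude) for per-area interpretation. It is off by default
  so that the default output matches the per-cell convention of common
  assignment tooling; at Scandinavian-type latitudes the difference is
  material, which is why it is a visible switch rather than a silent choice.

Per-cell Sr uncertainty is the quantile-forest error map passed through the
calibration (`sqrt((slope·sd)² + residual_sd²)`); O uncertainty is a
constant 1‰ map (a conservative convention for precipitation isoscapes)
propagated the same way. Propagating the calibration residual is an explicit
design choice: it makes the assignment variance reflect the observed
tissue-vs-isoscape scatter rather than the map error alone.

The "top q" origin region is area-based by default (the ⌈q·N⌉ highest-mass
cells, ties included); a cumulative-probability mode (smallest cell set
holding mass q) is also implemented, since both conventions circulate and
they differ strongly for peaked posteriors.

## Sr isoscape

Random-forest regression of point ⁸⁷Sr/⁸⁶Sr on environmental rasters, never
on coordinates, so predictions generalize through environmental similarity
rather than spatial proximity. Hyperparameters follow the regression
conventions of the R forest packages this workflow family uses: 1000 trees,
`mtry = ceil(p/3)`, terminal node size 5. Node size 5 matters twice: it is
the R default, and quantile estimation needs non-degenerate terminal-node
response distributions.

Predictor selection ranks candidates by permutation importance measured on
a one-third held-out split (training-set importance rewards overfit splits
on uninformative predictors) and keeps those above 5% of the maximum
importance, always at least one.

Cross-validation uses a simple random k=10 partition by seed. Spatial
blocking is deliberately not used (it is a different estimand — transfer
error rather than interpolation error); this matches the plain k-fold
convention and is noted as an extension point.

The uncertainty map is a quantile regression forest in the Meinshausen
sense: each prediction point inherits weight 1/|leaf| on every training
observation sharing its terminal node in a tree, weights averaged over
trees; the weighted empirical quantiles of the training responses give
per-cell q₀.₁₆/q₀.₈₄ and the error map is half their difference (a ~68%
half-interval, comparable to a 1σ). For homoscedastic Normal noise this
estimator's map-median recovers the noise SD to within ~±30%, which is the
tolerance used in tests.

## Conversions

All conversions are affine with constants in
`src/isoprov/data/conversion_constants.yml`, each with a citation string:
carbonate→phosphate (all-mammal relation, slope 1.037, intercept 8.57‰),
phosphate→drinking water (deer relation, forward slope 0.813, intercept
22.02‰), VPDB→VSMOW (slope 1.03091, intercept 30.91‰). Keeping them in
configuration rather than code makes alternative calibrations (species-
specific equations, updated scale conversions) a data change.

The Suess correction subtracts `L(year of death) − L(reference year)` from
measured δ¹³C, where `L` is a LOESS fit (tricube-weighted local polynomial,
span 0.3, degree 2, fitted on the record's annual resolution) of an
atmospheric CO₂ δ¹³C record. Span 0.3/degree 2 smooths the secular trend
without chasing interannual noise. Beyond the record's span the fit is
continued as a constant only when extrapolation is explicitly enabled;
silent trend extrapolation is refused. Degree 1 reproduces standard lowess
implementations to within plotting accuracy; degree 2 reduces boundary bias
at the record ends, which is where the 1800 reference sits.

## Locality classification

`Δ = tissue value − buffered isoscape mean` at the death site, per axis
(Sr ratio; water-equivalent δ¹⁸O against the precipitation surface with no
further offset). Buffered extraction is the unweighted mean of non-nodata
cells whose centers lie within the great-circle radius (haversine, Earth
radius 6371 km); if no center falls inside, the containing cell is used.
Center-in-circle selection without partial-area weighting keeps results
bit-stable and is equivalent to the brute-force oracle used in tests.

The 1σ rule computes mean and SD of each Δ distribution once over **all**
samples (outliers included, no iterative re-trimming) and flags a sample
non-local when it is outside 1σ on either axis. Mean ± SD (not median ± SD)
is used. Consequences a user should understand:

- with two axes, even perfectly local Gaussian data would only be retained
  at ≈ 0.68² ≈ 46% unless the pooled SDs are inflated by genuinely
  contrasting non-locals — the rule's usefulness *depends on* the outliers
  it is meant to find;
- an additive tissue offset (antler mineralizes in spring/summer and sits
  ~+1‰ above bone on the water-equivalent scale) displaces that tissue's Δ
  distribution; with a +1‰ offset comparable to the pooled SD, roughly a
  third of local antlers are intrinsically misflagged. This is a property of
  the published rule, faithfully reproduced, not of this implementation.

The Mann-Whitney U test used for group comparisons (sex, tissue) enumerates
the exact null over all assignments of the pooled midranks when both groups
have n ≤ 8 (correct under ties), and uses the tie-corrected normal
approximation with continuity correction otherwise.

## Calibration

Classical calibration: OLS of tissue value (response) on buffered isoscape
value (predictor), fitted on locals only, applied cell-wise to the raster.
The inverse (regressing isoscape on sample) was rejected because the
workflow treats the isoscape as the predictor and reports sample-on-isoscape
slopes. Residual SD is `sqrt(SSres/(n−2))`. Fitting on pairs from an exact
affine map recovers slope/intercept to 1e−10, and refitting after applying
the calibration returns slope 1/intercept 0 (idempotence) — both asserted.

## The synthetic landscape

`make_landscape` emulates the statistical structure of a
Scandinavian-type setting on a geographic grid (default 100×100 cells over
10–25°E, 55–70°N; square 0.15° cells; row 0 north):

- **Sr field**: a Voronoi partition into `n_geo_units` geology units (default
  4), each with a base ratio drawn from [0.708, 0.748] (the range of
  regional-scale bioavailable-Sr models), plus spatially correlated noise
  (Gaussian-smoothed white noise, kernel 5 cells, pointwise SD 0.002). With
  a sea strip enabled, coastal cells are pulled toward the marine ratio
  0.7092 with a 60-km e-folding distance (sea-spray deposition).
- **Correlation length**: reported as the e-folding distance of the smoothed
  noise autocorrelation, 2·σ_kernel ≈ 120 km at the defaults — a regional
  geochemical anomaly scale.
- **δ¹⁸O field**: −8‰ at the southern edge, declining 0.6‰ per degree of
  latitude and 2.8‰ per km of elevation, plus 0.5‰ correlated noise;
  consistent with a ~10‰ span over a 15° peninsula.
- **Predictors**: a geochemical proxy = true field + 0.001 correlated error
  (the analog of a prior continental Sr model, deliberately strong because
  such products dominate real predictor rankings); elevation; coast
  distance; a latitude-driven temperature proxy; and one pure-noise layer
  that selection must discard.
- **Individuals**: origins uniform over land; a fraction (default 15%)
  displaced by a fixed great-circle distance at a uniform random bearing
  (redrawn until on land); tissue Sr = field at origin + 0.002 noise; tissue
  δ¹⁸O (water scale) = field at origin + tissue offset (antler +1‰, bone 0)
  + 0.5‰ noise; sex and tissue frequencies follow a 29M/17F/19U,
  50-bone/15-antler composition. The default displacement in the recovery
  experiments, three correlation lengths ≈ 365 km, is in the documented
  range of long seasonal/annual cervid movements (~100–500 km).
- **Atmosphere**: a logistic-ramp δ¹³C decline (slow 19th century,
  accelerating late record) normalized to an exact total decline (default
  1.5‰ over 1800–1994).

The tissue-δ¹⁸O noise (0.5‰) plus the ~±1–4‰ isotopic contrasts produced by
long displacements yield a Δ¹⁸O distribution with a compact local core and
long non-local tails — the regime in which the 1σ rule is informative. What
the generator does **not** emulate: real geological texture (intrusions,
glacial transport of till), seasonal intake vs annual precipitation
mismatch beyond a constant offset, individual-level physiological random
effects, non-uniform sampling of the landscape, and measurement covariance
between systems. Recovery results therefore demonstrate the pipeline's
correctness and its statistical behaviour under its own assumptions, not
field performance on any particular real region.

## Numerical and degenerate-input conventions

- NaN is nodata everywhere; statistics and posteriors exclude nodata cells;
  rasters must be co-registered (checked, not resampled).
- Posterior densities are computed in log space and shifted before
  exponentiation; every posterior normalizes to 1 ± 1e−9.
- Zero-SD delta distributions classify everything local, with a warning.
- Radius-scan ties break toward the smallest radius; radii with < 3 valid
  pairs are skipped with a warning.
- All randomness flows from explicit integer seeds via numpy Generators;
  identical seeds give bit-identical tables and rasters.

## Problem sizes in the shipped experiments

The test-suite and acceptance-script experiments use a 100×100 landscape,
400 training points, 1000-tree forests (500 for the CV refits), herds of
200 individuals, 60 classification replicates and 20 assignment replicates.
These sizes give replicate-averaged estimates whose Monte-Carlo error is
small relative to the thresholds being checked (e.g. the specificity
estimator's SD per 200-individual draw is ~0.03, so averages use enough
replicates that sampling noise does not decide a verdict).

## Known limitations

- The classifier's specificity under the default mixture sits near 0.80:
  the +1‰ antler offset places local antlers about one pooled-SD off the
  Δ¹⁸O center (see above). Tissue-specific offsets before classification
  would fix this but would depart from the published rule.
- The quantile forest is exact Meinshausen weighting but O(cells × training)
  in memory; for very large grids predict in tiles.
- No errors-in-variables calibration; no spatial blocking in CV; no habitat
  priors. All three are natural extensions.
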