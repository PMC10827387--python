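# Methods

This note records the modelling assumptions, parameter choices, and
numerical conventions behind `marinesdm`, and what the synthetic-data
tests do and do not demonstrate about real data.

## Data model and grid conventions

All layers are single-band float32 GeoTIFFs on a geographic WGS84 grid
(0.05° cells by default, ~5.6 km at the equator), with an explicit nodata
value; binary range maps are 0/1 with nodata preserved. One convention is
fixed once and used everywhere: cells are half-open intervals whose west
and north edges are inclusive, coordinates refer to cell centers, and
point-to-cell assignment is nearest-cell with no interpolation — training
features and per-cell predictions therefore come from identical values,
which removes a common source of train/predict skew. Longitudes are not
wrapped across the antimeridian for grid indexing (study regions avoid
it); great-circle distances use the haversine formula on a 6371-km sphere
and handle the wrap correctly. Occurrence files are `Lon,Lat` CSVs in
decimal degrees; rows with unparsable or out-of-range coordinates are
dropped with a logged count, and exact duplicates are collapsed at load
time (near-duplicates are the thinning stage's job). Records falling on
nodata cells are dropped and logged.

## Spatial autocorrelation and thinning

The uncorrelated distance is estimated from a correlogram: random
unmasked cell pairs are binned by great-circle distance (50-km classes up
to 1,000 km by default), and within each class a single Pearson r is
computed from the standardized predictor values at the two pair ends,
pooled over predictors. Pooling (rather than per-predictor correlograms)
yields the one distance the rest of the workflow needs. A class counts as
correlated when r > 0 with two-sided p < 0.05 at its point count; the
uncorrelated distance is the lower edge of the first non-correlated
class, falling back to the maximum distance when all classes are
correlated. Zero-variance predictors are excluded from pooling and a
fully constant stack is treated as non-significant. Note that with many
pairs the significance rule is conservative: fields built with a Gaussian
kernel of standard deviation L decorrelate statistically only around
2–4 L, and the estimate rises further when large-scale gradients add
long-range correlation. Thinning then greedily visits records in seeded
random order, keeping a record iff no kept record lies within the
uncorrelated distance; this is idempotent and guarantees the minimum
spacing exactly.

## Pseudo-absences

Candidates are unmasked cells farther than an exclusion radius (default:
the uncorrelated distance, the same scale used for thinning) from every
occurrence. Desired counts: species with more than 1,000 occurrences get
one run balanced 1:1; rarer species get 10 runs of max(100, n)
pseudo-absences, which preserves balance in the 100 < n ≤ 1,000 regime.
Per run, K-means (seeded, standardized features, k = number of absences,
10 restarts) partitions the candidates and the member nearest each
centroid becomes one pseudo-absence — every absence is a distinct cell in
a distinct cluster, so the absences tile the available environment
without redundancy and class balance is built in (no class weighting is
applied anywhere). On small domains the exclusion buffer can swallow the
whole ocean; the pipeline then halves the radius (floor: one cell) until
the candidate pool suffices, logging each step. K-means runs on candidate
cells only, not the full raster.

## Cross-validation blocks

Folds are hexagons, not random records: points are projected onto a local
equirectangular plane centered on their median, tessellated into
flat-topped hexagons whose across-flats width equals the uncorrelated
distance (floored at one correlogram class so a white-noise world still
tessellates), and occupied hexagons are dealt round-robin to 10 folds
after a seeded shuffle. Two points in one hexagon can never cross folds.
Because every fold must contain presences to be scorable, the pipeline
deals presence-bearing hexagons first and reduces the fold count (never
below 2, with a logged warning) when fewer presence hexagons than folds
exist.

## Learners, grids, and monotonicity

Three boosting families are fitted per species, each with per-feature
monotone constraints so responses follow ecological expectation:
maximum temperature, sea ice cover, wave energy, and sea water speed act
negatively; minimum temperature, salinity, nutrients, pH, oxygen,
productivity, slope, and ruggedness act positively. Constrained partial
dependence is monotone exactly, not approximately — the tests assert it
without tolerance.

Backends: BRT is scikit-learn's `HistGradientBoostingClassifier`
(tree complexity = max depth, trees = boosting iterations); the
AdaBoost-style member is LightGBM (iterations = estimators, "degrees of
freedom" d = a leaf budget of d+1 leaves per tree, shrinkage = learning
rate); XGBoost is itself. All use logistic loss: no library combines
exponential loss with monotone constraints, and at these class-balanced
sample sizes the two losses fit nearly identical rankings, so enforceable
monotonicity was chosen over loss pedigree. All three are deterministic
given (data, hyperparameters, seed), single-threaded.

Hyperparameter search is an exhaustive grid under the spatial CV: BRT
learning rate {0.1, 0.01, 0.001} × depth {1..4} × trees {50..1000 step
50} (240 combinations); AdaBoost iterations {50..250 step 50} × degrees
of freedom {1..12} × shrinkage {0.25..1 step 0.25} (240); XGBoost gamma
{0..5} × depth {1..4} × shrinkage {0.1..0.5} × rounds {10..100 step 10}
(1,200). The selection metric is mean CV AUC, with ties broken by mean
Boyce and then by fewer boosting iterations (parsimony). A reduced
8-combination grid spanning the same axes is the default
(`grid_mode="reduced"`); the full lattices sit behind
`grid_mode="full"`. Within-CV sensitivity/specificity use the MTP
threshold fitted on the training folds' presences.

## Evaluation metrics

AUC is the rank statistic (ties count ½). TSS = sensitivity +
specificity − 1; the standard definition is kept, so TSS can be negative
even though well-performing models live in [0, 1]. The continuous Boyce
index slides 101 windows of width 0.1 × the background score range,
forms P/E ratios (windows with zero expected fraction skipped), collapses
consecutive duplicate P/E values (runs of empty windows would otherwise
drown the signal in ties), and reports the Spearman correlation of P/E
against window midpoint; a constant P/E returns 0 with a warning. Folds
too small for a stable Boyce (fewer than 5 presences or 20 background
points) report NaN and are skipped in means. The MTP threshold is the
exact optimum: the largest observed presence score keeping sensitivity
≥ 0.95, verified in tests against a brute-force scan. Collinearity is
reported (pairwise Pearson r and VIF = 1/(1−R²) on the training matrix)
but never used to auto-drop predictors — predictor sets are fixed per
group a priori.

## Ensemble, uncertainty, and clipping

Ensemble weights are max(metric − floor, 0) normalized to 1, with floor
0.5 for AUC (random ranking skill) and 0 for Boyce; all members at or
below the floor fall back to equal weights with a warning. For rare
species the 10 runs are averaged within each algorithm before
ensembling; uncertainty is the unweighted sample standard deviation
(n−1) across the three per-algorithm maps, so it reflects
between-algorithm disagreement, not between-run noise.

Range maps apply, in order: MTP reclassification (presence iff
suitability ≥ threshold), depth restriction (cells deeper than the
species' maximum reported depth become absence — applied first so deep
cells cannot act as dispersal stepping stones), and dispersal clipping.
Dispersal is chained reachability, not a one-shot buffer: occurrence
cells seed a reached set, any presence cell within one 200-km step of a
reached cell joins it, and the expansion runs to fixpoint — an
unsuitable gap wider than one step is impassable unless occurrence
records demonstrate the species is already beyond it. Internally,
8-connected presence patches are collapsed to components (valid whenever
the cell diagonal is below the step length) and reachability runs on the
component graph with exact haversine pair distances; tests verify
equivalence against a brute-force multi-source BFS over individual
cells. Future scenarios reuse the baseline threshold unchanged and seed
dispersal from the baseline clipped range, so projected colonization must
originate from currently occupied or reachable habitat. All clips are
monotone (never add presence) and idempotent.

## Interpretation

Contributions are permutation importances — the mean drop in training
AUC over shuffles of one predictor's column, floored at zero, normalized
to 100 % — computed identically for every algorithm and weight-averaged
for the ensemble, because a model-agnostic score is the only one
comparable across three different tree libraries. Partial dependence
uses a 100-point grid over the training range with rows subsampled
deterministically to ≤ 2,000.

A tolerance limit ("tipping point") is read off the ensemble
partial-dependence curve: for a negatively constrained predictor, the
largest grid value where the curve still clears a threshold (side
"max"); for a positive one, the smallest (side "min"). The threshold is
expressed on the curve's own scale — a fraction of its range above its
floor — because partial dependence averages predictions over training
rows and is compressed relative to full-model suitability, so an
absolute cutoff such as the species' MTP threshold is frequently never
reached. The fraction (default 0.2) was calibrated by simulation:
virtual species with known trapezoid limits were run through the full
pipeline on independent worlds and the fraction minimizing the recovery
error of the known limit (median ~0.8, worst ~1.4 partial-dependence
grid steps at 0.2; small fractions overshoot badly when pseudo-absences
are excluded near the niche margin) was frozen. It remains configurable
(`tipping_rel_threshold`), and `extract_tipping_point` itself takes any
absolute threshold. Curves that never reach the threshold report
"absent"; curves that never drop below it report the range edge with an
"unbounded_in_range" flag.

## Synthetic worlds and what the tests show

The generator emulates the structure of real predictor stacks — smoothed
Gaussian random fields with a controllable correlation length (kernel
standard deviation in cells = length / (111.32 × cell size)), an optional
latitudinal gradient, a contiguous land mask, positive-down bathymetry,
and future scenarios as additive shifts of dynamic predictors with
static terrain layers held fixed. Virtual species are products of
piecewise-trapezoidal responses, so their suitability, tolerance limits,
and depth limits are known exactly; occurrences are drawn with
probability ∝ suitability^bias from cell centers.

Default desk-scale conditions, chosen once: 200×200 cells at 0.05°
(a ~10°×10° window), correlation length 50 km, temperature gradient
0.1 °C per degree latitude, 10 % land. The ratios matter more than the
absolutes: a global analysis has domain extent far larger than the
uncorrelated distance, and reproducing that ratio in a 1,100-km window
requires mesoscale correlation and subordinate trend variance —
otherwise thinning at the estimated distance leaves too few independent
presences for any model to be informative. With these conditions a
500-record sample thins to ~20 independent presences, triggering the
rare-species path (10 runs × 100 pseudo-absences), which is also the
situation most of the real species catalogue is in.

What passing tests do show: every stage's contract (balancing rules,
spacing guarantees, fold integrity, monotonicity, threshold optimality,
clipping geometry) holds exactly; and the pipeline as a whole recovers a
known niche limit and direction of range change under warming. What they
do not show: performance on real occurrence data with detection bias,
taxonomic error, non-additive climate change signals, substrate and
light limitation, or coastline change — none of which the generator
emulates. Additive scenario shifts test projection plumbing and
range-shift direction, not climate realism.

## Reproducibility and numerics

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage sub-seeds from the one config seed via `SeedSequence`, so a
rerun is bit-identical (asserted in tests down to the written rasters).
Ties are broken by seeded order everywhere. Cell indexing applies a
1e-9-cell snap so points exactly on a cell edge resolve deterministically
despite floating-point rounding; rasters are written float32, and
consumers comparing float64 thresholds against re-read rasters should
allow a 1e-6 tolerance. Model persistence is a joblib bundle (algorithm,
hyperparameters, monotone map, seed, estimator).

The command-line surface is `simulate`, `run`, and `batch`; a single
`run` covers fit, projection, and reporting in one pass because a
per-species desk-scale run takes under a minute, making staged
re-execution from persisted models an optimization without a use case
here. The library API exposes the stages individually.

## Known limitations

Substrate, light, biotic interactions, and sea-level-driven coastline
change are not modelled; depth clipping is the only proxy. The
correlogram's significance rule makes the uncorrelated distance grow
with pair count and with large-scale gradients — on strongly trended
real data it can be very conservative. The AdaBoost member is a
leaf-budgeted logistic-loss booster, not a literal exponential-loss
AdaBoost. Hexagon geometry uses a local equirectangular projection and
is approximate at very high latitudes. Dispersal treats all suitable
cells as equally passable and ignores currents.
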