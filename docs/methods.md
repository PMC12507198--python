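# Methods

## Scope and model

`habshift` implements a presence/pseudo-absence species-distribution
workflow on a regular 1-km lattice in planar map units. The statistical
object is a binary classifier `P(presence | environment)` fitted to
occurrence records and a co-registered predictor stack, followed by
cartographic post-processing: four-level ordinal classification of the
probability surface, scenario projection, and land-cover overlay. The
package performs no geodesy or reprojection; co-registration is an input
contract. Distances default to Euclidean map units; a `haversine` option
covers inputs in WGS84 degrees.

## Synthetic study system

The generator produces the structure the analysis assumes, with known
ground truth:

- **Predictors.** 47 layers named after the standard bioclimatic
  (BIO1–BIO19), terrain (DEM, ASP, SLO, landform class DMTZ) and layered
  soil variables (thickness, N/pH/P/K/SOC at four depths, USDA texture at
  three). Continuous layers are Gaussian-smoothed white noise
  (correlation length 5 cells by default) rescaled to plausible per-family
  means and spreads (temperature-like ≈ 15 ± 6 °C, precipitation-like
  ≈ 1100 ± 400 mm, terrain ≈ 800 ± 500 m, soil ≈ 1 ± 0.4). Categorical
  layers are quantile bins (6 classes) of a smoothed field.
- **Engineered collinearity.** For each configured pair the derived layer
  is rebuilt as `r·ẑ_source + √(1−r²)·ê`, with the noise field
  residualized against the source and both parts standardized, so the
  *sample* Pearson correlation equals the target exactly. Defaults:
  (BIO1, BIO11, 0.92), (BIO12, BIO16, 0.90), (BIO4, BIO7, 0.85) — three
  pairs above the 0.8 screening threshold.
- **Truth.** Suitability is `logistic(β₀ + Σ βⱼ·zⱼ)` over five drivers
  spanning all three factor classes — BIO1 (+1.0), BIO12 (+1.2),
  BIO4 (−0.8), DEM (−0.7), ST (+0.6), intercept −0.5. The positive
  temperature coefficient gives warming scenarios a predictable sign.
- **Presences** are drawn at cell centers with probability proportional to
  suitability (with replacement; downstream thinning enforces one per
  cell, as it would for real records).
- **Forest mask** thresholds `ẑ(suitability) + 0.6·smoothed noise` at the
  quantile matching the target cover (0.55 by default), giving an exact
  cover fraction and a forest–suitability association, which the overlay
  stage needs to have signal.
- **Scenarios** are additive shifts on climate layers only, six
  combinations (3 SSPs × 2050s/2090s) with warming from +0.8 °C
  (SSP1–2.6, 2050s) to +4.0 °C (SSP5–8.5, 2090s) and small precipitation
  increases. Terrain and soil are bit-identical across scenarios.
- **Regions.** Four contiguous quadrants with seeded jitter of the two
  split lines (vertical strips for other k): disjoint, exhaustive,
  trivially auditable.

What the generator does *not* emulate: sampling bias in occurrence data,
nonstationary predictor–response relationships, categorical–continuous
interactions, realistic coastlines/projections, and land-use dynamics.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative model, not real-world
predictive skill.

## Sample construction

Thinning keeps the first record (stable input order) per thinning-grid
cell. Disk pseudo-absences are drawn uniformly *without replacement* over
cells whose centers are ≥ 10 km (default) from every presence — without
replacement to mirror the one-point-per-cell presence rule. The count is
`round(ratio × n_presences)`, ratio 1 by default. The train/test split is
stratified by label with `floor(0.7·n)` per stratum going to train and the
remainder to test, making 752 samples split 526/226. Points on nodata
cells are dropped and counted, never imputed.

On a bounded domain the 10-km disks can exhaust the eligible area; the
sampler raises with the eligible-cell count rather than degrading the
buffer. The default 200 × 200 km domain with ≈ 400 thinned presences
leaves several thousand eligible cells.

## Variable selection

Importance is computed once, on all candidates, from a 500-tree random
forest (impurity importances, normalized to sum 1). Columns are fitted in
canonical name order and mapped back so the score of a named variable is
independent of input column order. Greedy elimination then walks flagged
pairs (|r| > 0.8) in descending |r|, dropping the lower-importance member;
importance ties keep the alphabetically earlier name. The survivor set is
certified on every run to contain no pair above the threshold. Categorical
layers enter the correlation as integer codes — a logged caveat, accepted
so that all candidates appear in one screening. Elimination at a lower
threshold is a superset of elimination at a higher one (the extra pairs
sort strictly later), so retained sets grow monotonically with the
threshold; this is property-tested.

## Model suite

Default hyperparameters are fixed at the published settings listed in the
README. Two choices deserve emphasis:

- **"MaxEnt" as penalized logistic regression.** The configuration this
  pipeline targets (inverse regularization C = 0.1, quasi-Newton lbfgs
  solver) describes scikit-learn's `LogisticRegression`, and that is what
  is implemented — *not* the Phillips feature-class MaxEnt. Users wanting
  feature expansions should engineer them into the stack.
- **Probabilities from the linear SVM** come from Platt (sigmoid)
  calibration on 5 training folds, since the mapping stage needs
  calibrated probabilities rather than margins.

Continuous features are standardized with training-set statistics for the
logistic and SVM families (inside the estimator pipeline, so surfaces and
tables see one interface); tree families consume raw features. Grid search
is exhaustive over the user grid, scored by mean 5-fold stratified
cross-validated rank AUC, ties broken toward the first candidate in grid
order, winner refit on the full training set.

AUC is the Mann–Whitney rank statistic (ties counted ½), computed directly
rather than through a ROC sweep; threshold metrics use 0.5, the
conventional cut the published equations presuppose. The F1 identity
`F1 = 2PR/(P+R)` is enforced at construction of every report.

## Mapping and classification

Fisher–Jenks breaks are computed by the exact O(k·n²) dynamic program over
sorted values with prefix-sum SSD evaluation; cost ties resolve toward the
smaller lower class (first-argmin). Reported breaks are midpoints between
adjacent class boundary values. Above 10,000 values the DP runs on a
seeded uniform subsample — on smooth unimodal probability surfaces the
sampled and exact breaks agree on ≥ 99% of cell assignments (tested), and
the exact path remains available via `sample_cap=None`.

Class labels are `1 + #{breaks ≤ value}`: intervals are lower-inclusive,
a value equal to a break joins the class above, the top class is closed.
Areas are cell count × nominal cell area (1 km² default; latitude-
dependent cell areas are out of scope), shares rounded to 2 decimals half
away from zero.

## Scenarios and overlay

Default break policy is `fixed_current`: breaks learned under current
climate are reused for futures, so class-area changes reflect climate, not
reclassification; `refit` is one flag away. The forest mask is static
across scenarios. The primary habitability area is the union of classes 3
and 4; per-region overlap is an exact cell-level AND, so the class-3 and
class-4 overlaps partition the primary overlap. Percent change is taken
relative to the *current primary overlap* (not the forest area), the only
baseline reproducible from overlap tables alone.

## Orchestration and determinism

One global seed drives every stage through derived sub-seeds
(CRC32 of `"stage:seed"`, masked below 2³¹). All estimators run
single-threaded with fixed seeds; artifacts are plain text (ESRI ASCII
grids, CSV, JSON) with deterministic formatting, and the manifest records
SHA-256 checksums of every artifact. Re-running an identical config and
seed reproduces identical checksums, asserted in the test suite.

Default problem sizes — 200 × 200 cells, 400 presence draws, five model
families, six scenarios — keep a full run under ~15 s on one CPU while
leaving several thousand disk-eligible cells and ≈ 800 labelled samples,
comfortably inside the regime where the recovery properties (held-out
AUC ≥ 0.85, ≥ 4 of 5 true drivers in the top-8 importances) hold across
seeds.

## Known limitations

- Single climate realization per scenario; no multi-GCM ensembles.
- No spatial cross-validation; the random split shares spatial
  autocorrelation between train and test, which inflates AUC relative to
  block-held-out evaluation (the synthetic truth is known, so this is a
  documented property rather than a hidden bias).
- Pearson screening treats categorical codes as numeric.
- The Jenks subsampling bound is probabilistic, not worst-case; adversarial
  multimodal distributions near a break can shift assignments by more than
  1%.
- Planar geometry only; real-data studies must co-register and project
  inputs upstream.
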