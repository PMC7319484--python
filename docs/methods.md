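# Methods

`traitscape` predicts community mean plant traits from gridded
environmental predictors and quantifies how far those predictions can be
trusted. This note records the models, the defaults and why they are
set as they are, what the synthetic data generator does and does not
emulate, and the numerical choices made where the design was open.

## The modelling problem

The response variable is the community mean of a trait: the unweighted
average over the species of a local plant community, averaged again to
0.5° grid cells. Four traits are handled: specific leaf area (SLA,
mm²/mg), leaf nitrogen concentration (LNC, mg/g), plant height (m) and
wood density (mg/mm³). Six predictors describe climate and soil:
minimum temperature of the coldest month (Tmin, °C), a humidity index
(HumInd, precipitation over potential evapotranspiration,
dimensionless), precipitation of the driest quarter (PrecDryQ, mm),
precipitation seasonality (PrecSeas, CV of monthly precipitation, %),
soil cation exchange capacity (CEC, cmol+/kg) and soil pH, all consumed
as ready-made layers.

Trait–environment relationships at this scale arise through two
channels: species turnover (environmental filtering changes which
species are present) and intraspecific trait variation (ITV; individuals
of one species differ along environmental gradients). Both are
represented explicitly in the synthetic data (below), because the
pipeline's data-quality experiment is precisely about what happens when
the ITV channel is discarded.

## Observation selection and aggregation

Observations pass six criteria, applied in a fixed order so that every
removal is attributed to the first criterion it definitively fails:
georeferencing, direct measurement (no species-level averages), natural
vegetation, community-representative sampling ("all or dominant"
species), adult/all life stages, and measurement year ≥ 1980. Rows
whose metadata flag is missing or "unknown" — and which fail no definite
check — are removed as *uncheckable*. The accounting is conservative:
input = retained + per-criterion removals + uncheckable, always.

Cleaning drops exact duplicates, invalid coordinates, values outside
coarse physical plausibility bounds per trait (SLA 0.1–200 mm²/mg,
LNC 1–100 mg/g, height 0.01–150 m, wood density 0.05–1.5 mg/mm³), and,
within species × trait groups of at least 10 records, values farther
than 4 sample standard deviations from the species mean on the log
scale. Both the bounds and the k·SD rule are configurable; they are
this package's concretization of standard trait-database hygiene.

Community means are species-first: values are averaged within species,
then species means are averaged without abundance weighting. This makes
the community mean insensitive to how often one species was re-measured.
Abundances are carried through the tables but deliberately unused;
abundance weighting is left as an extension. Community means are then
averaged to half-degree cells on a global grid with origin (−180, −90)
and half-open cells `[edge, edge+0.5)`; a point on a shared edge belongs
to the cell whose lower edge it sits on, +180° wraps to −180°, +90°
clamps to the top row. Cells with a single community are retained.

Collinearity among predictors is pruned by iterated variance inflation
factors (VIF = 1/(1−R²) of regressing one predictor on the rest,
ordinary least squares): while the largest VIF is ≥ 4, the
highest-VIF predictor is dropped — except that the last member of a
protected group (climate: Tmin/HumInd/PrecDryQ/PrecSeas; soil: CEC/pH)
is never dropped, so both environmental factor families stay
represented. Perfect collinearity is capped at VIF 10¹²; if every
offending predictor is group-protected the situation is reported as
unresolvable rather than silently accepted.

## Learners and cross-validation

Four regression techniques sit behind one contract:

| learner | implementation | defaults |
|---|---|---|
| glm | per-predictor polynomial OLS on z-scored inputs | degree 2 |
| gam | statsmodels `GLMGam`, cubic B-spline per predictor | df 6, penalty α = 10 on z-scored inputs |
| rf  | scikit-learn `RandomForestRegressor` | 300 trees, mtry = p/3, leaf ≥ 5 |
| brt | scikit-learn `GradientBoostingRegressor` | lr 0.01, depth 3, ≤ 500 trees, early stopping (15% validation, patience 30) |

Degree-2 polynomials admit the unimodal responses the trait literature
expects. GAM inputs are z-scored before the spline basis is built so a
single curvature penalty is meaningful across predictors whose physical
scales differ by orders of magnitude; α = 10 was chosen as the weakest
penalty that stops the smooths from chasing noise along inert
predictors, and leaves skill on real signals unchanged. The RF leaf
size of 5 matches the long-standing regression default of the original
randomForest implementation and similarly suppresses noise-chasing; at
the problem sizes this pipeline targets (hundreds of cells, six
predictors), 300 trees and a 500-tree BRT cap give pseudo-R² values
indistinguishable from larger budgets. All hyperparameters are
serialized with every result.

Validation is a repeated split-sample procedure: 10 independent random
80/20 train/test splits (the split sequence depends only on the seed
and n, so every learner sees identical partitions), held-out
predictions pooled over repetitions, and skill summarized as the
cross-validated pseudo-R² — the squared Pearson correlation between
pooled held-out predictions and observations. The squared correlation
is symmetric in direction and lives in [0, 1]; it is defined as 0 when
either vector is constant. A learner whose fit breaks down is returned
flagged with pseudo-R² 0 rather than aborting the run; the ensemble
then ignores it. Splits are purely random; spatially blocked CV is a
known extension, not implemented.

The GAM cannot evaluate its spline basis outside the training range of
a predictor, so its predictions extend the fitted smooth as a constant
beyond that range (inputs are clipped). This is the conservative
standard treatment of spline extrapolation; extrapolated regions are
flagged separately through MESS and the partial-response flags.

## Ensemble

Weights are the four cross-validated pseudo-R² values normalized to sum
to one (flagged learners enter as 0; if all four are 0 the run stops
with a "no skilled learner" error). The ensemble prediction is the
weighted mean of the learner predictions, hence always bounded by the
member predictions.

*Ensemble accuracy* is itself cross-validated: for each repetition the
learners' held-out predictions are composed with weights estimated only
from that repetition's training side (an inner 80/20 split of the
training part), so no test information leaks into the weighting; the
pooled composed predictions are scored with the same pseudo-R². A
repetition whose inner scores are all zero falls back to equal weights
over unflagged learners.

*Model disagreement* at a point is the performance-weighted coefficient
of variation, CV = √(Σ w (ŷₘ−ŷ)²/Σ w)/|ŷ|, with ŷ the ensemble value:
zero exactly when all positively weighted models agree, undefined (and
reported missing) where |ŷ| falls below 10⁻⁹ trait units. The same
formula serves the prediction maps, the partial-response bands and the
importance error bars.

*Variable importance* follows the permute-and-correlate recipe: predict
on the table with one predictor column permuted, and report 1 − Spearman
ρ between permuted-input and original predictions, averaged over 10
seeded permutations. A model that provably ignores a predictor scores
exactly 0; a negative ρ (importance > 1) is kept and flagged rather
than clamped, since it signals a pathological fit worth seeing.

*Partial responses* use partial-dependence averaging (the focal column
is replaced by each grid value in turn and predictions averaged over
all training rows) rather than fixing covariates at medians — the
former is well-defined for tree ensembles and smooths alike. Grid
points outside the focal predictor's training range are flagged
extrapolated.

## Reliability

**MESS.** The multivariate environmental similarity surface scores each
cell against the training cells per predictor: with f the percentage of
reference values strictly below the target value, similarity is
2f (f ≤ 50) or 2(100−f) (f > 50) inside the reference range, and the
signed fractional distance beyond the minimum or maximum outside it.
The cell's score is the minimum over predictors; ties in the minimizing
predictor break by column order. Negative values mark environmental
extrapolation. A reference predictor with no spread is skipped with a
warning by default (configurable to a hard error).

**Trait-combination realism.** A one-class support-vector boundary
(RBF kernel, ν = 0.05, kernel width by the median heuristic over
pairwise distances) is fitted to observation-level 4-trait vectors
after log₁₀ transform and z-scoring, and each cell's predicted 4-trait
vector is tested against it. ν = 0.05 lets about 5% of training points
fall outside, so even perfect predictions score ≈ 95% "realistic" — the
fraction is meaningful relative to that ceiling, and both ν and γ are
reported with every realism fraction. The boundary is deliberately
fitted at the observation level while predictions are community means:
a flagged cell means the predicted combination was never observed in
individuals, not that it cannot exist.

**Correlation preservation.** The six upper-triangle entries of the
observed cell-level trait correlation matrix are correlated (Pearson)
with the corresponding entries of the predicted matrix; 1 means the
among-trait correlation structure survived the modelling untouched.

## Synthetic worlds

The generator produces the study conditions every test runs under.

*Environment.* Each predictor layer is Gaussian-smoothed white noise
(kernel σ = the stated correlation length) rescaled to its physical
range (Tmin −35–25 °C, HumInd 0.05–3, PrecDryQ 0–800 mm, PrecSeas
5–120%, CEC 2–60 cmol+/kg, pH 3.5–9). The six fields are
orthogonalized before rescaling, so inter-layer correlations start near
zero and collinearity exists only when explicitly induced — VIF pruning
is exercised only when a test asks for it.

*Species.* Base traits are lognormal (log-SD 0.3 per trait) around
geometric means SLA 15, LNC 20, height 2, wood density 0.6, with a
configurable among-species log-trait correlation target. Each species
has a niche optimum (uniform over each predictor's range), a niche
breadth (0.25–0.5 of the range) and idiosyncratic plasticity slopes
(SD 0.05 log-units per unit scaled predictor, scaled by
`plasticity_scale`; 0 disables every intraspecific channel).

*Communities.* Sites occupy distinct random cells; membership is
sampled ∝ a Gaussian niche weight around each species' optima
(species_per_site = 15 by default). A trait value is built on the log
scale: base value + injected signal + idiosyncratic plasticity +
lognormal measurement noise (log-SD 0.1). The injected signal per
predictor has amplitude √(effect) × 0.5 log-units and a shape (linear
increase/decrease, Gaussian bump for unimodal, zero for flat), split
between a turnover component (a function of the species' optimum, so it
survives species-mean substitution) and a plastic component (a function
of the site environment, so it does not), with `itv_fraction` = 0.5 by
default. Neither the ITV share nor the variance magnitudes are
calibrated to any real dataset — real-world analogues are unknown at
this resolution — so they are configurable, chosen once to be
ecologically plausible, and stated here. The default response
configuration gives each trait 0.6–0.75 of its signal variance from two
or three predictors with the qualitative shapes the community-trait
literature expects (e.g. unimodal SLA–Tmin, increasing height–PrecDryQ,
decreasing wood density–HumInd).

*Degraded variants.* `no_itv` replaces every value by the species ×
trait mean over the full pre-degradation dataset (the "global species
average" surrogate); `random_species` keeps one uniformly chosen
species per community (an unrepresentative sample); the combined
variant applies both, with species means still computed on the full
input. Variants are evaluated against the *default* data's community
means with identical split and learner seeds, so score differences are
attributable to the data treatment alone.

What the generator does **not** emulate: real spatial sampling bias,
taxonomic error, unit heterogeneity, dispersal limitation, biotic
interactions, phylogenetic structure, or the empirical magnitudes of
ITV. Passing tests therefore demonstrate that the machinery recovers
known structure under controlled conditions — not that any particular
real-world accuracy will be achieved.

## Problem sizes and determinism

The test suite and the acceptance script run worlds of 80–600 sites on
12×12 to 30×30 grids with 150–400 species; these sizes keep every
statistical check well-posed (cross-validation needs ≥ 25 cells; the
hypervolume ≥ 50 records) while completing on a single CPU in minutes.
Flat-response recovery uses the largest world because flatness of a
partial response is an asymptotic property.

Every operation is a pure function of its inputs and a seed; one master
seed deterministically derives all stage seeds (numpy `SeedSequence`,
all below 2³¹). A run directory always contains a manifest with the
config, the derived seeds and a SHA-256 hash of every output file;
re-running the same config reproduces every hash, and manifests exclude
the output path so runs of one seed are byte-identical wherever they
are written.

## Known limitations

- pseudo-R² as squared correlation ignores calibration: a biased but
  correlated prediction scores well. The realism and
  correlation-preservation checks partly compensate.
- Random (not spatially blocked) CV splits can flatter models when
  spatial autocorrelation is strong.
- The OneClassSVM boundary is not star-shaped in general; the
  "shrinking toward the centroid stays inside" behaviour is verified on
  seeded fixtures, not guaranteed mathematically.
- Raster I/O is plain CSV + JSON sidecar (one row per valid cell);
  there is no GeoTIFF writer.
- The quality experiment recomputes ensemble weights per variant;
  per-variant and across-variant summaries are both reported.
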