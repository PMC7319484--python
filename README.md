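# traitscape

Global prediction of **community mean plant traits** from environmental
layers, with a systematic assessment of how far the predictions can be
trusted.

Plant ecologists increasingly map community-level traits — specific
leaf area (SLA), leaf nitrogen concentration (LNC), plant height, wood
density — across the globe by regressing locally measured community
means on climate and soil predictors. Published maps disagree, partly
because of data quality (species-level averages vs. local measurements,
unrepresentative species samples) and partly because of model choice.
`traitscape` implements the full workflow this problem calls for, as a
tested, reusable library:

- **observation selection** by six criteria (georeferencing, direct
  measurement, natural vegetation, community-representative sampling,
  adult/all life stages, year ≥ 1980), with a per-criterion removal
  report;
- **unweighted, species-first community means**, aggregated to 0.5°
  grid cells and linked to six predictors (Tmin, HumInd, PrecDryQ,
  PrecSeas, CEC, pH), pruned for collinearity by iterated VIF < 4;
- **four learners** (polynomial GLM, spline GAM, random forest, boosted
  regression trees) validated by 10 repeated 80/20 splits, scored by
  the cross-validated pseudo-R²
  `R² = corr(ŷ_heldout, y)²`;
- an **ensemble** that averages the four predictions weighted by their
  cross-validated pseudo-R², with ensemble variable importance
  (1 − Spearman ρ under predictor permutation), ensemble partial
  responses, and model-disagreement maps — the performance-weighted
  coefficient of variation
  `CV = sqrt(Σ w (ŷ_m − ŷ_ens)² / Σ w) / |ŷ_ens|`;
- **reliability assessment**: the multivariate environmental similarity
  surface (MESS) applicability domain, a one-class-SVM trait
  hypervolume testing whether predicted trait combinations occur in the
  observed data, and preservation of among-trait correlations;
- a **data-quality experiment** comparing the default data against
  variants without intraspecific trait variation (`no_itv`), with one
  random species per community (`random_species`), and both;
- a **synthetic world generator** (autocorrelated environments, species
  pools with correlated traits and environmental niches, community
  assembly by niche filtering, known injected trait–environment
  response shapes) so that every stage is testable end to end without
  restricted-access trait databases.

## Worked example

```python
from traitscape import pipeline as pl

config = pl.RunConfig(
    out_dir="demo_run", seed=11,
    world=pl.WorldConfig(n_cols=12, n_rows=12, n_species=150,
                         n_sites=80, species_per_site=10),
    n_permutations=3, partial_grid_size=20,
)
result = pl.run_full_pipeline(config)
for trait, acc in result.ensemble_accuracy.items():
    scores = {k: round(f.pseudo_r2, 2) for k, f in result.ensembles[trait].fits.items()}
    print(f"{trait:14s} learners={scores} ensemble={acc:.2f}")
print("correlation preservation r =", round(result.correlation_preservation, 2))
print("realistic trait combinations:",
      f"{100 * result.realism.fraction_inside:.1f}%")
```

prints (seed 11):

```
sla            learners={'glm': 0.76, 'gam': 0.74, 'rf': 0.72, 'brt': 0.77} ensemble=0.78
lnc            learners={'glm': 0.79, 'gam': 0.82, 'rf': 0.78, 'brt': 0.71} ensemble=0.80
height         learners={'glm': 0.83, 'gam': 0.85, 'rf': 0.74, 'brt': 0.72} ensemble=0.82
wood_density   learners={'glm': 0.83, 'gam': 0.84, 'rf': 0.74, 'brt': 0.75} ensemble=0.82
correlation preservation r = 0.98
realistic trait combinations: 100.0%
```

Each learner's number is its cross-validated pseudo-R² on pooled
held-out cells; the ensemble accuracy composes the learners' held-out
predictions with leakage-free per-repetition weights and is at least as
good as the best single model here. The correlation-preservation score
says the among-trait correlation structure of the observed cells
survived into the predictions; the realism percentage counts predicted
4-trait combinations inside the observed trait hypervolume (the
boundary deliberately excludes ~5% of the raw training observations, so
smoothed community-mean predictions near the centre of trait space can
legitimately score close to 100%). The run directory `demo_run/` contains all tables
(community means, features, importance, partial responses, prediction
and CV maps as cell CSVs, MESS), the reliability report, and a manifest
with hashes of every output.

The same flow is scriptable from a shell:

```bash
traitscape all --seed 11 --out demo_run
traitscape quality --seed 11 --out demo_quality   # data-quality experiment
```

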