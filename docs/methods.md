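# Methods

This note documents the models and procedures `eodiet` implements, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not establish about real EMA data.

## Outcomes and transforms

Per-EO servings of six food groups (five core groups + discretionary) are
semicontinuous: a point mass at zero plus a right-skewed positive part,
bounded in practice at about six servings per occasion.  Models are fit on
`y = ln(servings + 1)`; predictions return to the serving scale via
`exp(ŷ) − 1`, clipped below at zero.  The `ln(x+1)` form keeps zero intake at
exactly zero on both scales and makes a log-normal positive part linear in
its parameters.  Daily diet quality (DGI, 0–120) is continuous with no zero
inflation and is modelled on its original scale; hurdle families are
rejected for it by validation.

## Eating-occasion construction

Items consumed "simultaneously" merge into one EO; occasions under 210 kJ
are discarded.  Simultaneity defaults to an identical reported start time
(EMA apps record one start time per occasion); a merge window in minutes is
configurable, in which case grouping is single-linkage in time — verified in
tests against an independent pairwise union-find clustering.  The energy
threshold is applied after merging, so a sub-threshold beverage adjacent to
a meal still counts within the merged occasion.

## DGI scoring

Each of the 12 components maps a daily quantity to a 0–10 score, by default
proportionally between a zero-score cut-off and a full-score target
(direction `healthy_max` or `limit_max`); step scoring is available per
component.  The shipped component set is a **reconstruction** in the spirit
of the DGI-2013 adaptation for 24-hour-recall data — the authoritative
cut-offs were not available — and every constant is configuration-editable.
The engine's guarantees (bounds, monotonicity, total = sum of components,
fully adherent day = 120) are independent of the particular cut-offs.

## Hurdle models

The occurrence part is a classifier on `1{servings > 0}`; the amount part a
regressor trained on exactly the positive rows (the standard hurdle
definition).  Families: gradient-boosted trees (subsample 0.8 by default,
hence *stochastic* GBDT) and random forests, via scikit-learn.

Two combination rules are provided, and the choice matters:

- **expected_value** (default): `p̂ · (e^ŷ − 1)`, the model's conditional
  mean on the serving scale.  This is the right predictor under squared
  error and the natural quantity for intervention reasoning.
- **thresholded**: `e^ŷ − 1` where `p̂ ≥ τ` (default τ = 0.5), else 0.  This
  is a median-type predictor: with zero inflation the conditional median is
  0 wherever `p̂ < 0.5`.  Because model selection here uses MAE — which is
  minimised by the conditional median, not the mean — MAE-based comparisons
  of hurdle against single models use the thresholded rule.  Empirically
  (and reproducibly in the acceptance suite) the expected-value rule loses
  MAE to a single log-scale forest at high zero inflation, while the
  thresholded rule wins consistently: a property of the error metric, not of
  the implementations.

The amount part is back-transformed before combination, so the combined
prediction lives on the serving scale throughout.

## Cross-validation, imputation, grid search

Folds partition *participants* (balanced within one), independently per
repeat; every record of a participant is on one side of every split.
Defaults: k = 10, 3 repeats.  Median/mode imputation is fitted inside each
training fold by default (no leakage); a `pre_cv` mode imputes once before
CV for pipelines that prepare data up front.  Grid search trains every
combination on every split — with the default 216-point boosted grid and
3×10-fold CV that is 6480 training runs per outcome, and 300 for the
10-point forest grid (`count_training_runs` exposes the accounting).
Selection minimises mean CV MAE on the original scale; ties break by fewer
trees, then lower depth, then declaration order, for full determinism.  A
fold whose training data lacks an outcome class flags the combination
rather than silently dropping it; flagged combinations lose selection
priority to fully completed ones but remain in the report.

Categoricals are encoded as one indicator column per declared level, with
ordered factors (income band, education, SEIFA) as integer codes; level
orders are frozen so design matrices are stable across folds and runs.

## Attribution

Feature attributions are exact path-dependent tree-Shapley values computed
in-package (`_treeshap.py`): the value function is the conditional
expectation encoded by each tree's training covers, evaluated for all
coalitions simultaneously in O(leaves × depth²) per tree and instance.  The
kernel is numba-compiled (pure-Python fallback, identical results).
Correctness is established two ways in the tests: local accuracy
(`base + Σφ` equals the raw model output — response for regressors, class-1
probability for forest classifiers, log-odds margin for boosted classifiers
— to ~1e-15) and exact agreement with an exhaustive 2^p Shapley enumeration
oracle on single trees.  No background sample is needed; results are fully
deterministic, which is why rank-recovery tests carry no Monte-Carlo
attribution noise.  Hurdle parts are attributed separately; indicator
columns are pooled back to their source factor by summing attributions, so
rankings speak in terms of contextual factors.  Importance is the mean
absolute attribution over a scope: one EO, one day (a participant's EOs that
day), one participant, or global; the global ranking equals the
instance-weighted pooling of participant-level rankings by construction.
Attributions describe model behaviour and carry no causal interpretation.

## Synthetic cohort generator

The generator is the package's test bed and emulates the study conditions:

- **Cohort**: 675 participants by default, age truncated-normal(24.24, 3.3)
  on [18, 30]; categorical marginals (73.3% female, 75.1% Australian-born,
  income/education/smoking/living/SEIFA distributions) and score means/sds
  follow the published cohort summary, renormalised over non-missing counts
  where the published percentages do not sum to 100.  Two published
  instrument summaries (food shopping 31.32 on a 0–21 scale; food
  availability 12.60 on a 0–12 scale) fall outside their stated instrument
  ranges; the generator honours the declared ranges and uses in-range
  defaults (15.0 ± 4.0 and 9.5 ± 2.2) instead.
- **EO counts**: zero-truncated Poisson per recording day, day rate
  calibrated so the 4-day mean is 17.03 EOs per participant.
- **Servings**: per group, occurrence ~ Bernoulli(logistic(β₀ + Σβx)) and
  positive amount `exp(z) − 1` with `z` ~ Normal(μ₀ + Σγx, σ) truncated to
  z > 0, capped at 6 servings — so `ln(servings+1)` is exactly the normal
  linear predictor the models target.  Numeric covariates enter rescaled to
  [−1, 1] over their instrument range; categoricals as named indicators.
- **Missingness**: completely at random per column, outcomes protected.
  Context factors are drawn independently (only marginals are published).

What passing tests show: the pipeline recovers known structure — occurrence
probabilities, strong effects in SHAP rankings, the hurdle advantage — under
the generative assumptions above.  What they do not show: performance on
real intake data, whose context factors are correlated, whose missingness is
not MCAR, and whose serving distributions are only approximately
log-normal.  Real-data error magnitudes cannot be reproduced without the
original dataset.

## Study-condition sizes used in the verification suite

The statistical acceptance checks use scaled, fixed conditions chosen once:
the hurdle-vs-single comparison uses 175 participants (~3000 EOs), zero
fraction calibrated to 0.8, strong occurrence effects (log-odds
coefficients 2–3 on the [−1,1] covariate scale — the regime where an
explicit occurrence part is informative), 60-tree forests under grouped
5-fold CV, 20 seeds; the SHAP recovery check uses 80 participants
(~1350 EOs), three amount effects of 0.7–0.8 against ~25 candidate factors,
20 seeds.  Deterministic structural checks (DGI bounds, 6480/300
accounting, the 210 kJ boundary, 675-participant fold disjointness) run at
full published scale.

## Known limitations

- DGI cut-offs are reconstructions; absolute DGI totals are not comparable
  to published cohort values, though the engine's behaviour is.
- The hurdle grid applies one hyperparameter combination to both parts;
  per-part grids would square the search space.
- `ImportanceRanking` ties are resolved by declaration order and flagged;
  with heavily discretised predictors exact ties do occur.
- Execution is sequential; determinism is prioritised over parallel speed.
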