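# eodiet

Modelling what young adults eat at individual eating occasions — and how good
their daily diet is — from the context in which eating happens.

Ecological momentary assessment (EMA) food diaries yield item-level intake
records plus two layers of context: stable person-level factors (demographics,
cooking confidence, food environment scores) and momentary EO-level factors
(who was present, where, what activity, where the food came from).  `eodiet`
implements the full analysis pipeline for such data:

- **Eating-occasion coding** — items consumed simultaneously contributing
  ≥ 210 kJ form one eating occasion (EO); servings are quantified for the five
  core food groups (vegetables, fruits, grains, meats and alternatives, dairy
  and alternatives) plus discretionary foods at 600 kJ per serving; modelled
  outcomes are `ln(servings + 1)`.
- **Diet quality** — daily Dietary Guideline Index (DGI): 12 components,
  0–10 points each, 0–120 total, configuration-driven cut-offs.
- **Hurdle tree ensembles** — per-EO servings are zero-inflated and
  right-skewed, so alongside stochastic gradient-boosted trees (SGBDT) and
  random forests (RF), their hurdle extensions model occurrence
  (`P(servings > 0 | x)`, a classifier) and conditional amount
  (`E[ln(servings+1) | servings > 0, x]`, a regressor on the positive rows)
  separately, combined as `p̂ · (e^ŷ − 1)` (expected value) or gated at a
  probability threshold (median-type).
- **Participant-grouped repeated k-fold CV with grid search** — all EOs of a
  participant stay on one side of every split (no identity leakage); every
  hyperparameter combination is trained on every split (216-point SGBDT grid
  × 30 splits = 6480 training runs; 10-point RF grid = 300), imputation fitted
  inside training folds; selection by lowest mean CV MAE on the serving scale.
- **Exact SHAP interpretation** — deterministic path-dependent tree-Shapley
  attributions (implemented in-package, numba-accelerated) with local
  accuracy `base + Σφ = prediction`; mean-|SHAP| importance aggregated per
  EO, day, participant, and globally, with top-k rankings and bump charts.
- **Synthetic cohort generator** — the study's data are not public, so a
  generator emulates the cohort (675 young adults aged 18–30, ~73% female,
  3–4 recording days, ~17 EOs per person) with known logistic-occurrence /
  log-normal-amount ground truth, enabling recovery tests of everything above.

## Worked example

`examples/04_fit_hurdle_cv.py` simulates 60 participants (~1000 EOs), injects
5% missingness, and compares a random forest with its hurdle extension for
per-EO vegetable servings under grouped 3-fold CV:

```
1006 EOs, 1 grid point(s), 3 training runs per family

         random_forest: RMSE 1.046  MAE 0.713  R² -0.023 (servings, out-of-fold)
  hurdle_random_forest: RMSE 1.030  MAE 0.730  R² 0.009 (servings, out-of-fold)

best model by lowest MAE: random_forest (mean absolute error of 0.71 servings per EO)
```

MAE/RMSE are in servings on the original scale (back-transformed out-of-fold
predictions); the best model per outcome is the lowest-MAE one.
`examples/05_shap_importance.py` then explains a fitted model:

```
local accuracy: max |base + sum(phi) - prediction| = 5.55e-16

top-5 mean |SHAP| at          eo level: cooking_confidence (0.0563), start_time (0.0535), ...
top-5 mean |SHAP| at      global level: eo_type (0.0699), cooking_confidence (0.0403), ...
```

Each remaining example covers one capability: cohort generation (`01`),
intake coding (`02`), DGI scoring (`03`).  A thin CLI wraps the pipeline:
`eodiet simulate`, `eodiet score-dgi`, `eodiet run-all --config cfg.yaml`.

## Layout

```
src/eodiet/
  synthetic_cohort.py    cohort + EO generator with known ground truth
  intake_coding.py       EO construction, serving vectors, ln(x+1) transform
  diet_quality.py        12-component DGI scoring engine
  hurdle_models.py       grouped CV, imputation, model families, grid search
  evaluation.py          original-scale RMSE/MAE/R², lowest-MAE selection
  shap_interpretation.py exact tree-Shapley attribution + aggregation
  _treeshap.py           path-dependent Shapley kernel (numba)
  pipeline.py, cli.py    configured end-to-end runs
docs/methods.md          model, assumptions, parameter choices, limitations
examples/                one narrative script per capability
```

SHAP rankings describe model behaviour, not causal effects of context on
intake; see `docs/methods.md` for assumptions and limitations.
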