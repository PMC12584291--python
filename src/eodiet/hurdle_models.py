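"""Hurdle tree-ensemble models under participant-grouped repeated k-fold CV.

Four model families predict per-EO food-group servings (and daily diet
quality): stochastic gradient-boosted decision trees (SGBDT), random forests
(RF), and their hurdle extensions.  A hurdle model is a two-part model for
zero-inflated semicontinuous outcomes: a binary classifier for whether any
intake occurred, and a regressor for the (log) amount fitted on the non-zero
rows only.  The default prediction-combination rule is the expected value
``p_hat * back_transform(amount_hat)`` on the original serving scale.

Cross-validation is grouped by participant: all EOs of a participant stay on
the same side of every split, so no identity leakage occurs between training
and testing.  Grid search trains every hyperparameter combination on every
split of a repeated k-fold plan and selects the combination with the lowest
mean cross-validated MAE on the original outcome scale.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)

from .intake_coding import back_transform
from .synthetic_cohort import CATEGORY_LEVELS, EO_CATEGORY_LEVELS, SCORE_RANGES

__all__ = [
    "FeatureTable",
    "CVPlan",
    "HyperGrid",
    "HurdleModel",
    "HurdleError",
    "GridSearchResult",
    "build_feature_table",
    "encode_features",
    "build_cv_plan",
    "ColumnImputer",
    "impute_fit",
    "impute_apply",
    "fit_single",
    "fit_hurdle",
    "predict_hurdle",
    "predict_single_original",
    "grid_search",
    "count_training_runs",
    "default_boosted_grid",
    "default_forest_grid",
    "MODEL_FAMILIES",
]

MODEL_FAMILIES = ("boosted_trees", "random_forest",
                  "hurdle_boosted_trees", "hurdle_random_forest")

KEY_COLUMNS = ("participant_id", "day_index", "eo_id")

#: ordered categoricals encoded as integer codes rather than indicators
ORDERED_FACTORS = ("income_band", "education", "seifa")

_PERSON_NUMERIC = tuple(SCORE_RANGES) + ("pa_guideline_met",)
_PERSON_CATEGORICAL = tuple(CATEGORY_LEVELS)
_EO_NUMERIC = ("homemade", "start_time")
_EO_CATEGORICAL = tuple(EO_CATEGORY_LEVELS)


@dataclass
class FeatureTable:
    """Modelling table: raw predictors + keys + one outcome column.

    ``meta`` maps each predictor column to its level ('person' | 'eo') and
    kind ('numeric' | 'categorical'); categorical columns carry a frozen level
    order so encoding is stable across folds and runs.
    """

    data: pd.DataFrame
    outcome: str
    meta: Mapping[str, dict]
    outcome_scale: str = "log"  # 'log' (servings) | 'identity' (e.g. daily DGI)

    def __post_init__(self) -> None:
        if self.outcome in self.meta:
            raise ValueError("outcome column must not appear among predictors")
        missing = [c for c in self.meta if c not in self.data.columns]
        if missing:
            raise ValueError(f"meta names absent columns: {missing}")
        if self.outcome not in self.data.columns:
            raise ValueError(f"outcome column {self.outcome!r} missing")
        if self.outcome_scale not in ("log", "identity"):
            raise ValueError("outcome_scale must be 'log' or 'identity'")

    @property
    def feature_columns(self) -> list[str]:
        return list(self.meta)

    def predictors(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    def outcome_values(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=float)

    def participant_ids(self) -> np.ndarray:
        return self.data["participant_id"].to_numpy()


def _default_meta() -> dict[str, dict]:
    meta: dict[str, dict] = {}
    for c in _PERSON_NUMERIC:
        meta[c] = {"level": "person", "kind": "numeric"}
    for c in _PERSON_CATEGORICAL:
        meta[c] = {"level": "person", "kind": "categorical",
                   "levels": CATEGORY_LEVELS[c]}
    for c in _EO_CATEGORICAL:
        meta[c] = {"level": "eo", "kind": "categorical",
                   "levels": EO_CATEGORY_LEVELS[c]}
    for c in _EO_NUMERIC:
        meta[c] = {"level": "eo", "kind": "numeric"}
    return meta


def build_feature_table(
    eo_frame: pd.DataFrame,
    outcome: str,
    outcome_scale: str = "log",
    extra_meta: Mapping[str, dict] | None = None,
) -> FeatureTable:
    """Assemble a FeatureTable from a merged EO + person-factor frame.

    When ``outcome_scale == 'log'`` and the named outcome is a raw
    ``servings_*`` column, a ``log_<outcome>`` column is derived and used.
    """
    meta = {c: m for c, m in _default_meta().items() if c in eo_frame.columns}
    if extra_meta:
        meta.update(extra_meta)
    data = eo_frame.copy()
    out_col = outcome
    if outcome_scale == "log" and outcome.startswith("servings_"):
        out_col = "log_" + outcome
        if out_col not in data.columns:
            data[out_col] = np.log1p(data[outcome].to_numpy(dtype=float))
    keep = [c for c in KEY_COLUMNS if c in data.columns] + list(meta) + [out_col]
    extra_keep = [c for c in data.columns if c.startswith("servings_") and c not in keep]
    return FeatureTable(data=data[keep + extra_keep], outcome=out_col, meta=meta,
                        outcome_scale=outcome_scale)


def encode_features(
    raw: pd.DataFrame, meta: Mapping[str, dict]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Encode raw predictors to a numeric design matrix with stable columns.

    Unordered categoricals become one indicator column per declared level
    (``"col=level"``); ordered factors (income, education, SEIFA) become
    integer codes; numerics pass through.  Returns the matrix and a mapping
    from encoded column to its source factor (for attribution grouping).
    """
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for c, m in meta.items():
        if m["kind"] == "numeric":
            cols[c] = raw[c].to_numpy(dtype=float)
            groups[c] = c
        else:
            levels = list(m["levels"])
            vals = raw[c].astype(object).to_numpy()
            if c in ORDERED_FACTORS:
                code = np.full(len(raw), np.nan)
                for i, lv in enumerate(levels):
                    code[vals == lv] = float(i)
                cols[c] = code
                groups[c] = c
            else:
                for lv in levels:
                    name = f"{c}={lv}"
                    cols[name] = (vals == lv).astype(float)
                    groups[name] = c
    return pd.DataFrame(cols, index=raw.index), groups


# ----------------------------------------------------------------- CV plans

@dataclass(frozen=True)
class CVPlan:
    """Repeated grouped k-fold assignment of participants to folds."""

    k: int
    repeats: int
    assignment: Mapping[tuple[int, int], frozenset]

    def __post_init__(self) -> None:
        for r in range(self.repeats):
            folds = [self.assignment[(r, f)] for f in range(self.k)]
            seen: set = set()
            for fs in folds:
                if seen & fs:
                    raise ValueError("folds within a repeat must be disjoint")
                seen |= fs

    def splits(self) -> Iterator[tuple[int, int, frozenset, frozenset]]:
        """Yield (repeat, fold, train_participants, test_participants)."""
        for r in range(self.repeats):
            all_pids = frozenset().union(*(self.assignment[(r, f)] for f in range(self.k)))
            for f in range(self.k):
                test = self.assignment[(r, f)]
                yield r, f, all_pids - test, test

    @property
    def n_splits(self) -> int:
        return self.k * self.repeats


def build_cv_plan(participant_ids: Sequence, k: int = 10, repeats: int = 3,
                  seed: int = 0) -> CVPlan:
    """Randomly partition participants into k folds, independently per repeat.

    Fold sizes are balanced to within one participant; deterministic given
    ``seed``.
    """
    pids = np.asarray(sorted(set(participant_ids)))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(pids):
        raise ValueError(f"k={k} exceeds the number of participants ({len(pids)})")
    rng = np.random.default_rng(seed)
    assignment = {}
    for r in range(repeats):
        perm = rng.permutation(pids)
        for f, chunk in enumerate(np.array_split(perm, k)):
            assignment[(r, f)] = frozenset(chunk.tolist())
    return CVPlan(k=k, repeats=repeats, assignment=assignment)


# --------------------------------------------------------------- imputation

class ColumnImputer:
    """Median / mode imputer fitted on training rows only.

    Numeric predictor columns are filled with the training median, categorical
    columns with the training mode (ties broken by declared level order).
    """

    def __init__(self, meta: Mapping[str, dict]):
        self.meta = meta
        self.fill_: dict[str, object] | None = None

    def fit(self, raw: pd.DataFrame) -> "ColumnImputer":
        fill: dict[str, object] = {}
        for c, m in self.meta.items():
            col = raw[c]
            if col.notna().sum() == 0:
                raise ValueError(f"column {c!r} has no observed values in the training split")
            if m["kind"] == "numeric":
                fill[c] = float(col.median())
            else:
                counts = col.value_counts()
                top = counts.max()
                modes = set(counts[counts == top].index)
                fill[c] = next(lv for lv in m["levels"] if lv in modes)
        self.fill_ = fill
        return self

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        if self.fill_ is None:
            raise ValueError("imputer is not fitted")
        out = raw.copy()
        for c, v in self.fill_.items():
            if out[c].isna().any():
                out[c] = out[c].fillna(v)
        return out


def impute_fit(raw: pd.DataFrame, meta: Mapping[str, dict]) -> ColumnImputer:
    return ColumnImputer(meta).fit(raw)


def impute_apply(imputer: ColumnImputer, raw: pd.DataFrame) -> pd.DataFrame:
    return imputer.transform(raw)


# ------------------------------------------------------------------- models

_BOOSTED_DEFAULTS = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1,
                     "min_samples_leaf": 10, "subsample": 0.8}
_FOREST_DEFAULTS = {"n_estimators": 300, "max_features": 0.5,
                    "min_samples_leaf": 5, "max_depth": None}


def _make_estimator(family: str, task: str, hyperparams: Mapping, seed: int):
    hp = dict(hyperparams)
    if family == "boosted_trees":
        params = {**_BOOSTED_DEFAULTS, **hp, "random_state": seed}
        cls = GradientBoostingRegressor if task == "regression" else GradientBoostingClassifier
        return cls(**params)
    if family == "random_forest":
        params = {**_FOREST_DEFAULTS, **hp, "random_state": seed}
        cls = RandomForestRegressor if task == "regression" else RandomForestClassifier
        return cls(**params)
    raise ValueError(f"unknown family {family!r}; expected 'boosted_trees' or 'random_forest'")


def fit_single(family: str, features: pd.DataFrame, outcome: np.ndarray,
               hyperparams: Mapping | None = None, seed: int = 0):
    """Fit one tree-ensemble regressor on a numeric outcome."""
    y = np.asarray(outcome, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    est = _make_estimator(family, "regression", hyperparams or {}, seed)
    est.fit(features, y)
    return est


class HurdleError(ValueError):
    """Raised when a hurdle model cannot be fitted (degenerate outcome)."""


@dataclass
class HurdleModel:
    """Occurrence classifier + positive-amount regressor with a combination rule."""

    family: str
    occurrence_part: object
    amount_part: object
    combination_rule: str = "expected_value"  # 'expected_value' | 'thresholded'
    threshold: float = 0.5
    outcome_scale: str = "log"

    def __post_init__(self) -> None:
        if self.combination_rule not in ("expected_value", "thresholded"):
            raise ValueError("combination_rule must be 'expected_value' or 'thresholded'")
        if self.combination_rule == "thresholded" and not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


def fit_hurdle(family: str, features: pd.DataFrame, outcome: np.ndarray,
               hyperparams: Mapping | None = None, seed: int = 0,
               combination_rule: str = "expected_value", threshold: float = 0.5,
               outcome_scale: str = "log") -> HurdleModel:
    """Fit a two-part hurdle model on a zero-inflated (log-scale) outcome.

    The occurrence part is a classifier on ``outcome > 0``; the amount part is
    a regressor trained on exactly the rows with positive outcome.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("outcome contains non-finite values")
    pos = y > 0
    if pos.all() or not pos.any():
        raise HurdleError(
            "hurdle models need both zero and positive outcomes in training data "
            f"(got {int(pos.sum())} positives of {len(y)} rows)"
        )
    clf = _make_estimator(family, "classification", hyperparams or {}, seed)
    clf.fit(features, pos.astype(int))
    reg = _make_estimator(family, "regression", hyperparams or {}, seed)
    reg.fit(features.loc[pos] if hasattr(features, "loc") else features[pos], y[pos])
    return HurdleModel(family=family, occurrence_part=clf, amount_part=reg,
                       combination_rule=combination_rule, threshold=threshold,
                       outcome_scale=outcome_scale)


def predict_hurdle_parts(model: HurdleModel, features) -> tuple[np.ndarray, np.ndarray]:
    """(p_hat of occurrence, amount_hat on the original serving scale)."""
    if model.occurrence_part is None or model.amount_part is None:
        raise ValueError("hurdle model is not fitted")
    one = list(model.occurrence_part.classes_).index(1)
    p = model.occurrence_part.predict_proba(features)[:, one]
    amount = model.amount_part.predict(features)
    if model.outcome_scale == "log":
        amount = back_transform(amount)
    return p, np.asarray(amount, dtype=float)


def predict_hurdle(model: HurdleModel, features) -> np.ndarray:
    """Combined hurdle prediction on the original outcome scale.

    expected_value: ``p_hat * amount_hat``; thresholded: ``amount_hat`` where
    ``p_hat >= threshold`` else 0.
    """
    p, amount = predict_hurdle_parts(model, features)
    if model.combination_rule == "expected_value":
        return p * amount
    return np.where(p >= model.threshold, amount, 0.0)


def predict_single_original(model, features, outcome_scale: str = "log") -> np.ndarray:
    """Single-model prediction mapped back to the original outcome scale."""
    pred = np.asarray(model.predict(features), dtype=float)
    return back_transform(pred) if outcome_scale == "log" else pred


# -------------------------------------------------------------- grid search

@dataclass(frozen=True)
class HyperGrid:
    """Named hyperparameter lists; combinations are their Cartesian product."""

    params: Mapping[str, Sequence]

    def __post_init__(self) -> None:
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ValueError("grid must be non-empty with non-empty value lists")

    @property
    def n_combinations(self) -> int:
        n = 1
        for v in self.params.values():
            n *= len(v)
        return n

    def combinations(self) -> list[dict]:
        names = list(self.params)
        return [dict(zip(names, combo))
                for combo in itertools.product(*(self.params[n] for n in names))]


def default_boosted_grid() -> HyperGrid:
    """216-combination SGBDT grid (trees x depth x learning rate x leaf size)."""
    return HyperGrid({
        "n_estimators": [100, 200, 300],
        "max_depth": [2, 3, 4, 6],
        "learning_rate": [0.01, 0.05, 0.1],
        "min_samples_leaf": [5, 10, 15, 20, 30, 40],
    })


def default_forest_grid() -> HyperGrid:
    """10-combination RF grid over the fraction of features tried per split."""
    return HyperGrid({"max_features": [round(0.1 * i, 1) for i in range(1, 11)]})


def count_training_runs(grid: HyperGrid, plan: CVPlan) -> int:
    """Total model training runs for a full grid search: combos x k x repeats."""
    return grid.n_combinations * plan.k * plan.repeats


@dataclass
class GridSearchResult:
    model_kind: str
    best_params: dict
    best_index: int
    cv_table: pd.DataFrame  # one row per combination: mean CV metrics
    oof: pd.DataFrame  # out-of-fold predictions of the best combination
    n_fits: int
    flagged: list = field(default_factory=list)
    final_model: object | None = None
    imputer: ColumnImputer | None = None
    feature_names: list[str] = field(default_factory=list)
    feature_groups: dict[str, str] = field(default_factory=dict)


def _original_scale(y: np.ndarray, scale: str) -> np.ndarray:
    return back_transform(y) if scale == "log" else np.asarray(y, dtype=float)


def _fit_predict(model_kind: str, Xtr, ytr, Xte, params, seed,
                 combination_rule, threshold, scale):
    if model_kind.startswith("hurdle_"):
        model = fit_hurdle(model_kind.removeprefix("hurdle_"), Xtr, ytr, params, seed,
                           combination_rule=combination_rule, threshold=threshold,
                           outcome_scale=scale)
        return model, predict_hurdle(model, Xte)
    model = fit_single(model_kind, Xtr, ytr, params, seed)
    return model, predict_single_original(model, Xte, scale)


def grid_search(
    model_kind: str,
    grid: HyperGrid,
    plan: CVPlan,
    table: FeatureTable,
    *,
    seed: int = 0,
    imputation: str = "per_fold",  # 'per_fold' | 'pre_cv'
    combination_rule: str = "expected_value",
    threshold: float = 0.5,
    base_params: Mapping | None = None,
    refit: bool = True,
) -> GridSearchResult:
    """Exhaustive grid search under a grouped repeated k-fold plan.

    Every combination is trained on every split (so the number of training
    runs equals ``count_training_runs(grid, plan)``); selection minimises the
    mean cross-validated MAE on the original outcome scale, with ties broken
    by fewer trees, then lower depth, then declaration order.  Out-of-fold
    predictions of the winning combination are retained for evaluation.

    With ``imputation='per_fold'`` (default) the median/mode imputer is fitted
    inside each training fold; ``'pre_cv'`` fits it once on all rows before
    CV, mirroring pipelines that impute during data preparation.
    """
    if model_kind not in MODEL_FAMILIES:
        raise ValueError(f"model_kind must be one of {MODEL_FAMILIES}")
    if imputation not in ("per_fold", "pre_cv"):
        raise ValueError("imputation must be 'per_fold' or 'pre_cv'")
    raw = table.predictors()
    y = table.outcome_values()
    pids = table.participant_ids()
    scale = table.outcome_scale
    actual_orig = _original_scale(y, scale)

    pre_imputer = impute_fit(raw, table.meta) if imputation == "pre_cv" else None
    if pre_imputer is not None:
        raw_full = pre_imputer.transform(raw)

    combos = grid.combinations()
    base = dict(base_params or {})
    split_list = list(plan.splits())
    masks = [(np.isin(pids, list(tr)), np.isin(pids, list(te)))
             for _, _, tr, te in split_list]

    n_fits = 0
    flagged: list[tuple[int, int, int, str]] = []
    per_combo_rows = []
    # per combo, keep only the raw prediction vectors (one per completed
    # split, keyed by split index); frames are built for the winner only
    oof_store: dict[int, dict[int, np.ndarray]] = {i: {} for i in range(len(combos))}
    for ci, combo in enumerate(combos):
        params = {**base, **combo}
        maes, rmses = [], []
        ok = True
        for si, ((r, f, _, _), (trm, tem)) in enumerate(zip(split_list, masks)):
            if pre_imputer is None:
                imp = impute_fit(raw.loc[trm], table.meta)
                Xtr_raw, Xte_raw = imp.transform(raw.loc[trm]), imp.transform(raw.loc[tem])
            else:
                Xtr_raw, Xte_raw = raw_full.loc[trm], raw_full.loc[tem]
            Xtr, _ = encode_features(Xtr_raw, table.meta)
            Xte, _ = encode_features(Xte_raw, table.meta)
            try:
                _, pred = _fit_predict(model_kind, Xtr, y[trm], Xte, params, seed,
                                       combination_rule, threshold, scale)
            except HurdleError as err:
                flagged.append((ci, r, f, str(err)))
                ok = False
                continue
            n_fits += 1
            err_v = pred - actual_orig[tem]
            maes.append(float(np.mean(np.abs(err_v))))
            rmses.append(float(np.sqrt(np.mean(err_v ** 2))))
            oof_store[ci][si] = np.asarray(pred, dtype=float)
        per_combo_rows.append({
            **combo,
            "combo_index": ci,
            "mean_mae": float(np.mean(maes)) if maes else np.nan,
            "mean_rmse": float(np.mean(rmses)) if rmses else np.nan,
            "n_splits_ok": len(maes),
            "flagged": not ok,
        })

    cv_table = pd.DataFrame(per_combo_rows)
    # flagged combinations (a fold lacked both outcome classes) stay in the
    # report; selection prefers combinations with the most completed splits
    done = cv_table[cv_table["mean_mae"].notna()]
    if done.empty:
        raise RuntimeError("no hyperparameter combination completed any CV split")
    valid = done[done["n_splits_ok"] == done["n_splits_ok"].max()]

    def sort_key(row) -> tuple:
        n_est = row.get("n_estimators")
        depth = row.get("max_depth")
        return (row["mean_mae"],
                np.inf if n_est is None else n_est,
                np.inf if depth is None else depth,
                row["combo_index"])

    ordered = sorted(valid.to_dict("records"), key=sort_key)
    best = ordered[0]
    best_index = int(best["combo_index"])
    best_params = {**base, **combos[best_index]}

    oof_frames = []
    for si, ((r, f, _, _), (_, tem)) in enumerate(zip(split_list, masks)):
        if si in oof_store[best_index]:
            oof_frames.append(pd.DataFrame({
                "repeat": r, "fold": f,
                "participant_id": pids[tem],
                "row": np.flatnonzero(tem),
                "actual": actual_orig[tem],
                "prediction": oof_store[best_index][si],
            }))
    oof = pd.concat(oof_frames, ignore_index=True)

    final_model = None
    final_imputer = pre_imputer
    groups: dict[str, str] = {}
    feature_names: list[str] = []
    if refit:
        final_imputer = pre_imputer or impute_fit(raw, table.meta)
        X_full, groups = encode_features(final_imputer.transform(raw), table.meta)
        feature_names = list(X_full.columns)
        if model_kind.startswith("hurdle_"):
            final_model = fit_hurdle(model_kind.removeprefix("hurdle_"), X_full, y,
                                     best_params, seed, combination_rule=combination_rule,
                                     threshold=threshold, outcome_scale=scale)
        else:
            final_model = fit_single(model_kind, X_full, y, best_params, seed)
    else:
        _, groups = encode_features(raw.iloc[:1].ffill().bfill(), table.meta)
        feature_names = list(groups)

    if flagged:
        warnings.warn(f"{len(set(c for c, *_ in flagged))} grid combination(s) flagged: "
                      "a CV fold lacked both outcome classes", stacklevel=2)
    return GridSearchResult(
        model_kind=model_kind, best_params=best_params, best_index=best_index,
        cv_table=cv_table, oof=oof, n_fits=n_fits, flagged=flagged,
        final_model=final_model, imputer=final_imputer,
        feature_names=feature_names, feature_groups=groups,
    )
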