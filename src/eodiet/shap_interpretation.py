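"""SHAP-style feature attribution and multi-level importance aggregation.

Per-instance, per-feature attributions are computed with exact path-dependent
tree attribution (:mod:`eodiet._treeshap`), so results are deterministic and
satisfy local accuracy: ``base_value + sum(attributions) == raw prediction``
for every instance.  The raw prediction scale is the model's natural additive
output — the response for regressors, class-1 probability for random-forest
classifiers, and the log-odds margin for boosted classifiers.

Hurdle models are interpreted per part (occurrence and amount); no combined-
prediction attribution is attempted.  Importance is the mean absolute
attribution over a chosen scope — one EO, one day, one participant, or all
EOs globally — and attributions of indicator columns can be pooled back to
their source factor so that rankings speak in terms of contextual factors.
Attributions describe model behaviour, not causal effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ._treeshap import shap_values_trees
from .hurdle_models import HurdleModel

__all__ = [
    "ShapAttribution",
    "ImportanceRanking",
    "compute_attributions",
    "compute_hurdle_attributions",
    "raw_prediction",
    "aggregate_importance",
    "importance_table",
    "top_k",
    "plot_importance_bump",
]

AGGREGATION_LEVELS = ("eo", "day", "participant", "global")


@dataclass
class ShapAttribution:
    """Per-instance additive attributions for one model (or hurdle part)."""

    part: str  # 'single' | 'occurrence' | 'amount'
    base_value: float
    values: pd.DataFrame  # one row per instance, one column per feature
    keys: pd.DataFrame  # participant_id / day_index / eo_id per instance
    raw_predictions: np.ndarray  # model raw output per instance

    def __post_init__(self) -> None:
        if len(self.values) != len(self.keys):
            raise ValueError("values and keys must align row-wise")

    def additivity_error(self) -> np.ndarray:
        """|base + sum(phi) - prediction| per instance (local accuracy check)."""
        recon = self.base_value + self.values.to_numpy().sum(axis=1)
        return np.abs(recon - self.raw_predictions)


@dataclass
class ImportanceRanking:
    """Mean absolute attribution per feature over one aggregation scope."""

    level: str
    values: pd.Series  # descending; declaration order breaks ties
    n_instances: int

    def __post_init__(self) -> None:
        if self.level not in AGGREGATION_LEVELS:
            raise ValueError(f"level must be one of {AGGREGATION_LEVELS}")
        if (self.values < 0).any():
            raise ValueError("mean absolute attributions are non-negative")


def _positive_class_column(model) -> int:
    classes = list(model.classes_)
    return classes.index(1) if 1 in classes else len(classes) - 1


def _tree_dicts(tree, value: np.ndarray, scale: float) -> dict:
    return {
        "children_left": tree.children_left,
        "children_right": tree.children_right,
        "feature": tree.feature,
        "threshold": tree.threshold,
        "value": value,
        "weight": tree.weighted_n_node_samples,
        "scale": scale,
    }


def _ensemble_decomposition(model):
    """(tree dicts, fixed intercept, raw-output function) for a fitted model."""
    if isinstance(model, (DecisionTreeRegressor,)):
        t = model.tree_
        return ([_tree_dicts(t, t.value[:, 0, 0], 1.0)], 0.0,
                lambda X: model.predict(X))
    if isinstance(model, DecisionTreeClassifier):
        t = model.tree_
        col = _positive_class_column(model)
        val = t.value[:, 0, col]
        return ([_tree_dicts(t, val, 1.0)], 0.0,
                lambda X: model.predict_proba(X)[:, col])
    if isinstance(model, RandomForestRegressor):
        n = len(model.estimators_)
        trees = [_tree_dicts(e.tree_, e.tree_.value[:, 0, 0], 1.0 / n)
                 for e in model.estimators_]
        return trees, 0.0, lambda X: model.predict(X)
    if isinstance(model, RandomForestClassifier):
        n = len(model.estimators_)
        col = _positive_class_column(model)
        trees = [_tree_dicts(e.tree_, e.tree_.value[:, 0, col], 1.0 / n)
                 for e in model.estimators_]
        return trees, 0.0, lambda X: model.predict_proba(X)[:, col]
    if isinstance(model, (GradientBoostingRegressor, GradientBoostingClassifier)):
        lr = model.learning_rate
        trees = [_tree_dicts(e.tree_, e.tree_.value[:, 0, 0], lr)
                 for e in model.estimators_[:, 0]]

        def intercept_of(X):
            return float(model._raw_predict_init(np.asarray(X)[:1])[0, 0])

        if isinstance(model, GradientBoostingRegressor):
            return trees, intercept_of, lambda X: model.predict(X)
        return trees, intercept_of, lambda X: model.decision_function(X)
    raise TypeError(f"unsupported model type for tree attribution: {type(model).__name__}")


def raw_prediction(model, X) -> np.ndarray:
    """The additive raw output that attributions reconstruct."""
    _, _, raw = _ensemble_decomposition(model)
    return np.asarray(raw(X), dtype=float)


def compute_attributions(
    model,
    instances: pd.DataFrame,
    keys: pd.DataFrame | None = None,
    part: str = "single",
    feature_groups: Mapping[str, str] | None = None,
    background: pd.DataFrame | None = None,  # reserved for sampling fallback
    seed: int | None = None,
) -> ShapAttribution:
    """Exact per-feature attributions for every instance.

    ``instances`` is the encoded design matrix the model was trained on.
    ``feature_groups`` (encoded column -> source factor) pools indicator
    columns of one factor into a single attribution column.  The path-exact
    algorithm needs no background sample; the argument is accepted for
    interface compatibility and ignored.
    """
    del background, seed
    if not hasattr(instances, "columns"):
        instances = pd.DataFrame(np.asarray(instances, dtype=float))
    trees, intercept, raw = _ensemble_decomposition(model)
    X = instances.to_numpy(dtype=float)
    n_model_features = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_model_features:
        raise ValueError(
            f"instances have {X.shape[1]} features but the model expects {n_model_features}"
        )
    phi, base = shap_values_trees(trees, X)
    base += intercept(X) if callable(intercept) else intercept
    raw_out = np.asarray(raw(instances), dtype=float)
    values = pd.DataFrame(phi, columns=list(instances.columns))
    if feature_groups:
        values = values.T.groupby(
            values.columns.map(lambda c: feature_groups.get(c, c)), sort=False
        ).sum().T
    if keys is None:
        keys = pd.DataFrame({
            "participant_id": "all", "day_index": 0,
            "eo_id": [f"row{i}" for i in range(len(values))],
        })
    keys = keys.reset_index(drop=True)
    return ShapAttribution(part=part, base_value=float(base), values=values,
                           keys=keys, raw_predictions=raw_out)


def compute_hurdle_attributions(
    model: HurdleModel,
    instances: pd.DataFrame,
    keys: pd.DataFrame | None = None,
    feature_groups: Mapping[str, str] | None = None,
) -> dict[str, ShapAttribution]:
    """Separate attributions for the occurrence and amount hurdle parts."""
    return {
        "occurrence": compute_attributions(model.occurrence_part, instances, keys,
                                           part="occurrence", feature_groups=feature_groups),
        "amount": compute_attributions(model.amount_part, instances, keys,
                                       part="amount", feature_groups=feature_groups),
    }


def _scope_mask(attr: ShapAttribution, level: str, key) -> np.ndarray:
    k = attr.keys
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"unknown aggregation level {level!r}; expected {AGGREGATION_LEVELS}")
    if level == "global":
        return np.ones(len(k), dtype=bool)
    if key is None:
        raise ValueError(f"aggregation level {level!r} requires a scope key")
    if level == "participant":
        return (k["participant_id"] == key).to_numpy()
    if level == "day":
        pid, day = key
        return ((k["participant_id"] == pid) & (k["day_index"] == day)).to_numpy()
    if level == "eo":
        return (k["eo_id"] == key).to_numpy()
    raise ValueError(f"unknown aggregation level {level!r}; expected {AGGREGATION_LEVELS}")


def aggregate_importance(attr: ShapAttribution, level: str,
                         key=None) -> ImportanceRanking:
    """Mean absolute attribution per feature over the instances in scope.

    ``key`` selects the scope unit: an ``eo_id`` for level 'eo', a
    ``(participant_id, day_index)`` pair for 'day', a ``participant_id`` for
    'participant'; 'global' uses all instances of all participants.
    """
    mask = _scope_mask(attr, level, key)
    if not mask.any():
        raise ValueError(f"no instances match {level!r} scope key {key!r}")
    sub = attr.values.loc[mask]
    means = sub.abs().mean(axis=0)
    order = np.lexsort((np.arange(len(means)), -means.to_numpy()))
    return ImportanceRanking(level=level, values=means.iloc[order],
                             n_instances=int(mask.sum()))


def importance_table(attr: ShapAttribution, level: str) -> pd.DataFrame:
    """Mean absolute attributions for every scope unit at a level."""
    if level == "global":
        r = aggregate_importance(attr, "global")
        return r.values.rename("global").to_frame().T
    joined = pd.concat([attr.keys.reset_index(drop=True),
                        attr.values.abs().reset_index(drop=True)], axis=1)
    group_cols = {"participant": ["participant_id"],
                  "day": ["participant_id", "day_index"],
                  "eo": ["eo_id"]}.get(level)
    if group_cols is None:
        raise ValueError(f"unknown aggregation level {level!r}")
    return joined.groupby(group_cols, sort=False)[list(attr.values.columns)].mean()


def top_k(ranking: ImportanceRanking, k: int) -> list[tuple[str, float, bool]]:
    """The k features with the highest mean absolute attribution.

    Ties keep declaration order and are flagged; asking for more features
    than exist warns and truncates.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = ranking.values
    if k > len(vals):
        warnings.warn(f"k={k} exceeds the {len(vals)} available features; truncating",
                      stacklevel=2)
        k = len(vals)
    counts = vals.round(12).value_counts()
    out = []
    for name, v in vals.iloc[:k].items():
        out.append((str(name), float(v), bool(counts.get(round(float(v), 12), 0) > 1)))
    return out


def plot_importance_bump(rankings: Sequence[ImportanceRanking], k: int = 5, ax=None):
    """Bump chart of feature ranks across aggregation scopes (EO → global)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.8 * len(rankings) + 3, 4))
    shown = []
    for r in rankings:
        shown.extend(name for name, _, _ in top_k(r, min(k, len(r.values))))
    shown = list(dict.fromkeys(shown))
    xs = range(len(rankings))
    for feat in shown:
        ys = []
        for r in rankings:
            names = list(r.values.index)
            ys.append(names.index(feat) + 1 if feat in names else np.nan)
        ax.plot(xs, ys, marker="o", label=feat)
    ax.set_xticks(list(xs), [r.level for r in rankings])
    ax.invert_yaxis()
    ax.set_ylabel("importance rank (1 = highest)")
    ax.legend(fontsize=7, loc="center left", bbox_to_anchor=(1.01, 0.5))
    return ax
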