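"""Tree attribution: local accuracy, exact Shapley agreement, aggregation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeRegressor

from conftest import brute_force_shapley
from eodiet.hurdle_models import encode_features, fit_hurdle, impute_fit
from eodiet.shap_interpretation import (
    ImportanceRanking,
    ShapAttribution,
    aggregate_importance,
    compute_attributions,
    compute_hurdle_attributions,
    importance_table,
    top_k,
)


@pytest.fixture(scope="module")
def xy():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(400, 8)), columns=[f"f{i}" for i in range(8)])
    y = 2 * X.f0 - X.f1 + X.f2 * X.f3 + rng.normal(scale=0.3, size=400)
    return X, y.to_numpy()


MODELS = [
    lambda X, y: GradientBoostingRegressor(n_estimators=40, subsample=0.8,
                                           random_state=0).fit(X, y),
    lambda X, y: RandomForestRegressor(n_estimators=40, random_state=0).fit(X, y),
    lambda X, y: GradientBoostingClassifier(n_estimators=40, subsample=0.8,
                                            random_state=0).fit(X, (y > 0).astype(int)),
    lambda X, y: RandomForestClassifier(n_estimators=40, random_state=0).fit(
        X, (y > 0).astype(int)),
]


class TestLocalAccuracy:
    @pytest.mark.parametrize("make", MODELS)
    def test_base_plus_attributions_reconstruct_prediction(self, xy, make):
        X, y = xy
        attr = compute_attributions(make(X, y), X)
        assert attr.additivity_error().max() < 1e-6

    def test_unused_feature_gets_zero_attribution(self, xy):
        X, y = xy
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        attr = compute_attributions(stump, X)
        used = stump.tree_.feature[0]
        unused = [c for i, c in enumerate(X.columns) if i != used]
        assert (attr.values[unused] == 0.0).all().all()


class TestExactShapleyAgreement:
    def test_stump_matches_exhaustive_enumeration(self, xy):
        X, y = xy
        stump = DecisionTreeRegressor(max_depth=1, random_state=0).fit(X, y)
        attr = compute_attributions(stump, X)
        for r in range(10):
            oracle = brute_force_shapley(stump.tree_, X.to_numpy()[r], 8)
            assert np.abs(attr.values.iloc[r].to_numpy() - oracle).max() < 1e-10

    @pytest.mark.parametrize("depth", [2, 4, 6])
    def test_deeper_trees_match_exhaustive_enumeration(self, xy, depth):
        X, y = xy
        tree = DecisionTreeRegressor(max_depth=depth, random_state=0).fit(X, y)
        attr = compute_attributions(tree, X)
        for r in (0, 57, 311):
            oracle = brute_force_shapley(tree.tree_, X.to_numpy()[r], 8)
            assert np.abs(attr.values.iloc[r].to_numpy() - oracle).max() < 1e-10

    def test_feature_count_mismatch_rejected(self, xy):
        X, y = xy
        model = RandomForestRegressor(n_estimators=5, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            compute_attributions(model, X.iloc[:, :4].rename(columns=str))


class TestHurdleAttribution:
    def test_parts_are_attributed_separately(self, small_occasions):
        from eodiet.hurdle_models import build_feature_table

        table = build_feature_table(small_occasions, "servings_vegetables")
        imp = impute_fit(table.predictors(), table.meta)
        X, groups = encode_features(imp.transform(table.predictors()), table.meta)
        model = fit_hurdle("random_forest", X, table.outcome_values(),
                           {"n_estimators": 20, "max_depth": 6}, seed=0)
        keys = table.data[["participant_id", "day_index", "eo_id"]]
        parts = compute_hurdle_attributions(model, X, keys, feature_groups=groups)
        assert set(parts) == {"occurrence", "amount"}
        for attr in parts.values():
            assert attr.additivity_error().max() < 1e-6
            # indicator columns pooled back to source factors
            assert "eo_type" in attr.values.columns


def _toy_attr():
    values = pd.DataFrame({"a": [1.0, -1.0, 2.0, 0.5], "b": [0.2, 0.2, -0.4, 0.0]})
    keys = pd.DataFrame({
        "participant_id": ["p1", "p1", "p1", "p2"],
        "day_index": [1, 1, 2, 1],
        "eo_id": ["e1", "e2", "e3", "e4"],
    })
    return ShapAttribution(part="single", base_value=0.0, values=values, keys=keys,
                           raw_predictions=values.sum(axis=1).to_numpy())


class TestAggregation:
    def test_single_eo_is_absolute_attribution_verbatim(self):
        r = aggregate_importance(_toy_attr(), "eo", key="e2")
        assert r.values["a"] == 1.0 and r.values["b"] == 0.2

    def test_opposite_signs_average_by_magnitude(self):
        r = aggregate_importance(_toy_attr(), "day", key=("p1", 1))
        assert r.values["a"] == pytest.approx(1.0)  # mean(|1|, |-1|)

    def test_day_level_equals_brute_force_mean(self):
        attr = _toy_attr()
        r = aggregate_importance(attr, "day", key=("p1", 2))
        mask = (attr.keys.participant_id == "p1") & (attr.keys.day_index == 2)
        for f in attr.values.columns:
            assert r.values[f] == attr.values.loc[mask.to_numpy(), f].abs().mean()

    def test_global_equals_instance_weighted_participant_pooling(self):
        attr = _toy_attr()
        g = aggregate_importance(attr, "global")
        per_part = importance_table(attr, "participant")
        weights = attr.keys.groupby("participant_id", sort=False).size()
        pooled = per_part.mul(weights, axis=0).sum() / weights.sum()
        for f in attr.values.columns:
            assert g.values[f] == pytest.approx(pooled[f])

    def test_unknown_level_and_missing_key_rejected(self):
        with pytest.raises(ValueError, match="unknown aggregation level"):
            aggregate_importance(_toy_attr(), "week", key=None)
        with pytest.raises(ValueError, match="requires a scope key"):
            aggregate_importance(_toy_attr(), "day")
        with pytest.raises(ValueError, match="no instances"):
            aggregate_importance(_toy_attr(), "eo", key="nope")


class TestTopK:
    def _ranking(self, values):
        s = pd.Series(values)
        order = np.lexsort((np.arange(len(s)), -s.to_numpy()))
        return ImportanceRanking(level="global", values=s.iloc[order], n_instances=5)

    def test_k1_is_argmax(self):
        r = self._ranking({"a": 0.1, "b": 0.9, "c": 0.4})
        assert top_k(r, 1)[0][0] == "b"

    def test_all_equal_values_keep_declaration_order_and_flag_ties(self):
        # mirrors a ranking where five factors share one attribution value
        r = self._ranking({f: 0.0005 for f in "abcde"})
        out = top_k(r, 5)
        assert [f for f, _, _ in out] == list("abcde")
        assert all(tied for _, _, tied in out)

    def test_k_equal_to_feature_count_is_a_permutation(self):
        r = self._ranking({"a": 0.3, "b": 0.1, "c": 0.2})
        assert sorted(f for f, _, _ in top_k(r, 3)) == ["a", "b", "c"]

    def test_k_beyond_feature_count_warns_and_truncates(self):
        r = self._ranking({"a": 0.3, "b": 0.1})
        with pytest.warns(UserWarning, match="truncating"):
            out = top_k(r, 5)
        assert len(out) == 2

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            top_k(self._ranking({"a": 1.0}), 0)
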