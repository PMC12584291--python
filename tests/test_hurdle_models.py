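"""Grouped CV plans, fold-safe imputation, hurdle models and grid search."""

import numpy as np
import pandas as pd
import pytest

from eodiet.hurdle_models import (
    ColumnImputer,
    HurdleError,
    HyperGrid,
    build_cv_plan,
    build_feature_table,
    count_training_runs,
    default_boosted_grid,
    default_forest_grid,
    encode_features,
    fit_hurdle,
    fit_single,
    grid_search,
    impute_apply,
    impute_fit,
    predict_hurdle,
    predict_hurdle_parts,
)


@pytest.fixture(scope="module")
def veg_table(small_occasions):
    return build_feature_table(small_occasions, "servings_vegetables")


@pytest.fixture(scope="module")
def encoded(veg_table):
    imp = impute_fit(veg_table.predictors(), veg_table.meta)
    X, groups = encode_features(imp.transform(veg_table.predictors()), veg_table.meta)
    return X, veg_table.outcome_values(), groups


class TestCVPlan:
    def test_twenty_participants_make_ten_folds_of_two(self):
        plan = build_cv_plan([f"p{i}" for i in range(20)], k=10, repeats=1, seed=0)
        sizes = [len(plan.assignment[(0, f)]) for f in range(10)]
        assert sizes == [2] * 10

    def test_fold_sizes_balanced_within_one(self):
        plan = build_cv_plan([f"p{i}" for i in range(47)], k=10, repeats=2, seed=1)
        for r in range(2):
            sizes = [len(plan.assignment[(r, f)]) for f in range(10)]
            assert max(sizes) - min(sizes) <= 1

    def test_train_and_test_participants_never_overlap(self):
        plan = build_cv_plan([f"p{i}" for i in range(33)], k=5, repeats=3, seed=2)
        for _, _, train, test in plan.splits():
            assert not train & test
            assert train | test == {f"p{i}" for i in range(33)}

    def test_deterministic_given_seed(self):
        a = build_cv_plan(range(30), k=5, repeats=2, seed=3)
        b = build_cv_plan(range(30), k=5, repeats=2, seed=3)
        assert a.assignment == b.assignment

    def test_more_folds_than_participants_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_cv_plan(["a", "b"], k=10, repeats=1, seed=0)


class TestImputation:
    meta = {"x": {"kind": "numeric", "level": "person"},
            "c": {"kind": "categorical", "level": "eo", "levels": ("a", "b", "z")}}

    def test_complete_table_passes_through(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "c": ["a", "b"]})
        out = impute_apply(impute_fit(df, self.meta), df)
        pd.testing.assert_frame_equal(out, df)

    def test_numeric_filled_with_training_median(self):
        train = pd.DataFrame({"x": [1.0, 3.0, 100.0], "c": ["a", "a", "b"]})
        test = pd.DataFrame({"x": [np.nan, 5.0], "c": ["b", "b"]})
        out = impute_apply(impute_fit(train, self.meta), test)
        assert out.loc[0, "x"] == 3.0  # median of the training column

    def test_categorical_filled_with_training_mode(self):
        train = pd.DataFrame({"x": [0.0, 0.0, 0.0], "c": ["z", "z", "a"]})
        test = pd.DataFrame({"x": [1.0], "c": [np.nan]})
        out = impute_apply(impute_fit(train, self.meta), test)
        assert out.loc[0, "c"] == "z"

    def test_all_missing_column_rejected(self):
        train = pd.DataFrame({"x": [np.nan, np.nan], "c": ["a", "b"]})
        with pytest.raises(ValueError, match="'x'"):
            impute_fit(train, self.meta)

    def test_unfitted_imputer_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            ColumnImputer(self.meta).transform(pd.DataFrame({"x": [1.0], "c": ["a"]}))


class TestEncoding:
    def test_indicator_and_ordered_codes(self):
        meta = {"sex": {"kind": "categorical", "level": "person",
                        "levels": ("female", "male")},
                "seifa": {"kind": "categorical", "level": "person",
                          "levels": ("low", "medium", "high")},
                "age": {"kind": "numeric", "level": "person"}}
        raw = pd.DataFrame({"sex": ["female", "male"], "seifa": ["high", "low"],
                            "age": [20.0, 25.0]})
        X, groups = encode_features(raw, meta)
        assert list(X["sex=female"]) == [1.0, 0.0]
        assert list(X["seifa"]) == [2.0, 0.0]  # ordered integer codes
        assert groups["sex=female"] == "sex" and groups["age"] == "age"

    def test_column_order_stable_across_subsets(self, veg_table):
        raw = veg_table.predictors()
        a, _ = encode_features(raw.iloc[:10], veg_table.meta)
        b, _ = encode_features(raw.iloc[10:40], veg_table.meta)
        assert list(a.columns) == list(b.columns)

    def test_outcome_never_among_predictors(self, veg_table):
        assert veg_table.outcome == "log_servings_vegetables"
        assert veg_table.outcome not in veg_table.meta


class TestFitting:
    def test_constant_outcome_predicted_exactly(self, encoded):
        X, _, _ = encoded
        y = np.full(len(X), 2.5)
        for fam in ("boosted_trees", "random_forest"):
            m = fit_single(fam, X, y, {"n_estimators": 10}, seed=0)
            assert np.allclose(m.predict(X), 2.5)

    def test_strong_signal_beats_mean_predictor(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=800)})
        y = 2.0 * X["x"].to_numpy() + rng.normal(scale=0.1, size=800)
        m = fit_single("random_forest", X, y, {"n_estimators": 50}, seed=0)
        mae_model = np.abs(m.predict(X) - y).mean()
        mae_mean = np.abs(y.mean() - y).mean()
        assert mae_model < mae_mean

    def test_nonfinite_outcome_rejected(self, encoded):
        X, y, _ = encoded
        bad = y.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_single("random_forest", X, bad, seed=0)

    def test_hurdle_requires_both_classes(self, encoded):
        X, _, _ = encoded
        with pytest.raises(HurdleError):
            fit_hurdle("random_forest", X, np.ones(len(X)), seed=0)
        with pytest.raises(HurdleError):
            fit_hurdle("random_forest", X, np.zeros(len(X)), seed=0)

    def test_amount_part_trained_on_exactly_the_positive_rows(self, encoded):
        X, y, _ = encoded
        m = fit_hurdle("boosted_trees", X, y,
                       {"n_estimators": 5, "subsample": 1.0}, seed=0)
        first_tree = m.amount_part.estimators_[0, 0].tree_
        assert first_tree.n_node_samples[0] == int((y > 0).sum())

    def test_expected_value_prediction_is_product_of_parts(self, encoded):
        X, y, _ = encoded
        m = fit_hurdle("random_forest", X, y, {"n_estimators": 20}, seed=0)
        p, amount = predict_hurdle_parts(m, X)
        combined = predict_hurdle(m, X)
        assert np.array_equal(combined, p * amount)

    def test_thresholded_rule_gates_on_probability(self, encoded):
        X, y, _ = encoded
        m = fit_hurdle("random_forest", X, y, {"n_estimators": 20}, seed=0,
                       combination_rule="thresholded", threshold=0.5)
        p, amount = predict_hurdle_parts(m, X)
        combined = predict_hurdle(m, X)
        assert np.array_equal(combined, np.where(p >= 0.5, amount, 0.0))


class TestGridSearch:
    def test_single_combination_is_returned(self, veg_table):
        plan = build_cv_plan(veg_table.participant_ids(), k=3, repeats=1, seed=0)
        grid = HyperGrid({"n_estimators": [15], "max_features": [0.5]})
        res = grid_search("random_forest", grid, plan, veg_table, seed=0, refit=False)
        assert res.best_params == {"n_estimators": 15, "max_features": 0.5}
        assert res.n_fits == 3

    def test_fit_count_equals_combinations_times_splits(self, veg_table):
        plan = build_cv_plan(veg_table.participant_ids(), k=3, repeats=2, seed=1)
        grid = HyperGrid({"n_estimators": [5, 10], "max_depth": [2, 3]})
        res = grid_search("boosted_trees", grid, plan, veg_table, seed=0, refit=False)
        assert res.n_fits == 4 * 3 * 2 == count_training_runs(grid, plan)

    def test_tie_on_constant_outcome_broken_by_fewer_trees(self, veg_table):
        data = veg_table.data.copy()
        data[veg_table.outcome] = 1.0  # every model predicts exactly 1.0
        table = type(veg_table)(data=data, outcome=veg_table.outcome,
                                meta=veg_table.meta, outcome_scale="log")
        plan = build_cv_plan(table.participant_ids(), k=3, repeats=1, seed=2)
        grid = HyperGrid({"n_estimators": [300, 50]})
        res = grid_search("random_forest", grid, plan, table, seed=0, refit=False)
        assert res.best_params["n_estimators"] == 50

    def test_reproducible_given_seed(self, veg_table):
        plan = build_cv_plan(veg_table.participant_ids(), k=3, repeats=1, seed=3)
        grid = HyperGrid({"n_estimators": [10, 20]})
        a = grid_search("random_forest", grid, plan, veg_table, seed=5, refit=False)
        b = grid_search("random_forest", grid, plan, veg_table, seed=5, refit=False)
        assert a.best_params == b.best_params
        pd.testing.assert_frame_equal(a.oof, b.oof)

    def test_oof_predictions_cover_all_rows_each_repeat(self, veg_table):
        plan = build_cv_plan(veg_table.participant_ids(), k=3, repeats=2, seed=4)
        grid = HyperGrid({"n_estimators": [10]})
        res = grid_search("random_forest", grid, plan, veg_table, seed=0, refit=False)
        counts = res.oof.groupby("repeat")["row"].nunique()
        assert (counts == len(veg_table.data)).all()

    def test_fold_without_both_classes_is_flagged_not_dropped(self, veg_table):
        data = veg_table.data.copy()
        pids = sorted(data["participant_id"].unique())
        # positives only for one participant: when that participant is held
        # out, the training fold has a single class and the split is flagged
        data[veg_table.outcome] = np.where(data["participant_id"] == pids[0], 1.0, 0.0)
        table = type(veg_table)(data=data, outcome=veg_table.outcome,
                                meta=veg_table.meta, outcome_scale="log")
        plan = build_cv_plan(pids, k=4, repeats=1, seed=5)
        grid = HyperGrid({"n_estimators": [5]})
        with pytest.warns(UserWarning, match="flagged"):
            res = grid_search("hurdle_random_forest", grid, plan, table,
                              seed=0, refit=False)
        assert len(res.flagged) == 1
        assert bool(res.cv_table.loc[0, "flagged"])
        assert res.cv_table.loc[0, "n_splits_ok"] == 3

    def test_hurdle_grid_search_runs_end_to_end(self, veg_table):
        plan = build_cv_plan(veg_table.participant_ids(), k=3, repeats=1, seed=6)
        grid = HyperGrid({"n_estimators": [15]})
        res = grid_search("hurdle_random_forest", grid, plan, veg_table, seed=0)
        assert res.final_model is not None
        assert (res.oof["prediction"] >= 0).all()


class TestAccounting:
    def test_published_training_run_counts(self):
        plan = build_cv_plan(range(40), k=10, repeats=3, seed=0)
        assert default_boosted_grid().n_combinations == 216
        assert count_training_runs(default_boosted_grid(), plan) == 6480
        assert default_forest_grid().n_combinations == 10
        assert count_training_runs(default_forest_grid(), plan) == 300

    def test_degenerate_single_run(self):
        plan = build_cv_plan(range(4), k=2, repeats=1, seed=0)
        grid = HyperGrid({"n_estimators": [10]})
        assert count_training_runs(grid, plan) == 2  # 1 combination x 2 folds

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            HyperGrid({})
        with pytest.raises(ValueError):
            HyperGrid({"a": []})
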