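import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.tree import DecisionTreeClassifier

from tracewell.modeling import (FoldSplit, FoldResult, ModelSpec,
                                classification_model_specs, cv_classification,
                                cv_regression, majority_baseline, make_folds,
                                regression_baselines, regression_model_specs,
                                run_rfe, stable_features)


class TestFolds:
    def test_372_users_split_298_37_37(self, rng):
        folds = make_folds(rng.uniform(size=372), seed=0)
        assert len(folds) == 10
        for f in folds:
            assert (len(f.train), len(f.dev), len(f.test)) == (298, 37, 37)

    def test_test_bins_disjoint_and_cover_all_but_leftovers(self, rng):
        folds = make_folds(rng.uniform(size=372), seed=1)
        tested = np.concatenate([f.test for f in folds])
        assert len(tested) == len(set(tested)) == 370

    def test_bins_stratified_over_target_range(self, rng):
        y = rng.uniform(size=500)
        folds = make_folds(y, seed=2)
        for f in folds:
            assert abs(y[f.test].mean() - y.mean()) < 0.05

    def test_too_small_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            make_folds(rng.uniform(size=19))

    def test_leakage_assertion_fires(self):
        split = FoldSplit(0, np.array([0, 1]), np.array([1, 2]),
                          np.array([3]))
        with pytest.raises(AssertionError):
            split.assert_disjoint()

    def test_model_family_rosters(self):
        assert len(regression_model_specs()) == 7
        assert len(classification_model_specs()) == 3


class TestRFE:
    def test_best_subset_no_worse_than_full_set(self, rng):
        X = rng.normal(size=(120, 30))
        y = X[:, 0] + rng.normal(0, 0.5, 120)
        sel, history = run_rfe(Ridge(), X[:60], y[:60], X[60:], y[60:])
        full_score = history[0][1]
        best_score = min(s for _, s in history)
        sel_set = {tuple(sorted(a)): s for a, s in history}
        assert sel_set[tuple(sorted(sel))] == best_score <= full_score

    def test_single_feature_returned(self, rng):
        X = rng.normal(size=(40, 1))
        y = rng.normal(size=40)
        sel, _ = run_rfe(Ridge(), X[:20], y[:20], X[20:], y[20:])
        assert list(sel) == [0]

    def test_all_constant_features_warn(self, rng):
        X = np.ones((30, 4))
        y = rng.normal(size=30)
        with pytest.warns(UserWarning):
            sel, _ = run_rfe(Ridge(), X[:15], y[:15], X[15:], y[15:])
        assert len(sel) == 1

    def test_planted_informative_feature_retained(self):
        kept = 0
        n_sims = 50
        for s in range(n_sims):
            rng = np.random.default_rng(500 + s)
            X = rng.normal(size=(300, 51))
            y = X[:, 0] + rng.normal(0, 0.5, 300)
            sel, _ = run_rfe(Ridge(), X[:200], y[:200], X[200:], y[200:])
            if 0 in sel:
                kept += 1
        assert kept >= int(0.9 * n_sims)


def linear_spec():
    return [ModelSpec("Linear", LinearRegression, {})]


class TestRegressionCV:
    def test_constant_target_gives_zero_mae(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 5)))
        y = np.full(100, 0.4)
        folds = make_folds(rng.uniform(size=100), seed=0)
        report = cv_regression(X, y, folds, specs=linear_spec())
        assert report.aggregates.loc["Linear", "mae"] == pytest.approx(0.0)
        assert report.baselines["mean_baseline_mae"] == pytest.approx(0.0)

    def test_noiseless_linear_target_recovered(self, rng):
        X = pd.DataFrame(rng.normal(size=(120, 4)))
        y = 2.0 * X[0].to_numpy() + 1.0
        report = cv_regression(X, y, make_folds(y, seed=0),
                               specs=linear_spec())
        agg = report.aggregates.loc["Linear"]
        assert agg["mae"] == pytest.approx(0.0, abs=1e-8)
        assert agg["pearson_r"] == pytest.approx(1.0)

    def test_planted_variance_fraction_recovered(self, rng):
        # signal explains q = 0.5 of target variance; fold-averaged R²
        # approaches q at n = 2000
        n, q = 2000, 0.5
        x = rng.normal(size=n)
        y = np.sqrt(q) * x + np.sqrt(1 - q) * rng.normal(size=n)
        X = pd.DataFrame({"signal": x,
                          **{f"noise{j}": rng.normal(size=n)
                             for j in range(9)}})
        report = cv_regression(X, y, make_folds(y, seed=3),
                               specs=[ModelSpec("Ridge", Ridge,
                                                {"alpha": [1.0]})])
        assert report.aggregates.loc["Ridge", "r2"] == pytest.approx(
            q, abs=0.1)

    def test_nonfinite_features_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)))
        X.iloc[0, 0] = np.nan
        y = rng.uniform(size=100)
        with pytest.raises(ValueError):
            cv_regression(X, y, make_folds(y, seed=0), specs=linear_spec())

    def test_aggregates_are_fold_means(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 3)))
        y = X[0].to_numpy() + rng.normal(0, 0.3, 100)
        report = cv_regression(X, y, make_folds(y, seed=0),
                               specs=linear_spec())
        maes = [r.metrics["mae"] for r in report.results_for("Linear")]
        assert report.aggregates.loc["Linear", "mae"] == pytest.approx(
            np.mean(maes))


class TestClassificationCV:
    def tree_spec(self):
        return [ModelSpec("Tree",
                          lambda **kw: DecisionTreeClassifier(
                              random_state=0, **kw), {"max_depth": [3]})]

    def test_separable_classes_perfectly_classified(self, rng):
        x = np.concatenate([rng.uniform(0, 0.4, 60),
                            rng.uniform(0.6, 1.0, 60)])
        labels = np.where(x < 0.5, "low", "high")
        X = pd.DataFrame({"x": x, "noise": rng.normal(size=120)})
        report = cv_classification(X, labels, make_folds(x, seed=0),
                                   specs=self.tree_spec())
        assert report.aggregates.loc["Tree", "f1_macro"] > 0.99

    def test_majority_low_baseline_has_unit_rates(self):
        y_train = np.array(["low"] * 6 + ["high"] * 4)
        y_test = np.array(["low", "low", "high", "high"])
        m = majority_baseline(y_train, y_test)
        assert m["tpr_low"] == 1.0 and m["fpr_low"] == 1.0
        assert m["f1_high"] == 0.0

    def test_four_user_metrics_match_hand_confusion(self):
        # predictions all "low" against truth [low, low, high, high]:
        # TP=2 FP=2 FN=0 -> precision 0.5, recall 1, F1_low = 2/3
        m = majority_baseline(np.array(["low", "low", "low", "high"]),
                              np.array(["low", "low", "high", "high"]))
        assert m["f1_low"] == pytest.approx(2 / 3)
        assert m["f1_macro"] == pytest.approx((2 / 3) / 2)
        assert m["f1_weighted"] == pytest.approx((2 / 3) / 2)

    def test_single_class_fold_skipped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 2)))
        labels = np.array(["low"] * 59 + ["high"])
        folds = make_folds(rng.uniform(size=60), n_bins=3, seed=0)
        with pytest.warns(UserWarning):
            try:
                cv_classification(X, labels, folds, specs=self.tree_spec())
            except ValueError:
                pass  # every fold may lack the rare class


class TestBaselines:
    def test_mean_baseline_is_mean_absolute_deviation(self, rng):
        y = rng.normal(size=50)
        out = regression_baselines(y, y)
        assert out["mean_baseline_mae"] == pytest.approx(
            np.mean(np.abs(y - y.mean())))

    def test_median_baseline_on_skewed_toy(self):
        y = np.array([0.0, 0.0, 0.0, 1.0])
        assert regression_baselines(y, y)["median_baseline_mae"] == 0.25

    def test_majority_baseline_matches_counting_oracle(self, rng):
        y_train = rng.choice(["low", "high"], size=40, p=[0.7, 0.3])
        y_test = rng.choice(["low", "high"], size=20)
        m = majority_baseline(y_train, y_test)
        # train majority is "low" -> predict all low
        tp = np.sum(y_test == "low")
        fp = np.sum(y_test == "high")
        assert m["tpr_low"] == pytest.approx(tp / max(tp, 1) if tp else 0)
        assert m["fpr_low"] == pytest.approx(1.0 if fp else 0.0)


class TestStableFeatures:
    def make_results(self, counts):
        results = []
        for fold in range(10):
            selected = [f for f, c in counts.items() if fold < c]
            results.append(FoldResult(
                fold=fold, model="m", params={}, selected=selected,
                metrics={}, importances={f: fold + 1.0 for f in selected}))
        return results

    def test_five_fold_floor(self):
        report = stable_features(self.make_results({"a": 5, "b": 4}))
        assert list(report["feature"]) == ["a"]

    def test_empty_report_is_valid(self):
        report = stable_features(self.make_results({"a": 2}))
        assert len(report) == 0

    def test_mean_coefficient_over_selected_folds(self):
        report = stable_features(self.make_results({"a": 6}))
        # importances were 1..6 in the six folds where selected
        assert report.loc[0, "mean_coefficient"] == pytest.approx(3.5)
        assert report.loc[0, "n_folds"] == 6
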