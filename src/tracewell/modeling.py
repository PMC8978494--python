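"""Value-stratified cross-validated evaluation harness.

The design mirrors a 10-fold train/dev/test scheme: the sample is
shuffled, sorted by the target, and sorted index ``j`` goes to bin
``j mod n_bins`` until every bin holds ``floor(n/10)`` users (leftovers
always stay in train), so every bin spans the target's range.  Fold ``i``
tests on bin ``i`` and develops on bin ``(i+1) mod 10``; the remaining
users train.  Within each fold, hyperparameters are chosen on the dev
set, recursive feature elimination (drop the least-important 10% per
step, keep the subset with the best dev score) selects features, and
metrics are computed on the untouched test bin and averaged over folds.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import (AdaBoostClassifier, AdaBoostRegressor,
                              RandomForestClassifier, RandomForestRegressor)
from sklearn.linear_model import (ElasticNet, Lasso, LinearRegression,
                                  LogisticRegression, Ridge)
from sklearn.metrics import f1_score, mean_absolute_error, r2_score
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "ModelSpec",
    "FoldResult",
    "RunReport",
    "make_folds",
    "regression_model_specs",
    "classification_model_specs",
    "run_rfe",
    "cv_regression",
    "cv_classification",
    "regression_baselines",
    "majority_baseline",
    "stable_features",
]


@dataclass
class FoldSplit:
    index: int
    train: np.ndarray
    dev: np.ndarray
    test: np.ndarray

    def assert_disjoint(self) -> None:
        a, b, c = set(self.train), set(self.dev), set(self.test)
        if a & b or a & c or b & c:
            raise AssertionError("fold leakage: overlapping train/dev/test")


def make_folds(target, n_bins: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Build the 10 value-stratified train/dev/test splits.

    At n = 372 and 10 bins this yields 298/37/37 users per fold, with the
    2 leftover users always in train.
    """
    y = np.asarray(target, dtype=float)
    n = y.size
    if n < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} users for {n_bins} bins")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    order = perm[np.argsort(y[perm], kind="stable")]
    bin_size = n // n_bins
    binned = order[:bin_size * n_bins]
    leftover = order[bin_size * n_bins:]
    bins = [binned[j::n_bins] for j in range(n_bins)]
    folds = []
    for i in range(n_bins):
        test = bins[i]
        dev = bins[(i + 1) % n_bins]
        rest = [bins[j] for j in range(n_bins) if j not in (i, (i + 1) % n_bins)]
        train = np.concatenate(rest + [leftover])
        split = FoldSplit(i, np.sort(train), np.sort(dev), np.sort(test))
        split.assert_disjoint()
        folds.append(split)
    return folds


@dataclass
class ModelSpec:
    """A model family plus its (small, overridable) hyperparameter grid."""

    name: str
    factory: object  # callable(**params) -> estimator
    grid: dict = field(default_factory=dict)

    def candidates(self):
        if not self.grid:
            yield {}
            return
        keys = list(self.grid)
        for combo in itertools.product(*(self.grid[k] for k in keys)):
            yield dict(zip(keys, combo))


def regression_model_specs(random_state: int = 0) -> list[ModelSpec]:
    """The seven regression families: linear fits with several
    regularizations, a decision tree and two ensembles."""
    rs = {"random_state": random_state}
    return [
        ModelSpec("Linear", LinearRegression, {}),
        ModelSpec("Ridge", Ridge, {"alpha": [0.1, 1.0, 10.0]}),
        ModelSpec("Lasso", lambda **kw: Lasso(max_iter=5000, **kw),
                  {"alpha": [0.001, 0.01, 0.1]}),
        ModelSpec("ElasticNet",
                  lambda **kw: ElasticNet(max_iter=5000, **kw),
                  {"alpha": [0.001, 0.01, 0.1], "l1_ratio": [0.5]}),
        ModelSpec("DecisionTree",
                  lambda **kw: DecisionTreeRegressor(**rs, **kw),
                  {"max_depth": [3, 5, 8]}),
        ModelSpec("RandomForest",
                  lambda **kw: RandomForestRegressor(**rs, **kw),
                  {"n_estimators": [50], "max_depth": [None, 5]}),
        ModelSpec("AdaBoost",
                  lambda **kw: AdaBoostRegressor(**rs, **kw),
                  {"n_estimators": [50]}),
    ]


def classification_model_specs(random_state: int = 0) -> list[ModelSpec]:
    rs = {"random_state": random_state}
    return [
        ModelSpec("LogisticRegression",
                  lambda **kw: LogisticRegression(max_iter=2000, **kw),
                  {"C": [0.1, 1.0, 10.0]}),
        ModelSpec("RandomForest",
                  lambda **kw: RandomForestClassifier(**rs, **kw),
                  {"n_estimators": [50], "max_depth": [None, 5]}),
        ModelSpec("AdaBoost",
                  lambda **kw: AdaBoostClassifier(**rs, **kw),
                  {"n_estimators": [50]}),
    ]


def _importances(est) -> np.ndarray:
    if hasattr(est, "feature_importances_"):
        return np.asarray(est.feature_importances_, dtype=float)
    coef = np.asarray(est.coef_, dtype=float)
    if coef.ndim > 1:  # multiclass: aggregate magnitude over classes
        coef = np.abs(coef).sum(axis=0)
    return np.abs(coef)


def _dev_score(est, X_dev, y_dev, task: str) -> float:
    """Lower-is-better development score (MAE, or negated F1-macro)."""
    pred = est.predict(X_dev)
    if task == "regression":
        return mean_absolute_error(y_dev, pred)
    return -f1_score(y_dev, pred, average="macro", zero_division=0)


def run_rfe(estimator, X_train, y_train, X_dev, y_dev,
            task: str = "regression", step: float = 0.1
            ) -> tuple[np.ndarray, list]:
    """Recursive feature elimination guided by the development set.

    Repeatedly fits the estimator, drops the least-important 10% of the
    remaining features (at least one), and returns the feature index
    subset with the best dev score.  All-constant inputs return a single
    arbitrary feature with a warning.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_dev = np.asarray(X_dev, dtype=float)
    n_features = X_train.shape[1]
    if n_features == 0:
        raise ValueError("no features to select from")
    if np.all(X_train.std(axis=0) == 0):
        warnings.warn("all features constant on train; returning feature 0")
        return np.array([0]), []
    active = np.arange(n_features)
    history = []
    best = (np.inf, active.copy())
    while active.size >= 1:
        est = clone(estimator)
        est.fit(X_train[:, active], y_train)
        score = _dev_score(est, X_dev[:, active], y_dev, task)
        history.append((active.copy(), score))
        if score < best[0]:
            best = (score, active.copy())
        if active.size == 1:
            break
        n_drop = max(1, int(np.floor(step * active.size)))
        ranks = np.argsort(_importances(est))
        active = np.delete(active, ranks[:n_drop])
    return best[1], history


@dataclass
class FoldResult:
    fold: int
    model: str
    params: dict
    selected: list
    metrics: dict
    importances: dict  # feature name -> signed coef or importance


@dataclass
class RunReport:
    task: str
    fold_results: list
    aggregates: pd.DataFrame  # model x metric means over folds
    baselines: dict
    best_model: str

    def results_for(self, model: str) -> list:
        return [r for r in self.fold_results if r.model == model]


def _check_finite(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values "
                         "(impute or drop before modeling)")


def _signed_importances(est, names):
    if hasattr(est, "feature_importances_"):
        vals = est.feature_importances_
    else:
        coef = np.asarray(est.coef_, dtype=float)
        vals = coef if coef.ndim == 1 else np.abs(coef).sum(axis=0)
    return dict(zip(names, (float(v) for v in vals)))


def _pearson(y_true, y_pred) -> float:
    # undefined correlations (constant prediction) are reported as 0
    if np.std(y_pred) == 0 or np.std(y_true) == 0:
        return 0.0
    return float(stats.pearsonr(y_true, y_pred)[0])


def regression_baselines(y_train, y_test) -> dict:
    """Test MAE of predicting the train mean / median."""
    y_train = np.asarray(y_train, float)
    y_test = np.asarray(y_test, float)
    return {
        "mean_baseline_mae": float(np.mean(np.abs(y_test - y_train.mean()))),
        "median_baseline_mae": float(
            np.mean(np.abs(y_test - np.median(y_train)))),
    }


def majority_baseline(y_train, y_test, low_label="low") -> dict:
    """Metrics of always predicting the train-majority class."""
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    classes, counts = np.unique(y_train, return_counts=True)
    majority = classes[np.argmax(counts)]
    pred = np.full(y_test.shape, majority)
    return _classification_metrics(y_test, pred, low_label=low_label)


def _classification_metrics(y_true, y_pred, low_label="low",
                            high_label="high") -> dict:
    labels = np.unique(np.concatenate([y_true, y_pred]))
    out = {
        "f1_macro": float(f1_score(y_true, y_pred, average="macro",
                                   zero_division=0)),
        "f1_weighted": float(f1_score(y_true, y_pred, average="weighted",
                                      zero_division=0)),
    }
    for lab, key in ((low_label, "f1_low"), (high_label, "f1_high")):
        if lab in labels:
            out[key] = float(f1_score(y_true, y_pred, labels=[lab],
                                      average="macro", zero_division=0))
        else:
            out[key] = 0.0
    is_low = y_true == low_label
    pred_low = y_pred == low_label
    out["tpr_low"] = (float(np.sum(pred_low & is_low) / np.sum(is_low))
                      if np.any(is_low) else float("nan"))
    out["fpr_low"] = (float(np.sum(pred_low & ~is_low) / np.sum(~is_low))
                      if np.any(~is_low) else float("nan"))
    return out


def _run_cv(X: pd.DataFrame, y, folds, specs, task: str,
            rfe: bool = True) -> RunReport:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    names = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    _check_finite(Xv)
    y = np.asarray(y)
    fold_results = []
    baseline_rows = []
    for split in folds:
        split.assert_disjoint()
        # standardize per fold (train statistics only) so coefficient
        # magnitudes are comparable across feature families
        scaler = StandardScaler().fit(Xv[split.train])
        Xtr, ytr = scaler.transform(Xv[split.train]), y[split.train]
        Xdev, ydev = scaler.transform(Xv[split.dev]), y[split.dev]
        Xte, yte = scaler.transform(Xv[split.test]), y[split.test]
        if task == "classification":
            if len(np.unique(ytr)) < 2:
                warnings.warn(f"fold {split.index}: train set has a single "
                              "class; fold skipped")
                continue
            baseline_rows.append(majority_baseline(ytr, yte))
        else:
            baseline_rows.append(regression_baselines(ytr, yte))
        for spec in specs:
            # hyperparameters by dev score
            best_params, best_score = {}, np.inf
            for params in spec.candidates():
                est = spec.factory(**params)
                est.fit(Xtr, ytr)
                score = _dev_score(est, Xdev, ydev, task)
                if score < best_score:
                    best_params, best_score = params, score
            est = spec.factory(**best_params)
            if rfe:
                selected, _ = run_rfe(est, Xtr, ytr, Xdev, ydev, task=task)
            else:
                selected = np.arange(Xv.shape[1])
            est = spec.factory(**best_params)
            est.fit(Xtr[:, selected], ytr)
            pred = est.predict(Xte[:, selected])
            if task == "regression":
                yte_f = yte.astype(float)
                metrics = {
                    "mae": float(mean_absolute_error(yte_f, pred)),
                    "pearson_r": _pearson(yte_f, pred),
                    "r2": float(r2_score(yte_f, pred)),
                }
            else:
                metrics = _classification_metrics(yte, pred)
            sel_names = [names[j] for j in selected]
            fold_results.append(FoldResult(
                fold=split.index, model=spec.name, params=best_params,
                selected=sel_names, metrics=metrics,
                importances=_signed_importances(est, sel_names)))
    if not fold_results:
        raise ValueError("no fold produced a result")
    agg = (pd.DataFrame([{"model": r.model, **r.metrics}
                         for r in fold_results])
           .groupby("model").mean())
    baselines = (pd.DataFrame(baseline_rows).mean().to_dict()
                 if baseline_rows else {})
    if task == "regression":
        best_model = agg["mae"].idxmin()
    else:
        best_model = agg["f1_macro"].idxmax()
    return RunReport(task=task, fold_results=fold_results, aggregates=agg,
                     baselines=baselines, best_model=str(best_model))


def cv_regression(X, y, folds, specs=None, rfe: bool = True,
                  random_state: int = 0) -> RunReport:
    """Cross-validated regression over the model families; metrics MAE,
    Pearson r and R², fold-averaged."""
    if specs is None:
        specs = regression_model_specs(random_state)
    return _run_cv(X, np.asarray(y, dtype=float), folds, specs, "regression",
                   rfe=rfe)


def cv_classification(X, y, folds, specs=None, rfe: bool = True,
                      random_state: int = 0) -> RunReport:
    """Cross-validated classification (binary or trinary WHO-5 classes);
    reports F1-macro/weighted, per-class F1 and low-class TPR/FPR."""
    if specs is None:
        specs = classification_model_specs(random_state)
    return _run_cv(X, np.asarray(y), folds, specs, "classification", rfe=rfe)


def stable_features(fold_results, min_folds: int = 5,
                    family_of=None) -> pd.DataFrame:
    """Features selected by RFE in at least ``min_folds`` folds.

    Reports the selection count and the mean coefficient/importance over
    the folds where the feature was selected, optionally grouped by
    feature family.
    """
    counts: dict[str, int] = {}
    sums: dict[str, float] = {}
    for r in fold_results:
        for f in r.selected:
            counts[f] = counts.get(f, 0) + 1
            sums[f] = sums.get(f, 0.0) + r.importances.get(f, 0.0)
    rows = []
    for f, c in counts.items():
        if c >= min_folds:
            rows.append({
                "feature": f,
                "n_folds": c,
                "mean_coefficient": sums[f] / c,
                "family": family_of(f) if family_of else "",
            })
    df = pd.DataFrame(rows, columns=["feature", "n_folds",
                                     "mean_coefficient", "family"])
    return df.sort_values(["family", "n_folds"],
                          ascending=[True, False]).reset_index(drop=True)
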