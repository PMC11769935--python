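"""Seven-algorithm classification bench with repeated 70/30 hold-out and k-fold CV.

Hemangiosarcoma is the positive class throughout; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP) at a fixed score threshold, and AUC is the
probability that a random positive outscores a random negative (ties count
one half).  All stochastic components derive from a single master seed, so
reports are identical across reruns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_ALGORITHMS = ("adaboost", "bagging", "extra_trees", "gradient_boosting",
                      "random_forest", "svm", "xgboost")


@dataclass(frozen=True)
class BenchConfig:
    algorithms: tuple = DEFAULT_ALGORITHMS
    n_repeats: int = 10
    train_fraction: float = 0.7
    k_folds: int = 10
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class ClassificationReport:
    """Mean/sd of AUC, accuracy, sensitivity, specificity per algorithm."""

    scheme: str  # "holdout" or "kfold"
    table: pd.DataFrame  # algorithm, auc, accuracy, sensitivity, specificity + _sd cols

    def metric(self, algorithm: str, name: str) -> float:
        row = self.table.loc[self.table["algorithm"] == algorithm]
        if row.empty:
            raise KeyError(algorithm)
        return float(row.iloc[0][name])


def make_classifier(name: str, seed: int):
    """Instantiate one bench algorithm with a fixed random state."""
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if name == "bagging":
        return BaggingClassifier(random_state=seed)
    if name == "extra_trees":
        return ExtraTreesClassifier(random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear"))
    if name == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, n_estimators=100, n_jobs=1,
                             eval_metric="logloss")
    raise ValueError(f"unknown algorithm {name!r}")


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score: probability when available, else a logistic link
    applied to the decision margin (AUC needs a ranking; accuracy needs a cut)."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    margin = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-margin))


def binary_metrics(labels, scores, threshold: float = 0.5
                   ) -> tuple[float, float, float, float]:
    """(auc, accuracy, sensitivity, specificity) with class 1 positive.

    AUC is the rank statistic P(score_pos > score_neg) with ties worth 0.5.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / n_pos
    specificity = tn / n_neg
    return float(auc), float(accuracy), float(sensitivity), float(specificity)


_METRICS = ("auc", "accuracy", "sensitivity", "specificity")


def _report_from_runs(scheme: str, per_algo: dict[str, list[tuple]]) -> ClassificationReport:
    rows = []
    for algo in per_algo:
        arr = np.array(per_algo[algo])  # runs x 4
        row = {"algorithm": algo}
        for j, m in enumerate(_METRICS):
            row[m] = float(arr[:, j].mean())
            row[f"{m}_sd"] = float(arr[:, j].std(ddof=1)) if len(arr) > 1 else 0.0
        rows.append(row)
    return ClassificationReport(scheme, pd.DataFrame(rows))


def repeated_holdout(matrix: FeatureMatrix, config: BenchConfig = BenchConfig()
                     ) -> ClassificationReport:
    """Stratified 70/30 splits repeated ``n_repeats`` times; metrics averaged."""
    X, y = matrix.values, matrix.labels
    _check_two_classes(y)
    rng = np.random.default_rng(config.seed)
    per_algo: dict[str, list[tuple]] = {a: [] for a in config.algorithms}
    for _ in range(config.n_repeats):
        split_seed = int(rng.integers(2**31))
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, train_size=config.train_fraction, stratify=y,
            random_state=split_seed)
        for algo in config.algorithms:
            model = make_classifier(algo, int(rng.integers(2**31)))
            model.fit(X_tr, y_tr)
            per_algo[algo].append(
                binary_metrics(y_te, _scores(model, X_te), config.threshold))
    return _report_from_runs("holdout", per_algo)


def kfold_cv(matrix: FeatureMatrix, config: BenchConfig = BenchConfig()
             ) -> ClassificationReport:
    """Stratified k-fold CV; out-of-fold scores pooled per algorithm.

    k is reduced (with a warning) when it exceeds the minority-class count.
    """
    X, y = matrix.values, matrix.labels
    _check_two_classes(y)
    if config.k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    k = config.k_folds
    minority = int(np.bincount(y).min())
    if k > minority:
        warnings.warn(f"k={k} exceeds minority-class count {minority}; using k={minority}",
                      stacklevel=2)
        k = minority
    rng = np.random.default_rng(config.seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(rng.integers(2**31)))
    folds = list(skf.split(X, y))
    per_algo: dict[str, list[tuple]] = {}
    for algo in config.algorithms:
        pooled = np.empty(len(y))
        for tr, te in folds:
            model = make_classifier(algo, int(rng.integers(2**31)))
            model.fit(X[tr], y[tr])
            pooled[te] = _scores(model, X[te])
        per_algo[algo] = [binary_metrics(y, pooled, config.threshold)]
    return _report_from_runs("kfold", per_algo)


def _check_two_classes(y: np.ndarray) -> None:
    counts = np.bincount(y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError("need at least two samples per class")
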