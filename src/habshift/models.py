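"""Classifier suite, cross-validated tuning, and evaluation metrics.

Five model families with published default settings are wrapped behind one
predict-probability interface:

* RF — random forest (70 trees, depth 10, sqrt feature subsampling)
* MAXENT_LOGISTIC — L2-penalized logistic regression (C = 0.1, lbfgs).
  Note: this is the penalized-logistic parameterization of "MaxEnt" as used
  in many recent suitability studies, not the Phillips feature-class MaxEnt.
* SVM_LINEAR — linear-kernel SVM (C = 10) with Platt (sigmoid) calibration
  on training folds to obtain probabilities
* GBDT_XGB — gradient boosting via xgboost (lr 0.1, depth 10, 80 rounds,
  colsample 0.8)
* GBDT_LGBM — gradient boosting via lightgbm (lr 0.05, depth 10, 80 rounds,
  31 leaves)

Continuous features are standardized (train statistics) for the logistic
and linear-SVM families; tree families consume raw features. Metrics
(confusion counts, precision/recall/accuracy/F1, rank-statistic AUC) are
computed from first principles.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .occurrences import SampleMatrix

ALGORITHMS = ("RF", "MAXENT_LOGISTIC", "SVM_LINEAR", "GBDT_XGB", "GBDT_LGBM")

DEFAULT_HYPERPARAMETERS: Dict[str, Dict[str, object]] = {
    "RF": {
        "n_estimators": 70,
        "max_depth": 10,
        "max_features": "sqrt",
        "min_samples_split": 2,
        "min_samples_leaf": 4,
    },
    "MAXENT_LOGISTIC": {"C": 0.1, "solver": "lbfgs"},
    "SVM_LINEAR": {"C": 10, "kernel": "linear", "gamma": "scale"},
    "GBDT_XGB": {
        "learning_rate": 0.1,
        "max_depth": 10,
        "n_estimators": 80,
        "subsample": 1.0,
        "colsample_bytree": 0.8,
    },
    "GBDT_LGBM": {
        "learning_rate": 0.05,
        "max_depth": 10,
        "n_estimators": 80,
        "num_leaves": 31,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def resolved_hyperparameters(self) -> Dict[str, object]:
        out = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        out.update(self.hyperparameters)
        return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    model_id: str
    auc: float
    f1: float
    accuracy: float
    precision: float
    recall: float
    confusion: Optional[ConfusionCounts] = None

    def __post_init__(self) -> None:
        for name in ("auc", "f1", "accuracy", "precision", "recall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.precision + self.recall > 0:
            expect = f1_from_precision_recall(self.precision, self.recall)
            if abs(expect - self.f1) > 1e-9:
                raise ValueError("F1 inconsistent with precision/recall")


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank statistic: P(score(presence) > score(absence)),
    ties counted 1/2 (Mann–Whitney)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5, model_id: str = ""
) -> MetricsReport:
    """Confusion-count metrics at the threshold plus rank-statistic AUC.

    Scores >= threshold predict presence (class 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    cc = ConfusionCounts(tp, tn, fp, fn)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    accuracy = (tp + tn) / cc.n if cc.n > 0 else 0.0
    f1 = f1_from_precision_recall(precision, recall)
    auc = rank_auc(scores, labels)
    return MetricsReport(model_id, auc, f1, accuracy, precision, recall, cc)


def metrics_from_confusion(cc: ConfusionCounts, auc: float, model_id: str = "") -> MetricsReport:
    """Recompute threshold metrics from stored confusion counts."""
    precision = cc.tp / (cc.tp + cc.fp) if cc.tp + cc.fp > 0 else 0.0
    recall = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn > 0 else 0.0
    accuracy = (cc.tp + cc.tn) / cc.n if cc.n > 0 else 0.0
    return MetricsReport(
        model_id, auc, f1_from_precision_recall(precision, recall), accuracy, precision, recall, cc
    )


class FittedModel:
    """A fitted estimator plus the variable registry it was trained on."""

    def __init__(self, spec: ModelSpec, estimator, variable_names: Sequence[str]) -> None:
        self.spec = spec
        self.estimator = estimator
        self.variable_names = list(variable_names)

    def predict_proba(self, X) -> np.ndarray:
        """Probability of presence for each row of X (columns = registry order)."""
        import pandas as pd

        frame = pd.DataFrame(np.asarray(X, dtype=float), columns=self.variable_names)
        proba = self.estimator.predict_proba(frame)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(1)]

    def score_samples(self, samples: SampleMatrix) -> np.ndarray:
        return self.predict_proba(samples.features[self.variable_names].to_numpy(dtype=float))


def _build_estimator(spec: ModelSpec, hp: Mapping[str, object]):
    algo, seed = spec.algorithm, spec.seed
    if algo == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if algo == "MAXENT_LOGISTIC":
        clf = LogisticRegression(max_iter=5000, random_state=seed, **hp)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if algo == "SVM_LINEAR":
        svc = SVC(random_state=seed, **hp)
        calibrated = CalibratedClassifierCV(svc, method="sigmoid", cv=5)
        return Pipeline([("scale", StandardScaler()), ("clf", calibrated)])
    if algo == "GBDT_XGB":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **hp,
        )
    if algo == "GBDT_LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbosity=-1, **hp)
    raise ValueError(algo)


def fit_model(spec: ModelSpec, train: SampleMatrix) -> FittedModel:
    """Fit with the spec's (resolved) hyperparameters, no search."""
    hp = spec.resolved_hyperparameters()
    est = _build_estimator(spec, hp)
    est.fit(train.features, train.labels)
    return FittedModel(spec, est, train.variable_names)


def tune_and_fit(
    spec: ModelSpec,
    train: SampleMatrix,
    grid: Optional[Mapping[str, Sequence[object]]] = None,
    k_folds: int = 5,
) -> FittedModel:
    """Exhaustive grid search scored by mean cross-validated rank AUC.

    Ties break toward the first candidate in grid (itertools product)
    order; the winner is refit on the full training set. An empty grid
    fits directly with the spec's defaults.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if not grid:
        return fit_model(spec, train)
    keys = list(grid)
    candidates = [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]
    labels = train.labels
    if np.unique(labels).size < 2:
        raise ValueError("single-class training labels; use stratified folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=spec.seed)
    X = train.features
    best_score, best_hp = -np.inf, None
    for cand in candidates:
        hp = spec.resolved_hyperparameters()
        hp.update(cand)
        fold_aucs = []
        for tr_idx, va_idx in skf.split(X, labels):
            if np.unique(labels[tr_idx]).size < 2 or np.unique(labels[va_idx]).size < 2:
                raise ValueError("fold with a single class; use stratified folds")
            est = _build_estimator(spec, hp)
            est.fit(X.iloc[tr_idx], labels[tr_idx])
            proba = est.predict_proba(X.iloc[va_idx])
            p1 = proba[:, list(est.classes_).index(1)]
            fold_aucs.append(rank_auc(p1, labels[va_idx]))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_score:  # strict: ties keep the earlier candidate
            best_score, best_hp = mean_auc, hp
    final = _build_estimator(spec, best_hp)
    final.fit(X, labels)
    fitted = FittedModel(spec, final, train.variable_names)
    fitted.tuned_hyperparameters = best_hp  # type: ignore[attr-defined]
    return fitted


def select_best_model(reports: List[MetricsReport]) -> str:
    """Winner = highest AUC; ties by F1, then accuracy, then stable order."""
    if not reports:
        raise ValueError("no reports to select from")
    best = max(
        range(len(reports)),
        key=lambda i: (reports[i].auc, reports[i].f1, reports[i].accuracy, -i),
    )
    return reports[best].model_id
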