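"""Collinearity-aware variable selection.

Pairwise Pearson screening at |r| > 0.8 with a random-forest importance
tie-break: all candidates are ranked once by impurity importance, then a
greedy pass over flagged pairs (largest |r| first) drops the lower-importance
member of each pair until no surviving pair exceeds the threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .occurrences import SampleMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrMatrix:
    variable_names: List[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.variable_names)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (p, p):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variable_names, columns=self.variable_names)


@dataclass
class ImportanceRanking:
    """Normalized importance scores; ranks break ties by name order."""

    variable_names: List[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.variable_names):
            raise ValueError("scores/names length mismatch")
        if (self.scores < 0).any():
            raise ValueError("scores must be nonnegative")
        if abs(self.scores.sum() - 1.0) > 1e-9:
            raise ValueError("scores must sum to 1")

    def score_of(self, name: str) -> float:
        return float(self.scores[self.variable_names.index(name)])

    def rank_order(self) -> List[str]:
        """Names in descending score; ties broken by name order."""
        order = sorted(
            range(len(self.variable_names)),
            key=lambda i: (-self.scores[i], self.variable_names[i]),
        )
        return [self.variable_names[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"variable": self.variable_names, "importance": self.scores})
        return df.sort_values("importance", ascending=False, kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SelectionConfig:
    r_threshold: float = 0.8
    seed: int = 0
    n_estimators: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ValueError("r_threshold must be in (0, 1)")


def correlation_matrix(samples: SampleMatrix) -> CorrMatrix:
    """Pearson correlation over all candidate columns.

    Constant columns have undefined correlations; these are recorded as 0
    with a warning (diagonal stays 1).
    """
    if samples.n < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    X = samples.features.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "constant columns in correlation matrix (r set to 0): %s",
            [n for n, c in zip(samples.variable_names, constant) if c],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrMatrix(list(samples.variable_names), r)


def rank_importance(samples: SampleMatrix, cfg: SelectionConfig) -> ImportanceRanking:
    """Impurity-based random-forest importance over all candidates.

    Columns are fitted in canonical (sorted-name) order and scores mapped
    back, so the score assigned to a named variable does not depend on the
    column order of the input table.
    """
    labels = samples.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("binary labels with >= 2 members per class required")
    names = list(samples.variable_names)
    canonical = sorted(names)
    X = samples.features[canonical].to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=cfg.n_estimators, random_state=cfg.seed, n_jobs=1)
    rf.fit(X, labels)
    imp = rf.feature_importances_
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    by_name = dict(zip(canonical, imp))
    scores = np.array([by_name[n] for n in names])
    scores = scores / scores.sum()
    return ImportanceRanking(names, scores)


def resolve_collinearity(
    corr: CorrMatrix, imp: ImportanceRanking, cfg: SelectionConfig
) -> List[str]:
    """Greedy elimination of collinear pairs.

    Repeatedly take the surviving pair with largest |r| above the threshold
    and drop its lower-importance member (importance ties keep the
    name-order-earlier variable); stop when no surviving pair exceeds the
    threshold. Output preserves input name order.
    """
    if set(corr.variable_names) != set(imp.variable_names):
        raise ValueError("correlation and importance cover different variables")
    names = corr.variable_names
    score = {n: imp.score_of(n) for n in names}
    alive = set(names)
    p = len(names)
    pairs = [
        (abs(corr.r[i, j]), names[i], names[j])
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr.r[i, j]) > cfg.r_threshold
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    for _, a, b in pairs:
        if a in alive and b in alive:
            # drop the lower-importance member; ties keep the earlier name
            if (score[a], b) > (score[b], a):
                alive.discard(b)
            else:
                alive.discard(a)
    retained = [n for n in names if n in alive]
    # post-condition certificate
    idx = {n: i for i, n in enumerate(names)}
    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            if abs(corr.r[idx[a], idx[b]]) > cfg.r_threshold:
                raise AssertionError(f"retained pair ({a}, {b}) exceeds |r| threshold")
    return retained


def select_variables(samples: SampleMatrix, cfg: SelectionConfig) -> List[str]:
    """Convenience wrapper: correlation + importance + greedy resolution."""
    corr = correlation_matrix(samples)
    imp = rank_importance(samples, cfg)
    return resolve_collinearity(corr, imp, cfg)
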