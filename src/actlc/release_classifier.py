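"""Random-forest classification of pre-equilibrium reads against an RCP
release threshold, with ROC/AUC evaluation.

A forest is trained on (read time, measured RCP) to predict whether a
set's equilibrium RCP meets the discrimination threshold (0.90 or 0.95).
The predicted probability is the tree-vote fraction; discrimination is
summarized by the ROC curve and its trapezoid AUC on the validation
split, with a seeded stratified-bootstrap 95% confidence interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, confusion_matrix, roc_auc_score, roc_curve

__all__ = [
    "ClassifierSpec",
    "RocResult",
    "FittedClassifier",
    "train_classifier",
    "evaluate_roc",
    "confusion_at_default_cut",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Release-classifier configuration.

    Defaults follow the classic random-forest recipe: 500 trees, one
    candidate feature per split (of the two features), unlimited depth.
    """

    threshold: float = 0.90
    n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_lower: float
    ci_upper: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC outside [0, 1]")


@dataclass
class FittedClassifier:
    spec: ClassifierSpec
    forest: RandomForestClassifier
    feature_names: Tuple[str, str] = ("read_time_h", "measured")

    def scores(self, frame: pd.DataFrame) -> np.ndarray:
        """Tree-vote fraction for the positive (release) class."""
        X = frame[list(self.feature_names)].to_numpy(float)
        return self.forest.predict_proba(X)[:, 1]

    def labels(self, frame: pd.DataFrame) -> np.ndarray:
        return (frame["true_rcp"].to_numpy(float) >= self.spec.threshold).astype(int)


def train_classifier(
    training_frame: pd.DataFrame, spec: ClassifierSpec
) -> FittedClassifier:
    """Train a seeded forest on (read time, measured) with label
    [true RCP >= threshold]."""
    labels = (training_frame["true_rcp"].to_numpy(float) >= spec.threshold).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError(
            f"training labels are single-class at threshold {spec.threshold}"
        )
    X = training_frame[["read_time_h", "measured"]].to_numpy(float)
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=1,
        random_state=spec.seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    return FittedClassifier(spec=spec, forest=forest)


def evaluate_roc(
    classifier: FittedClassifier,
    validation_frame: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve, trapezoid AUC and stratified-bootstrap 95% CI."""
    labels = classifier.labels(validation_frame)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation labels are single-class")
    scores = classifier.scores(validation_frame)
    fpr, tpr, _ = roc_curve(labels, scores)
    point = float(auc(fpr, tpr))
    rng = np.random.default_rng([seed, 17])
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [
                rng.choice(pos, size=len(pos), replace=True),
                rng.choice(neg, size=len(neg), replace=True),
            ]
        )
        stats[b] = roc_auc_score(labels[idx], scores[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        auc=point,
        ci_lower=float(min(lo, point)),
        ci_upper=float(max(hi, point)),
    )


def confusion_at_default_cut(
    classifier: FittedClassifier, validation_frame: pd.DataFrame
) -> Dict[str, float]:
    """Confusion counts and accuracy at the 0.5 vote-fraction cut."""
    labels = classifier.labels(validation_frame)
    pred = (classifier.scores(validation_frame) >= 0.5).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    total = tn + fp + fn + tp
    return {
        "tp": int(tp),
        "fp": int(fp),
        "tn": int(tn),
        "fn": int(fn),
        "n": int(total),
        "accuracy": float((tp + tn) / total),
    }
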