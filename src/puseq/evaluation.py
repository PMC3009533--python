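"""Performance metrics and evaluation protocols.

Only accuracy and sensitivity are provided: with no labeled negatives the
holdout contains positives only, so specificity-style metrics are undefined
and the two provided metrics coincide on a positives-only holdout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import NEGATIVE, POSITIVE, make_classifier
from .datasets import SequenceRecord
from .pu_core import PUModel, Prediction, SpyConfig, predict


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(c: ConfusionCounts) -> float:
    """(tp + tn) / total."""
    if c.total == 0:
        raise ValueError("cannot compute accuracy on zero predictions")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    """tp / (tp + fn), the fraction of true positives predicted positive."""
    if c.tp + c.fn == 0:
        raise ValueError("cannot compute sensitivity with no positive examples")
    return c.tp / (c.tp + c.fn)


@dataclass
class HoldoutResult:
    counts: ConfusionCounts
    sensitivity: float
    predictions: list[Prediction]
    misclassified_ids: list[str] = field(default_factory=list)


def evaluate_holdout(model: PUModel, holdout: Sequence[SequenceRecord]) -> HoldoutResult:
    """Score a positives-only holdout; only sensitivity is meaningful.

    Every holdout example is positive by assumption, so tp counts the
    predicted positives, fn the predicted negatives, and fp = tn = 0.
    """
    if not holdout:
        raise ValueError("holdout must be non-empty")
    preds = predict(model, holdout)
    tp = sum(1 for p in preds if p.label == "positive")
    fn = len(preds) - tp
    counts = ConfusionCounts(tp=tp, fn=fn)
    return HoldoutResult(
        counts=counts,
        sensitivity=sensitivity(counts),
        predictions=preds,
        misclassified_ids=[p.id for p in preds if p.label == "negative"],
    )


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    accuracy: float
    sensitivity: float


@dataclass
class CVResult:
    folds: list[FoldMetrics]
    mean_accuracy: float
    mean_sensitivity: float


def cross_validate(
    p_X: np.ndarray,
    n_X: np.ndarray,
    k: int = 5,
    cfg: SpyConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Seeded stratified k-fold over positives vs negatives."""
    cfg = cfg if cfg is not None else SpyConfig()
    if k < 2:
        raise ValueError("k must be >= 2")
    p_X = np.asarray(p_X, dtype=float)
    n_X = np.asarray(n_X, dtype=float)
    if len(p_X) < k or len(n_X) < k:
        raise ValueError(f"need at least k={k} examples per class")
    X = np.vstack([p_X, n_X])
    y = np.concatenate([np.full(len(p_X), POSITIVE), np.full(len(n_X), NEGATIVE)])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[FoldMetrics] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y), start=1):
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            raise ValueError(f"fold {fold} is single-class")
        clf = make_classifier(cfg.classifier, seed=seed + fold, **cfg.classifier_params)
        clf.fit(X[train_idx], y[train_idx])
        pred = (clf.predict_proba_pos(X[test_idx]) >= 0.5).astype(int)
        truth = y[test_idx]
        counts = ConfusionCounts(
            tp=int(((pred == POSITIVE) & (truth == POSITIVE)).sum()),
            tn=int(((pred == NEGATIVE) & (truth == NEGATIVE)).sum()),
            fp=int(((pred == POSITIVE) & (truth == NEGATIVE)).sum()),
            fn=int(((pred == NEGATIVE) & (truth == POSITIVE)).sum()),
        )
        folds.append(FoldMetrics(fold, accuracy(counts), sensitivity(counts)))
    return CVResult(
        folds=folds,
        mean_accuracy=float(np.mean([f.accuracy for f in folds])),
        mean_sensitivity=float(np.mean([f.sensitivity for f in folds])),
    )
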