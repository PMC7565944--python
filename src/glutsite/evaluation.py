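"""Performance evaluation: confusion metrics, ROC/AUC, cross-validation.

Accuracy, sensitivity and specificity are reported as percentages; MCC in
[-1, 1] and F1 in [0, 1].  Cross-validation is stratified k-fold with
minority oversampling applied inside each training fold only, and headline
metrics come from the pooled out-of-fold predictions (per-fold accuracies
are retained for inspection) — pooling keeps MCC well-defined when folds
are small.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import StratifiedKFold

from glutsite.dataset import DEFAULT_SCALARS, LabeledDataset, oversample_positives
from glutsite.model import ClassifierConfig, predict, train_classifier


@dataclass(frozen=True)
class ConfusionCounts:
    """The four binary confusion counts (positive = glutarylated)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts plus the derived scalar metrics and optional ROC."""

    counts: ConfusionCounts
    acc: float  # percent
    sn: float  # percent (sensitivity / recall)
    sp: float  # percent (specificity)
    mcc: float
    f1: float
    roc_points: tuple[tuple[float, float], ...] = ()  # (fpr, tpr)
    auc: float | None = None
    fold_accuracies: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        d = {
            "counts": asdict(self.counts),
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "f1": self.f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        if self.fold_accuracies:
            d["fold_accuracies"] = list(self.fold_accuracies)
        return d

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_roc_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(path, index=False)


def compute_metrics(counts: ConfusionCounts) -> EvaluationReport:
    """Scalar metrics from confusion counts.

    ACC = 100 (tp + tn) / n, SN = 100 tp / (tp + fn), SP = 100 tn / (tn + fp),
    MCC = (tp tn - fp fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)) with a zero
    denominator mapping to 0, and F1 = 2 PR RE / (PR + RE) with F1 = 0 when
    precision and recall are both zero.  Both classes must be represented.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:
        raise ValueError("no positive samples (tp + fn == 0); metrics undefined")
    if tn + fp == 0:
        raise ValueError("no negative samples (tn + fp == 0); metrics undefined")
    n = tp + fp + tn + fn
    acc = 100.0 * (tp + tn) / n
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    pr = tp / (tp + fp) if tp + fp > 0 else 0.0
    re = tp / (tp + fn)
    f1 = 2 * pr * re / (pr + re) if pr + re > 0 else 0.0
    return EvaluationReport(counts=counts, acc=acc, sn=sn, sp=sp, mcc=mcc, f1=f1)


def roc_auc(
    labels: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float]], float]:
    """ROC curve by descending-score threshold sweep and trapezoidal AUC.

    Ties are grouped at a single threshold step, so the AUC equals the
    Mann-Whitney statistic (probability that a random positive outscores a
    random negative, ties counted one half).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _roc_curve(labels, scores)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_trapezoid_auc(fpr, tpr))


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> EvaluationReport:
    """Full report (metrics plus ROC/AUC when scores are supplied)."""
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    report = compute_metrics(counts)
    if scores is not None:
        points, area = roc_auc(y_true, scores)
        report = EvaluationReport(
            **{**report.__dict__, "roc_points": tuple(points), "auc": area}
        )
    return report


def cross_validate(
    data: LabeledDataset,
    k: int = 10,
    seed: int = 0,
    config: ClassifierConfig | None = None,
    scalars: Sequence[float] = DEFAULT_SCALARS,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with in-fold oversampling.

    Oversampling is applied to the training folds only; the held-out fold
    is scored untouched.  Pooled out-of-fold predictions give the headline
    report; per-fold accuracies are attached for inspection.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    counts = np.bincount(data.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} members for {k}-fold CV; class counts {counts.tolist()}"
        )
    if data.augmented.any():
        raise ValueError("cross_validate expects un-augmented data")
    config = config or ClassifierConfig()
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_pred = np.empty(len(data), dtype=int)
    oof_score = np.empty(len(data), dtype=float)
    fold_accs = []
    for train_idx, test_idx in skf.split(data.features, data.labels):
        train = data.subset(train_idx)
        if scalars:
            train = oversample_positives(train, scalars)
        model = train_classifier(train, config)
        pred, score = predict(model, data.features[test_idx])
        oof_pred[test_idx] = pred
        oof_score[test_idx] = score
        fold_accs.append(float((pred == data.labels[test_idx]).mean() * 100.0))
    report = evaluate_predictions(data.labels, oof_pred, oof_score)
    return EvaluationReport(
        **{**report.__dict__, "fold_accuracies": tuple(fold_accs)}
    )
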