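"""Validation protocols and confusion-matrix statistics.

Three protocols quantify the influence of recording context on activity
recognition: within-context 10-fold cross-validation on lab data,
training on lab and testing on home data, and within-context 10-fold
cross-validation on home data.  Folds are stratified by activity over the
pooled clips ("within-subject": one subject's clips may land in both the
training and the test folds).

All derived statistics (overall accuracy, per-class recall/precision,
macro averages, binomial confidence intervals, merged-class accuracy) are
computed from a :class:`ConfusionMatrix` with rows = true activities and
columns = predicted activities, class order (lie, stand, sit, wheel,
walk, stairs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classifiers import ClassifierSpec, predict, stratified_fold_indices, train
from .features import FeatureDataset
from .signal_io import ACTIVITIES


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = true classes, columns = predicted."""

    counts: np.ndarray
    classes: tuple[str, ...] = ACTIVITIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for classes {self.classes}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {"classes": list(self.classes), "counts": self.counts.tolist()}

    @classmethod
    def from_predictions(
        cls,
        true: Sequence[str],
        predicted: Sequence[str],
        classes: Sequence[str] = ACTIVITIES,
    ) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(true, predicted, strict=True):
            counts[index[t], index[p]] += 1
        return cls(counts, tuple(classes))


@dataclass(frozen=True)
class BinomialCI:
    """A binomial proportion with its two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    method: str
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.point <= self.upper <= 1.0:
            raise ValueError("CI bounds must satisfy 0 <= lower <= point <= upper <= 1")


def _classes_for(data: FeatureDataset) -> tuple[str, ...]:
    present = set(data.labels)
    if present <= set(ACTIVITIES):
        return tuple(c for c in ACTIVITIES if c in present) if present != set(ACTIVITIES) else ACTIVITIES
    return tuple(sorted(present))


def kfold_cv(
    data: FeatureDataset,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
) -> ConfusionMatrix:
    """Stratified k-fold cross-validation over pooled clips.

    Each clip is predicted exactly once, by the model trained on the other
    folds; the accumulated confusion matrix is returned.  Deterministic
    given ``seed``.
    """
    assignment = stratified_fold_indices(data.labels, folds, seed)
    true: list[str] = []
    pred: list[str] = []
    for f in range(folds):
        test_idx = np.flatnonzero(assignment == f)
        train_idx = np.flatnonzero(assignment != f)
        model = train(spec, data.subset(train_idx))
        pred.extend(predict(model, data.subset(test_idx)))
        true.extend(data.labels[i] for i in test_idx)
    return ConfusionMatrix.from_predictions(true, pred, _classes_for(data))


def cross_context(
    train_data: FeatureDataset,
    test_data: FeatureDataset,
    spec: ClassifierSpec,
) -> ConfusionMatrix:
    """Single train on all training rows, single evaluation on all test rows."""
    shared = set(train_data.contexts) & set(test_data.contexts)
    if shared:
        warnings.warn(
            f"train and test share context tag(s) {sorted(shared)}; "
            "cross-context evaluation expects disjoint contexts",
            stacklevel=2,
        )
    model = train(spec, train_data)
    pred = predict(model, test_data)
    classes = _classes_for(train_data) if set(test_data.labels) <= set(train_data.labels) else tuple(
        sorted(set(train_data.labels) | set(test_data.labels))
    )
    return ConfusionMatrix.from_predictions(test_data.labels, pred, classes)


def accuracy(cm: ConfusionMatrix, total_override: int | None = None) -> float:
    """trace / total; ``total_override`` allows a stated denominator when
    recomputing published tables."""
    total = cm.total if total_override is None else int(total_override)
    if total <= 0:
        raise ValueError("total must be positive")
    return float(np.trace(cm.counts)) / total


def per_class_recall(cm: ConfusionMatrix) -> np.ndarray:
    """Diagonal over row sums; NaN marks zero-support (undefined) classes."""
    row = cm.counts.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.diag(cm.counts) / row
    return np.where(row > 0, out, np.nan)


def per_class_precision(cm: ConfusionMatrix) -> np.ndarray:
    col = cm.counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.diag(cm.counts) / col
    return np.where(col > 0, out, np.nan)


def macro_recall(cm: ConfusionMatrix) -> float:
    """Unweighted mean recall over classes with defined recall."""
    r = per_class_recall(cm)
    if np.all(np.isnan(r)):
        raise ValueError("no class has defined recall")
    return float(np.nanmean(r))


def macro_precision(cm: ConfusionMatrix) -> float:
    p = per_class_precision(cm)
    if np.all(np.isnan(p)):
        raise ValueError("no class has defined precision")
    return float(np.nanmean(p))


def binomial_ci(
    correct: int,
    total: int,
    method: str = "clopper_pearson",
    level: float = 0.95,
) -> BinomialCI:
    """Two-sided binomial CI for an accuracy: exact Clopper-Pearson
    (beta-quantile) or normal-approximation (Wald)."""
    if not (0 <= correct <= total) or total <= 0:
        raise ValueError(f"invalid counts correct={correct}, total={total}")
    p = correct / total
    alpha = 1.0 - level
    if method == "clopper_pearson":
        lower = 0.0 if correct == 0 else float(stats.beta.ppf(alpha / 2, correct, total - correct + 1))
        upper = 1.0 if correct == total else float(
            stats.beta.ppf(1 - alpha / 2, correct + 1, total - correct)
        )
    elif method == "normal":
        zcrit = float(stats.norm.ppf(1 - alpha / 2))
        half = zcrit * np.sqrt(p * (1 - p) / total)
        lower, upper = max(0.0, p - half), min(1.0, p + half)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return BinomialCI(point=p, lower=lower, upper=upper, method=method, level=level)


def merge_classes(
    cm: ConfusionMatrix,
    groups: Sequence[Sequence[str]] | Mapping[str, Sequence[str]],
) -> ConfusionMatrix:
    """Sum rows/columns within groups (a partition of the class labels).

    Merging confusable classes can only move off-diagonal mass onto the
    diagonal, so accuracy never decreases.  Singleton groups keep their
    label; merged groups are labelled by joining members with '+'.
    """
    if isinstance(groups, Mapping):
        named = [(str(k), tuple(v)) for k, v in groups.items()]
    else:
        named = [("+".join(g), tuple(g)) for g in groups]
    flat = [c for _, members in named for c in members]
    if sorted(flat) != sorted(cm.classes):
        raise ValueError(f"groups must partition the classes {cm.classes}")
    index = {c: i for i, c in enumerate(cm.classes)}
    k = len(named)
    counts = np.zeros((k, k), dtype=np.int64)
    for gi, (_, gmembers) in enumerate(named):
        for gj, (_, hmembers) in enumerate(named):
            rows = [index[c] for c in gmembers]
            cols = [index[c] for c in hmembers]
            counts[gi, gj] = cm.counts[np.ix_(rows, cols)].sum()
    return ConfusionMatrix(counts, tuple(name for name, _ in named))


def format_percent(fraction: float) -> str:
    """One-decimal percentage with half-up rounding, e.g. 0.91624 -> '91.6%'."""
    q = Decimal(repr(fraction * 100)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def metrics_report(
    cm: ConfusionMatrix,
    ci_method: str = "clopper_pearson",
    total_override: int | None = None,
) -> dict:
    """All derived statistics for one confusion matrix, JSON-serialisable."""
    acc = accuracy(cm, total_override)
    total = cm.total if total_override is None else int(total_override)
    ci = binomial_ci(int(np.trace(cm.counts)), total, method=ci_method)
    recalls = per_class_recall(cm)
    precisions = per_class_precision(cm)

    def listify(arr: np.ndarray) -> list:
        return [None if np.isnan(v) else float(v) for v in arr]

    return {
        "confusion": cm.to_dict(),
        "accuracy": acc,
        "accuracy_pct": format_percent(acc),
        "ci": {
            "method": ci.method,
            "level": ci.level,
            "lower": ci.lower,
            "upper": ci.upper,
        },
        "per_class_recall": dict(zip(cm.classes, listify(recalls))),
        "per_class_precision": dict(zip(cm.classes, listify(precisions))),
        "macro_recall": macro_recall(cm),
        "macro_precision": macro_precision(cm),
    }


def render_confusion(cm: ConfusionMatrix) -> str:
    """Aligned text table, rows = true activities, columns = predicted."""
    width = max(6, max(len(c) for c in cm.classes) + 1)
    header = "true\\pred".ljust(width) + "".join(c.rjust(width) for c in cm.classes)
    lines = [header]
    for i, c in enumerate(cm.classes):
        lines.append(c.ljust(width) + "".join(str(v).rjust(width) for v in cm.counts[i]))
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
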