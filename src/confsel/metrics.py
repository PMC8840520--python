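"""Confusion counts, accuracy/sensitivity/specificity, ROC/AUC, F1.

Accuracy is reported as a percent in [0, 100]; sensitivity and specificity
as ratios in [0, 1].  Degenerate denominators (a test set with no positives
or no negatives) yield ``None`` rather than a silent 0 or NaN.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from confsel.exceptions import MetricError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN cells for one classifier on one test set."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise MetricError(f"negative count {name}")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassMetrics:
    """Accuracy (percent), sensitivity and specificity (ratios).

    ``None`` marks an undefined ratio (zero denominator).
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None


@dataclass(frozen=True)
class RocCurve:
    """ROC points swept over descending unique scores, with trapezoidal AUC."""

    fpr: tuple[float, ...]
    tpr: tuple[float, ...]
    thresholds: tuple[float, ...]
    auc: float


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion cells for binary label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise MetricError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise MetricError(f"{name} contains values outside {{0,1}}: {bad}")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    """Accuracy = 100*(TP+TN)/N, Se = TP/(TP+FN), Sp = TN/(TN+FP).

    Full precision is retained; any display rounding is the caller's
    responsibility.  Zero-denominator ratios come back as ``None``.
    """
    if c.n == 0:
        raise MetricError("empty confusion matrix (N=0)")
    se = c.tp / c.n_positive if c.n_positive > 0 else None
    sp = c.tn / c.n_negative if c.n_negative > 0 else None
    return ClassMetrics(
        accuracy=100.0 * (c.tp + c.tn) / c.n,
        sensitivity=se,
        specificity=sp,
    )


def roc_auc(y_true, scores) -> RocCurve:
    """ROC curve and trapezoidal AUC from real-valued scores.

    The threshold sweeps the unique scores in descending order; a point is
    emitted per threshold (prediction: score >= threshold), preceded by
    (0,0) and necessarily ending at (1,1).  The trapezoidal AUC equals the
    normalized Mann-Whitney U statistic with ties counted half.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise MetricError("length mismatch between labels and scores")
    n1 = int(np.sum(y_true == 1))
    n0 = int(np.sum(y_true == 0))
    if n1 == 0 or n0 == 0:
        raise MetricError("ROC requires both classes in y_true")
    order = np.argsort(-scores, kind="stable")
    ys = y_true[order]
    ss = scores[order]
    # cumulative counts at each unique-score boundary
    distinct = np.r_[np.flatnonzero(np.diff(ss)), ss.size - 1]
    cum_tp = np.cumsum(ys == 1)[distinct]
    cum_fp = np.cumsum(ys == 0)[distinct]
    tpr = np.r_[0.0, cum_tp / n1]
    fpr = np.r_[0.0, cum_fp / n0]
    thresholds = np.r_[np.inf, ss[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(
        fpr=tuple(fpr.tolist()),
        tpr=tuple(tpr.tolist()),
        thresholds=tuple(thresholds.tolist()),
        auc=auc,
    )


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 for the positive class: 2*TP / (2*TP + FP + FN)."""
    if min(tp, fp, fn) < 0:
        raise MetricError("negative count")
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise MetricError("F1 undefined: TP+FP+FN == 0")
    return 2.0 * tp / denom


def write_roc_csv(curve: RocCurve, path) -> None:
    """Write ROC points as a two-column CSV (fpr, tpr)."""
    from pathlib import Path

    lines = ["fpr,tpr"]
    lines += [f"{f!r},{t!r}" for f, t in zip(curve.fpr, curve.tpr)]
    Path(path).write_text("\n".join(lines) + "\n")


def metrics_report(c: ConfusionCounts, **extra) -> str:
    """Flat JSON report of counts plus derived metrics."""
    m = class_metrics(c)
    payload = {**asdict(c), "n": c.n, **asdict(m), **extra}
    return json.dumps(payload, indent=2)
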