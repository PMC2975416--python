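"""Classifier performance measures and the pooled cross-validation protocol.

Conventions used throughout:

* labels are +1 (positive, increased stability) / -1 (negative, decreased);
* percentages (AC, SN, SP, ST) are carried at full precision and rounded
  (round-half-even) only when a report is rendered;
* sensitivity is undefined when there are no true positives+false negatives,
  specificity when there are no true negatives+false positives — undefined
  is reported as ``None``, never silently as 0;
* MCC with a zero denominator factor is defined as 0;
* cross-validation metrics are computed once on the pooled out-of-fold
  predictions, not averaged across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .dataset import Dataset
from .encoding import EncodingSpec, encode_dataset
from .scales import ScaleRegistry


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts for +/-1 label vectors (positive = stabilizing)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise MetricsError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise MetricsError("empty label vectors")
    bad = set(np.unique(np.concatenate([y_true, y_pred]))) - {-1, 1}
    if bad:
        raise MetricsError(f"labels must be +/-1, found {sorted(bad)}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(c: ConfusionCounts) -> float:
    """Overall accuracy, percent."""
    return 100.0 * (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float | None:
    """True positive rate, percent; ``None`` when no actual positives."""
    denom = c.tp + c.fn
    return None if denom == 0 else 100.0 * c.tp / denom


def specificity(c: ConfusionCounts) -> float | None:
    """True negative rate, percent; ``None`` when no actual negatives."""
    denom = c.tn + c.fp
    return None if denom == 0 else 100.0 * c.tn / denom


def prediction_strength(sn: float, sp: float) -> float:
    """The average of sensitivity and specificity (both in percent).

    The balanced summary measure preferred for imbalanced data: unlike
    overall accuracy it is not dominated by the majority class.
    """
    return (sn + sp) / 2.0


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    factors = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if 0 in factors:
        return 0.0
    denom = float(np.sqrt(np.prod([float(f) for f in factors])))
    return num / denom


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    fpr: float
    tpr: float


def roc_curve(scores: np.ndarray, y_true: np.ndarray) -> list[RocPoint]:
    """ROC sweep over the classifier score threshold.

    A point is emitted for every distinct score value (predicting positive
    when ``score >= threshold``), plus the all-negative endpoint at
    ``threshold = +inf``.  Tied scores move together, so the curve's last
    point is always (1, 1) and both coordinates are non-decreasing.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.shape != y_true.shape:
        raise MetricsError("scores and labels differ in length")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == -1))
    if n_pos == 0 or n_neg == 0:
        raise MetricsError("ROC needs both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = y_true[order]
    points = [RocPoint(float("inf"), 0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(s_sorted)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            if y_sorted[j] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append(RocPoint(float(s_sorted[i]), fp / n_neg, tp / n_pos))
        i = j
    return points


def auc(points: list[RocPoint]) -> float:
    """Trapezoidal area under a ROC point list.

    With tied scores grouped, this equals the Mann-Whitney pair statistic
    with ties counted 1/2 (checked against brute-force pair counting in the
    test suite).
    """
    x = np.array([p.fpr for p in points])
    y = np.array([p.tpr for p in points])
    return float(np.trapezoid(y, x))


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    return auc(roc_curve(scores, y_true))


@dataclass
class EvalReport:
    """Confusion counts and the full suite of performance measures for one
    evaluation run (threshold-0 predictions plus the ROC sweep)."""

    counts: ConfusionCounts
    ac: float
    sn: float | None
    sp: float | None
    st: float | None
    mcc: float
    auc: float
    roc_points: list[RocPoint] = field(repr=False, default_factory=list)
    n: int = 0

    @classmethod
    def from_scores(cls, scores: np.ndarray, y_true: np.ndarray) -> "EvalReport":
        """Build a report from decision values: class calls at threshold 0
        (a score of exactly 0 counts as positive), ROC over the full sweep."""
        scores = np.asarray(scores, dtype=float)
        y_true = np.asarray(y_true)
        y_pred = np.where(scores >= 0, 1, -1)
        c = confusion(y_true, y_pred)
        sn = sensitivity(c)
        sp = specificity(c)
        st = None if sn is None or sp is None else prediction_strength(sn, sp)
        pts = roc_curve(scores, y_true)
        return cls(
            counts=c,
            ac=accuracy(c),
            sn=sn,
            sp=sp,
            st=st,
            mcc=mcc(c),
            auc=auc(pts),
            roc_points=pts,
            n=c.total,
        )

    def to_row(self) -> dict:
        """Rendered row with percentages at 2 decimals (round-half-even)."""

        def r2(v):
            return None if v is None else round(v, 2)

        return {
            "AC": r2(self.ac),
            "SN": r2(self.sn),
            "SP": r2(self.sp),
            "ST": r2(self.st),
            "MCC": None if self.mcc is None else round(self.mcc, 4),
            "AUC": round(self.auc, 4),
            "n": self.n,
        }

    def to_json(self) -> dict:
        d = self.to_row()
        d["counts"] = {
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
        }
        return d

    def roc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.threshold, p.fpr, p.tpr) for p in self.roc_points],
            columns=["threshold", "FPR", "TPR"],
        )


def stratified_folds(
    y: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; per-class fold sizes differ by <= 1."""
    y = np.asarray(y)
    for cls in (1, -1):
        if int(np.sum(y == cls)) < k:
            raise MetricsError(
                f"class {cls:+d} has fewer than k={k} members"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [
        (train, test) for train, test in skf.split(np.zeros(len(y)), y)
    ]


def crossvalidate(
    dataset: Dataset,
    spec: EncodingSpec,
    cfg,
    registry: ScaleRegistry,
    k: int = 5,
    seed: int | None = None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> tuple[EvalReport, pd.DataFrame]:
    """Combined-fold k-fold cross-validation.

    Instances of each class are randomly distributed into ``k`` folds
    (stratified, seeded); each fold is scored by a classifier trained on the
    other ``k - 1``; all out-of-fold decision values are pooled and the
    metrics are computed once on the pooled predictions.  Returns the report
    and a per-instance table (index, fold, score, label) — the pooled pairs
    feed the confidence calibration.

    ``X``/``y`` may be passed to skip re-encoding (used by the subset
    search); they must match the dataset's order.
    """
    from .model import train_svc  # local import to avoid cycle

    if X is None or y is None:
        X, y = encode_dataset(dataset, spec, registry)
    if seed is None:
        seed = cfg.seed
    scores = np.empty(len(y), dtype=float)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(stratified_folds(y, k, seed)):
        svc = train_svc(X[train_idx], y[train_idx], cfg)
        scores[test_idx] = svc.decision_function(X[test_idx])
        fold_of[test_idx] = fold
    report = EvalReport.from_scores(scores, y)
    table = pd.DataFrame(
        {"index": np.arange(len(y)), "fold": fold_of, "score": scores, "label": y}
    )
    return report, table
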