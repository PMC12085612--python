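"""Confusion matrix, one-vs-rest classification metrics, overlap scores,
ROC/AUC and report assembly.

For a K-class problem each class c is reduced one-vs-rest to
TP = cm[c, c], FN = (row c) - TP, FP = (column c) - TP, TN = the rest,
from which

    ACC  = (TP + TN) / (TP + FP + TN + FN)
    PREC = TP / (TP + FP)
    SPEC = TN / (TN + FP)
    SEN  = TP / (TP + FN)
    F1   = 2 TP / (2 TP + FP + FN)

Segmentation overlap per foreground class uses the Dice coefficient
2|A∩B|/(|A|+|B|) and the Jaccard index |A∩B|/|A∪B|; the empty-vs-empty
case is defined as 1 (flagged).  AUC is the trapezoidal area under the
one-vs-rest ROC curve.  Report values are rounded to 2 decimals,
half-up.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_curve


@dataclass
class ConfusionMatrix:
    """K x K count table; rows = actual class, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be >= 0")

    @classmethod
    def from_predictions(
        cls, truths: np.ndarray, preds: np.ndarray, n_classes: int
    ) -> "ConfusionMatrix":
        truths = np.asarray(truths, dtype=np.int64)
        preds = np.asarray(preds, dtype=np.int64)
        counts = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(counts, (truths, preds), 1)
        return cls(counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def one_vs_rest_counts(cm: ConfusionMatrix, class_id: int) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) for one class of a multiclass confusion matrix."""
    k = cm.counts.shape[0]
    if not (0 <= class_id < k):
        raise IndexError(f"class_id {class_id} out of range for {k} classes")
    tp = int(cm.counts[class_id, class_id])
    fn = int(cm.counts[class_id].sum()) - tp
    fp = int(cm.counts[:, class_id].sum()) - tp
    tn = cm.total - tp - fn - fp
    return tp, fp, tn, fn


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    f1: float
    #: names of metrics whose denominator was zero (reported as 0)
    undefined: tuple[str, ...] = ()


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassificationMetrics:
    """The five confusion-matrix rates; 0/0 ratios reported as 0, flagged."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be >= 0")
    undefined = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    return ClassificationMetrics(
        accuracy=ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        precision=ratio(tp, tp + fp, "precision"),
        specificity=ratio(tn, tn + fp, "specificity"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        f1=ratio(2 * tp, 2 * tp + fp + fn, "f1"),
        undefined=tuple(undefined),
    )


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def segmentation_scores(
    pred: np.ndarray, truth: np.ndarray, classes: range | list[int] = range(1, 6)
) -> dict[int, tuple[float, float]]:
    """Per-class (Dice, IoU) between two label maps.

    Empty-vs-empty is defined as (1.0, 1.0).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    out = {}
    for k in classes:
        a = pred == k
        b = truth == k
        inter = float(np.logical_and(a, b).sum())
        sa, sb = float(a.sum()), float(b.sum())
        union = sa + sb - inter
        if sa + sb == 0:
            out[k] = (1.0, 1.0)
        else:
            dice = 2.0 * inter / (sa + sb)
            iou = inter / union if union else 1.0
            out[k] = (dice, iou)
    return out


def macro_mean(values) -> float:
    """Unweighted arithmetic mean of per-class metric values."""
    values = list(values)
    if not values:
        raise ValueError("macro_mean of an empty list")
    return float(np.mean(values))


def round_report(value: float, decimals: int = 2) -> float:
    """Round half-up to the report precision (2 decimals)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def roc_auc(scores: np.ndarray, truths: np.ndarray) -> dict[int, float]:
    """One-vs-rest AUC per class by trapezoidal integration of the ROC.

    ``scores`` is (N, K) class probabilities (or any monotone scores),
    ``truths`` the true class indices.  A class without both positives
    and negatives gets ``nan``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.int64)
    out = {}
    for k in range(scores.shape[1]):
        pos = truths == k
        if pos.all() or not pos.any():
            out[k] = float("nan")
            continue
        fpr, tpr, _ = roc_curve(pos.astype(int), scores[:, k])
        out[k] = float(np.trapezoid(tpr, fpr))
    return out


def auc_pair_count(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counted half.  Independent oracle for ``roc_auc``."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def icc_2_1(ratings: np.ndarray) -> float:
    """Two-way random, single-measure intraclass correlation ICC(2,1).

    ``ratings`` is (n_subjects, n_raters).  Provided as an extra
    agreement statistic; not validated against any external value.
    """
    x = np.asarray(ratings, dtype=np.float64)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs at least 2 subjects and 2 raters")
    mean_subj = x.mean(axis=1, keepdims=True)
    mean_rater = x.mean(axis=0, keepdims=True)
    grand = x.mean()
    msr = k * ((mean_subj - grand) ** 2).sum() / (n - 1)
    msc = n * ((mean_rater - grand) ** 2).sum() / (k - 1)
    mse = ((x - mean_subj - mean_rater + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return float(
        (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    )


@dataclass
class MetricsReport:
    """Per-class metrics plus macro means, as printed in evaluation
    reports (2 decimals, half-up)."""

    class_names: list[str]
    confusion: list[list[int]]
    per_class: dict[str, dict[str, float]]
    macro_dice: float
    macro_iou: float

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text


def build_report(
    truths: np.ndarray,
    preds: np.ndarray,
    scores: np.ndarray,
    seg_dice: dict[str, float],
    seg_iou: dict[str, float],
    class_names: list[str],
) -> MetricsReport:
    """Assemble the full evaluation report from predictions.

    ``seg_dice`` / ``seg_iou`` are per-class segmentation overlaps
    (per-slice averages).  Per-class rows carry both one-vs-rest
    accuracy and recall, labeled distinctly, because a per-class
    "accuracy" column is ambiguous.
    """
    k = len(class_names)
    cm = ConfusionMatrix.from_predictions(truths, preds, k)
    aucs = roc_auc(scores, truths)
    per_class = {}
    for i, name in enumerate(class_names):
        m = classification_metrics(*one_vs_rest_counts(cm, i))
        per_class[name] = {
            "ovr_accuracy": round_report(m.accuracy),
            "precision": round_report(m.precision),
            "recall": round_report(m.sensitivity),
            "specificity": round_report(m.specificity),
            "f1": round_report(m.f1),
            "auc": round_report(aucs[i]) if np.isfinite(aucs[i]) else float("nan"),
            "dice": round_report(seg_dice.get(name, float("nan")))
            if np.isfinite(seg_dice.get(name, float("nan")))
            else float("nan"),
            "iou": round_report(seg_iou.get(name, float("nan")))
            if np.isfinite(seg_iou.get(name, float("nan")))
            else float("nan"),
        }
    finite_d = [v for v in seg_dice.values() if np.isfinite(v)]
    finite_i = [v for v in seg_iou.values() if np.isfinite(v)]
    return MetricsReport(
        class_names=list(class_names),
        confusion=cm.counts.tolist(),
        per_class=per_class,
        macro_dice=round_report(macro_mean(finite_d)) if finite_d else float("nan"),
        macro_iou=round_report(macro_mean(finite_i)) if finite_i else float("nan"),
    )
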