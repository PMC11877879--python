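"""Confusion matrices and sensitivity/specificity/balanced accuracy reporting.

The headline multiclass metric is the unweighted mean of per-class recall
(the diagonal of the row-normalized confusion matrix): on class-balanced
designs it coincides with pooled sample accuracy, and on unbalanced data it
does not reward majority-class guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .datamodel import DataError


def confusion_matrix(truth, pred, classes) -> np.ndarray:
    """Counts matrix with truth in rows, prediction in columns."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    classes = list(classes)
    if truth.size != pred.size:
        raise DataError("truth and prediction vectors differ in length")
    unknown = (set(truth) | set(pred)) - set(classes)
    if unknown:
        raise DataError(f"labels {sorted(unknown)} not in class list {classes}")
    return _sk_confusion(truth, pred, labels=classes)


def row_percentages(cm: np.ndarray) -> np.ndarray:
    """Row-normalized view in percent; empty rows stay zero."""
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(sums > 0, 100.0 * cm / sums, 0.0)
    return pct


def sens_spec_acc(cm: np.ndarray, positive_index: int = 0) -> tuple[float, float, float]:
    """Sensitivity, specificity and balanced accuracy (percent) of a 2x2 matrix.

    On the class-balanced design the balanced accuracy (Se+Sp)/2 equals the
    per-class mean recall.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (2, 2):
        raise DataError("sens_spec_acc requires a 2x2 counts matrix")
    p = positive_index
    n = 1 - p
    if cm[p].sum() == 0 or cm[n].sum() == 0:
        raise DataError("empty positive or negative row: metric undefined")
    se = 100.0 * cm[p, p] / cm[p].sum()
    sp = 100.0 * cm[n, n] / cm[n].sum()
    return se, sp, (se + sp) / 2.0


def multiclass_accuracy(cm_row_pct: np.ndarray) -> float:
    """Unweighted mean of diagonal row-percentages, rounded to integer percent."""
    cm_row_pct = np.asarray(cm_row_pct, dtype=float)
    if cm_row_pct.ndim != 2 or cm_row_pct.shape[0] != cm_row_pct.shape[1]:
        raise DataError("row-percentage matrix must be square")
    return float(round(np.mean(np.diag(cm_row_pct))))


#: Class ordering by increasing pathological severity, used for tie-breaking
#: and for choosing the positive class of a binary pair.
SEVERITY_ORDER = ("H", "AK", "CNI", "BCC", "KC", "CI", "SCC")


def more_pathological(a: str, b: str) -> str:
    """The more severe of two class labels (unknown labels rank lowest)."""
    def rank(c):
        return SEVERITY_ORDER.index(c) if c in SEVERITY_ORDER else -1
    return a if rank(a) >= rank(b) else b


@dataclass
class PerformanceReport:
    classes: list[str]
    confusion: np.ndarray
    accuracy_pct: float
    repeat_accuracies_pct: list[float] = field(default_factory=list)
    se_pct: float | None = None
    sp_pct: float | None = None

    @property
    def confusion_row_pct(self) -> np.ndarray:
        return row_percentages(self.confusion)

    @property
    def repeat_sd_pct(self) -> float:
        if not self.repeat_accuracies_pct:
            return 0.0
        return float(np.std(self.repeat_accuracies_pct, ddof=0))

    def to_dict(self) -> dict:
        d = {
            "classes": self.classes,
            "confusion_counts": self.confusion.tolist(),
            "confusion_row_pct": np.round(self.confusion_row_pct, 1).tolist(),
            "accuracy_pct": self.accuracy_pct,
            "repeat_accuracies_pct": self.repeat_accuracies_pct,
            "repeat_sd_pct": self.repeat_sd_pct,
        }
        if self.se_pct is not None:
            d["se_pct"] = self.se_pct
            d["sp_pct"] = self.sp_pct
        return d


def performance_report(truth, pred, classes, repeats=None) -> PerformanceReport:
    """Build a report from pooled predictions (optionally tagged by repeat)."""
    classes = list(classes)
    cm = confusion_matrix(truth, pred, classes)

    def balanced_acc(counts: np.ndarray) -> float:
        # mean per-class recall over the classes actually present
        present = counts.sum(axis=1) > 0
        return float(np.mean(np.diag(row_percentages(counts))[present]))

    acc = balanced_acc(cm)
    rep_accs: list[float] = []
    if repeats is not None:
        truth = np.asarray(truth)
        pred = np.asarray(pred)
        repeats = np.asarray(repeats)
        for r in np.unique(repeats):
            m = repeats == r
            rep_accs.append(balanced_acc(confusion_matrix(truth[m], pred[m], classes)))
    se = sp = None
    if len(classes) == 2 and np.all(cm.sum(axis=1) > 0):
        pos = more_pathological(classes[0], classes[1])
        se, sp, acc = sens_spec_acc(cm, positive_index=classes.index(pos))
    return PerformanceReport(
        classes=classes,
        confusion=cm,
        accuracy_pct=acc,
        repeat_accuracies_pct=rep_accs,
        se_pct=se,
        sp_pct=sp,
    )
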