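"""Confusion matrices and the imbalance-aware multiclass metric suite.

Per class (one-vs-rest counts TP/FP/TN/FN):

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

"All classes" rows are support-weighted averages of precision,
sensitivity and specificity; the aggregate F1 is the harmonic mean of
the weighted precision and weighted sensitivity.  Weighted sensitivity
equals overall accuracy by the support-weighting identity.  Percentages
are reported to 2 decimals.

The multiclass Matthews correlation coefficient defaults to the
Gorodkin R_K statistic computed from the full K x K matrix; a
support-weighted binary variant is available behind a flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_ORDER = ("N", "S", "V", "F", "Q")


@dataclass
class ConfusionMatrix:
    """K x K integer counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_order: tuple = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_order),
                            columns=list(self.class_order))


def confusion_matrix(true_labels, predicted_labels,
                     class_order=CLASS_ORDER) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    k = len(class_order)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(class_order))


def _binary_counts(cm: ConfusionMatrix):
    c = cm.counts.astype(np.float64)
    tp = np.diag(c)
    fn = c.sum(axis=1) - tp
    fp = c.sum(axis=0) - tp
    tn = c.sum() - tp - fn - fp
    return tp, fp, tn, fn


def _safe_div(num, den, what):
    out = np.zeros_like(num, dtype=float)
    bad = den == 0
    if np.any(bad):
        logger.warning("%s undefined (0/0) for %d class(es); reported as 0",
                       what, int(bad.sum()))
    np.divide(num, den, out=out, where=~bad)
    return out


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class precision/sensitivity/specificity/F1, in percent."""
    tp, fp, tn, fn = _binary_counts(cm)
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    specificity = _safe_div(tn, tn + fp, "specificity")
    f1 = _safe_div(2 * precision * sensitivity, precision + sensitivity, "F1")
    return pd.DataFrame(
        {"f1": 100 * f1, "precision": 100 * precision,
         "sensitivity": 100 * sensitivity, "specificity": 100 * specificity},
        index=list(cm.class_order))


def weighted_metrics(cm: ConfusionMatrix, f1_mode="harmonic") -> dict:
    """Support-weighted aggregate metrics plus overall accuracy (percent).

    ``f1_mode``: "harmonic" (harmonic mean of the weighted precision and
    weighted sensitivity — the convention the per-strategy result tables
    follow) or "weighted" (support-weighted mean of per-class F1).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    per = per_class_metrics(cm)
    w = cm.supports / cm.total
    wp = float(w @ per["precision"])
    ws = float(w @ per["sensitivity"])
    wsp = float(w @ per["specificity"])
    accuracy = 100.0 * np.trace(cm.counts) / cm.total
    # support-weighting identity: weighted sensitivity == accuracy
    assert abs(ws - accuracy) < 1e-9
    if f1_mode == "harmonic":
        wf1 = 2 * wp * ws / (wp + ws) if wp + ws > 0 else 0.0
    elif f1_mode == "weighted":
        wf1 = float(w @ per["f1"])
    else:
        raise ValueError(f"unknown f1_mode {f1_mode!r}")
    return {"f1": wf1, "precision": wp, "sensitivity": ws,
            "specificity": wsp, "accuracy": accuracy}


def multiclass_mcc(cm: ConfusionMatrix, variant="gorodkin") -> float:
    """Multiclass Matthews correlation coefficient in [-1, 1].

    "gorodkin": the R_K covariance statistic over the full matrix
    (default).  "weighted_binary": support-weighted mean of the per-class
    one-vs-rest binary MCCs.  Returns 0 when a denominator vanishes.
    """
    c = cm.counts.astype(np.float64)
    if variant == "gorodkin":
        s = c.sum()
        trace = np.trace(c)
        t = c.sum(axis=1)  # true supports
        p = c.sum(axis=0)  # predicted supports
        num = trace * s - p @ t
        den = np.sqrt(s * s - p @ p) * np.sqrt(s * s - t @ t)
        return float(num / den) if den > 0 else 0.0
    if variant == "weighted_binary":
        tp, fp, tn, fn = _binary_counts(cm)
        den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        mcc = np.where(den > 0, (tp * tn - fp * fn) / np.where(den > 0, den, 1),
                       0.0)
        w = cm.supports / cm.total
        return float(w @ mcc)
    raise ValueError(f"unknown MCC variant {variant!r}")


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics for one strategy/model."""

    cm: ConfusionMatrix
    per_class: pd.DataFrame = field(init=False)
    weighted: dict = field(init=False)
    mcc: float = field(init=False)

    def __post_init__(self):
        self.per_class = per_class_metrics(self.cm)
        self.weighted = weighted_metrics(self.cm)
        self.mcc = multiclass_mcc(self.cm)

    def to_frame(self) -> pd.DataFrame:
        """Table layout: per-class rows plus an 'All classes' row."""
        rows = self.per_class.round(2)
        agg = {k: round(v, 2) for k, v in self.weighted.items()
               if k != "accuracy"}
        all_row = pd.DataFrame([agg], index=["All classes"])
        return pd.concat([rows, all_row])

    def to_json(self) -> str:
        return json.dumps({
            "confusion_matrix": self.cm.counts.tolist(),
            "class_order": list(self.cm.class_order),
            "per_class": self.per_class.round(2).to_dict(orient="index"),
            "weighted": {k: round(v, 2) for k, v in self.weighted.items()},
            "mcc": round(self.mcc, 4),
        }, indent=2)
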