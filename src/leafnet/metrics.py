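"""Classification metric suite: confusion matrix, accuracy, per-class and
macro precision/recall/F1, average precision (area under the
precision–recall curve) and mAP, plus a wall-clock throughput probe.

Multi-class accuracy is trace/total of the confusion matrix (the
one-vs-rest micro-averaged reading of the binary definition); precision,
recall and F1 are computed one-vs-rest per class and macro-averaged
without weighting.  AP uses the non-interpolated step estimator of the
PR-curve integral: items sorted by descending score (ties broken by item
index, stable), summing precision at each positive's rank.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ConfusionMatrix:
    """Rows are true classes, columns predicted (canonical ordering)."""

    counts: np.ndarray
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        if not self.class_names:
            self.class_names = [str(i) for i in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int):
        """(TP, FP, FN, TN) for class i."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum()) - tp
        fn = int(self.counts[i, :].sum()) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mAP: float | None = None
    fps: float | None = None
    class_names: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }
        if self.mAP is not None:
            d["mAP"] = self.mAP
        if self.fps is not None:
            d["fps"] = self.fps
        for i, name in enumerate(self.class_names):
            d[f"precision_{name}"] = float(self.precision[i])
            d[f"recall_{name}"] = float(self.recall[i])
            d[f"f1_{name}"] = float(self.f1[i])
        return d


def confusion(true_labels, predicted_labels, n_classes: int | None = None,
              class_names: list | None = None) -> ConfusionMatrix:
    """Count matrix: counts[i, j] = #(true class i, predicted class j)."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label arrays differ in length: {t.shape} vs {p.shape}")
    k = n_classes or (len(class_names) if class_names else int(max(t.max(initial=0), p.max(initial=0))) + 1)
    if ((t < 0) | (t >= k) | (p < 0) | (p >= k)).any():
        raise ValueError(f"labels outside the {k}-class set")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(counts, class_names or [])


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 defined as 0", RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, per-class and macro precision/recall/F1 from a matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.counts.shape[0]
    precision = np.zeros(k)
    recall = np.zeros(k)
    f1 = np.zeros(k)
    for i in range(k):
        tp, fp, fn, _ = cm.one_vs_rest(i)
        precision[i] = _safe_div(tp, tp + fp, f"precision[{cm.class_names[i]}]")
        recall[i] = _safe_div(tp, tp + fn, f"recall[{cm.class_names[i]}]")
        f1[i] = _safe_div(2 * precision[i] * recall[i], precision[i] + recall[i],
                          f"f1[{cm.class_names[i]}]")
    return MetricsReport(
        accuracy=float(np.trace(cm.counts) / cm.total),
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        class_names=cm.class_names,
    )


def average_precision(scores, binary_labels) -> float:
    """Step-estimator AP for one class.

    Sort by descending score (stable, so score ties resolve by item
    index), then average the precision observed at each positive's rank.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(binary_labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    order = np.argsort(-scores, kind="stable")
    hits = labels[order]
    cum_tp = np.cumsum(hits)
    ranks = np.arange(1, len(scores) + 1)
    return float((cum_tp[hits] / ranks[hits]).sum() / n_pos)


def mean_ap(probabilities, true_labels) -> float:
    """Unweighted mean of one-vs-rest APs over the class columns.

    probabilities: [N, K] per-class scores; classes with no positive
    items are excluded with a warning.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(true_labels, dtype=np.int64)
    aps = []
    for c in range(probs.shape[1]):
        pos = t == c
        if not pos.any():
            warnings.warn(f"class {c} has no positives; excluded from mAP", RuntimeWarning,
                          stacklevel=2)
            continue
        aps.append(average_precision(probs[:, c], pos))
    if not aps:
        raise ValueError("no class has positive items")
    return float(np.mean(aps))


def evaluate_model(model, ds, class_names: list | None = None) -> MetricsReport:
    """Full report (incl. mAP) for a fitted model on a labeled dataset."""
    probs = model.predict_proba(ds.images)
    cm = confusion(ds.labels, probs.argmax(axis=1), n_classes=probs.shape[1],
                   class_names=class_names)
    report = classification_metrics(cm)
    report.mAP = mean_ap(probs, ds.labels)
    return report


def measure_fps(model, images, n: int | None = None) -> float:
    """Wall-clock classification throughput (images/second); hardware-
    dependent, reported for information only."""
    if n is None:
        n = len(images)
    if n < 1:
        raise ValueError("need at least one image")
    batch = [images[i % len(images)] for i in range(n)]
    start = time.perf_counter()
    model.predict(batch)
    elapsed = time.perf_counter() - start
    return n / max(elapsed, 1e-12)
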