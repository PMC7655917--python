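"""Pixel-wise segmentation metrics: accuracy (ACC), positive predictive
value (PPV), Jaccard similarity (JS) and Dice coefficient (DC).

All four derive from the pixel confusion counts of a binary prediction
against a binary ground truth:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    PPV = TP / (TP + FP)
    JS  = TP / (TP + FP + FN)
    DC  = 2 TP / (2 TP + FP + FN)

DC and JS are linked by the identity DC = 2 JS / (1 + JS).  Zero-denominator
conventions: an empty prediction compared with an empty truth is vacuously
perfect (score 1.0); empty versus non-empty scores 0.0.  Dataset-level
aggregation is macro (mean of per-slice metrics) by default, with pooled
(micro) counts available by summing ConfusionCounts before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    acc: float
    ppv: float
    js: float
    dc: float


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isin(arr, [0, 1])):
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(bool)


def confusion(prediction: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel confusion counts of a binary prediction against a binary truth."""
    pred = _check_binary(prediction, "prediction")
    true = _check_binary(truth, "truth")
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    acc = (tp + tn) / total if total else 1.0
    ppv = tp / (tp + fp) if (tp + fp) else (1.0 if fn == 0 else 0.0)
    denom = tp + fp + fn
    js = tp / denom if denom else 1.0
    dc = 2 * tp / (2 * tp + fp + fn) if denom else 1.0
    return MetricReport(acc=acc, ppv=ppv, js=js, dc=dc)


def binarize(probability_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map (>= threshold -> 1)."""
    p = np.asarray(probability_map)
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return (p >= threshold).astype(np.uint8)


def dice(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Convenience: Dice coefficient of two binary images."""
    return compute_metrics(confusion(prediction, truth)).dc


def evaluate_slices(predictions, truths, average: str = "macro"):
    """Score a sequence of slices.

    Returns ``(per_slice: DataFrame, summary: MetricReport)``.  ``macro``
    averages the per-slice metrics; ``micro`` scores the pooled counts.
    """
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")
    rows = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for i, (pred, true) in enumerate(zip(predictions, truths)):
        counts = confusion(pred, true)
        pooled = pooled + counts
        rep = compute_metrics(counts)
        rows.append({"slice": i, "acc": rep.acc, "ppv": rep.ppv,
                     "js": rep.js, "dc": rep.dc})
    table = pd.DataFrame(rows)
    if average == "macro":
        summary = MetricReport(*(float(table[k].mean()) for k in ("acc", "ppv", "js", "dc")))
    else:
        summary = compute_metrics(pooled)
    return table, summary
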