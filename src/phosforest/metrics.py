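"""Binary-classification evaluation: confusion counts, Ac/Sn/Sp/MCC, ROC/AUC.

Labels and calls live in {+1, -1}.  The scalar metrics are

    Ac  = (TP + TN) / (TP + FN + FP + TN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TP+FP)(TN+FP)(TP+FN))

with MCC defined as 0 when any denominator factor vanishes.  The ROC
curve plots Sn against 1 - Sp over every distinct score threshold and
AUC is its trapezoidal area, which (with half credit for ties) equals
the Mann-Whitney probability that a positive outscores a negative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve


def confusion(labels: Sequence[int], calls: Sequence[int]) -> tuple[int, int, int, int]:
    """Exhaustive disjoint counts (TP, TN, FP, FN) over {+1, -1} vectors."""
    labels = np.asarray(labels)
    calls = np.asarray(calls)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must have equal length")
    for name, v in (("labels", labels), ("calls", calls)):
        bad = set(np.unique(v)) - {1, -1}
        if bad:
            raise ValueError(f"{name} contain values outside {{+1,-1}}: {sorted(bad)}")
    tp = int(np.sum((labels == 1) & (calls == 1)))
    tn = int(np.sum((labels == -1) & (calls == -1)))
    fp = int(np.sum((labels == -1) & (calls == 1)))
    fn = int(np.sum((labels == 1) & (calls == -1)))
    return tp, tn, fp, fn


def scalar_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """(Ac, Sn, Sp, MCC) from confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all counts are zero")
    ac = (tp + tn) / total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tn + fn) * (tp + fp) * (tn + fp) * (tp + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return ac, sn, sp, mcc


def roc_auc(labels: Sequence[int], scores: Sequence[float]):
    """ROC points (1-Sp, Sn) at every score threshold and trapezoidal AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(np.unique(labels)) - {1, -1}) > 0:
        raise ValueError("labels must be +1/-1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class EvalResult:
    """Full evaluation of thresholded calls plus the score-based ROC."""

    TP: int
    TN: int
    FP: int
    FN: int
    Ac: float
    Sn: float
    Sp: float
    MCC: float
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    AUC: float = float("nan")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("TP", "TN", "FP", "FN", "Ac", "Sn", "Sp", "MCC", "AUC")}
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_roc_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in self.roc_points:
                fh.write(f"{x:.6g}\t{y:.6g}\n")


def evaluate(
    labels: Sequence[int],
    calls: Sequence[int],
    scores: Sequence[float] | None = None,
) -> EvalResult:
    """Confusion counts + scalar metrics, with ROC/AUC when scores are given."""
    tp, tn, fp, fn = confusion(labels, calls)
    ac, sn, sp, mcc = scalar_metrics(tp, tn, fp, fn)
    points: list[tuple[float, float]] = []
    auc = float("nan")
    if scores is not None:
        points, auc = roc_auc(labels, scores)
    return EvalResult(tp, tn, fp, fn, ac, sn, sp, mcc, points, auc)
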