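"""ROC/AUC machinery, implemented from first principles.

Two independent routes to the AUC are provided: the trapezoidal area under
the empirical ROC curve, and the Mann-Whitney pair-counting statistic
(concordant pairs plus half the tied pairs, over all positive x negative
pairs). They agree to floating-point precision on any input, which every
evaluation in this package relies on as an internal consistency check.

Convention: label 1 = pass, and higher scores mean "more likely pass".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

__all__ = ["ROCResult", "roc_curve", "auc_mann_whitney", "UndefinedMetricError"]


class UndefinedMetricError(ValueError):
    """Raised when the ROC is undefined (only one class present)."""


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    if labels.min() == labels.max():
        raise UndefinedMetricError("ROC requires both classes present")
    return scores, labels


@dataclass
class ROCResult:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "thresholds": [None if np.isinf(t) else t for t in self.thresholds],
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "auc": self.auc,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve with trapezoidal AUC.

    Thresholds are the distinct score values in descending order (tied
    scores collapse to one operating point), preceded by +inf so the curve
    starts at (0, 0); it ends at (1, 1) by construction.
    """
    scores, labels = _validate(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = int(y.sum())
    n_neg = y.size - n_pos

    # cumulative counts at each position; keep only the last index of each
    # tied block so ties form a single operating point
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    last_of_block = np.r_[s[1:] != s[:-1], True]
    tp, fp, thr = tp[last_of_block], fp[last_of_block], s[last_of_block]

    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, thr]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic scaled to [0, 1].

    (concordant pairs + tied pairs / 2) / (n_pos * n_neg), computed from
    mid-ranks; ties receive half credit.
    """
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
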