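"""Confusion-matrix metrics for panel evaluation.

Conventions: the disease arm (LAC, or LAC+BENIGN for the combined
contrast) is the positive class; a sample scoring exactly at the decision
threshold is called negative. Undefined ratios (e.g. PPV with no positive
calls) are flagged as None, never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .roc import auc as _auc


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and derived rates of one dichotomized prediction set.

    sen = tp/(tp+fn), spe = tn/(tn+fp), fpr = 1-spe, fnr = 1-sen,
    ppv = tp/(tp+fp) (None when undefined), npv = tn/(tn+fn) (None when
    undefined); ``auc`` is the area under the ROC of the continuous
    scores when available.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float | None = None

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")
        if self.tp + self.fn == 0 or self.tn + self.fp == 0:
            raise ParameterError("both classes must be present (tp+fn>0, tn+fp>0)")

    @property
    def sen(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def spe(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def fpr(self) -> float:
        return 1.0 - self.spe

    @property
    def fnr(self) -> float:
        return 1.0 - self.sen

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return None if d == 0 else self.tp / d

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return None if d == 0 else self.tn / d

    @property
    def ppv_undefined(self) -> bool:
        return self.tp + self.fp == 0

    @property
    def npv_undefined(self) -> bool:
        return self.tn + self.fn == 0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sen": self.sen, "spe": self.spe,
            "ppv": self.ppv, "npv": self.npv,
            "fpr": self.fpr, "fnr": self.fnr,
            "auc": self.auc,
        }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int,
                      auc: float | None = None) -> ConfusionMetrics:
    """Build :class:`ConfusionMetrics` from raw counts."""
    return ConfusionMetrics(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn), auc=auc)


def evaluate_panel(decision_values, labels, threshold: float) -> ConfusionMetrics:
    """Dichotomize decision values at ``threshold`` and score the result.

    ``score > threshold`` is a positive (disease) call; the AUC of the
    continuous decision values is attached alongside the threshold-bound
    rates.
    """
    scores = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not np.isfinite(threshold):
        raise ParameterError("threshold must be finite")
    calls = scores > threshold
    tp = int(np.sum(calls & y))
    fp = int(np.sum(calls & ~y))
    tn = int(np.sum(~calls & ~y))
    fn = int(np.sum(~calls & y))
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, auc=_auc(scores, y))
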