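"""ROC analysis and per-pair marker selection.

A pair's score is its oriented ratio (disease-positive direction), so on
the data used for orientation the AUC is >= 0.5 by construction. Curves
are built over tie-grouped operating points: one cutpoint between each
run of equal scores, a sample counting positive when its score is
strictly above the cutpoint. The trapezoidal area of that curve equals
the Mann-Whitney U statistic scaled by n1*n2, with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateLabelsError


@dataclass(frozen=True)
class RocCurve:
    """Operating points of one score vector: parallel threshold/fpr/tpr arrays.

    Points run from (0, 0) (threshold above every score) to (1, 1);
    ``thresholds`` are midpoints between adjacent distinct scores, with
    +/-inf at the ends. Classification rule: score > threshold is positive.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have identical shape")
    keep = np.isfinite(scores)
    scores, labels = scores[keep], labels[keep]
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels) -> RocCurve:
    """Build the ROC curve of continuous scores against binary labels."""
    scores, labels = _validate(scores, labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    npos, nneg = int(y.sum()), int((~y).sum())

    # group ties: indices where a new distinct score starts
    distinct = np.r_[True, s[1:] != s[:-1]]
    starts = np.flatnonzero(distinct)
    ends = np.r_[starts[1:], s.size]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    tpr = np.r_[0.0, tp[ends - 1] / npos]
    fpr = np.r_[0.0, fp[ends - 1] / nneg]

    uniq = s[starts]
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.r_[np.inf, mids, -np.inf]
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area)


def auc(scores, labels) -> float:
    """Area under the ROC curve; equals P(score_pos > score_neg) + ties/2."""
    return roc_curve(scores, labels).auc


def youden_threshold(curve: RocCurve) -> tuple[float, float, float]:
    """Operating point maximizing Youden's J = TPR - FPR.

    Ties in J are broken toward higher specificity (lower FPR); returns
    ``(threshold, sensitivity, specificity)``.
    """
    j = curve.tpr - curve.fpr
    best = np.flatnonzero(j == j.max())
    k = best[np.argmin(curve.fpr[best])]
    return float(curve.thresholds[k]), float(curve.tpr[k]), float(1.0 - curve.fpr[k])


def auc_many(features: pd.DataFrame, pos_mask, neg_mask) -> np.ndarray:
    """Rank-based AUC of every column at once (NaNs dropped pairwise).

    Uses the Mann-Whitney identity AUC = (R_pos - n_pos(n_pos+1)/2) /
    (n_pos * n_neg) with midranks, column-vectorized via scipy rankdata.
    """
    from scipy.stats import rankdata

    arr = features.to_numpy()
    out = np.empty(arr.shape[1])
    pos_mask = np.asarray(pos_mask, bool)
    neg_mask = np.asarray(neg_mask, bool)
    both = pos_mask | neg_mask
    sub = arr[both]
    y = pos_mask[both]
    nan_cols = np.isnan(sub).any(axis=0)
    clean = ~nan_cols
    if clean.any():
        ranks = rankdata(sub[:, clean], axis=0)
        n1 = y.sum()
        n2 = (~y).sum()
        r1 = ranks[y].sum(axis=0)
        out[clean] = (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)
    for j in np.flatnonzero(nan_cols):  # per-column pairwise deletion
        col = sub[:, j]
        keep = np.isfinite(col)
        out[j] = auc(col[keep], y[keep])
    return out


def add_roc_stats(
    stats_table: pd.DataFrame,
    features: pd.DataFrame,
    pos_mask,
    neg_mask,
) -> pd.DataFrame:
    """Fill auc/sensitivity/specificity/threshold per pair (oriented score).

    Oriented score of pair a/b is the stored feature value times the
    orientation sign, so disease-like samples score high.
    """
    out = stats_table.copy()
    arr = features.to_numpy()
    colpos = {c: i for i, c in enumerate(features.columns)}
    pos_mask = np.asarray(pos_mask, bool)
    neg_mask = np.asarray(neg_mask, bool)
    both = pos_mask | neg_mask
    y = pos_mask[both]
    aucs, sens, spes, thrs = [], [], [], []
    for _, row in out.iterrows():
        raw = arr[both, colpos[row["feature_id"]]]
        flipped = row["pair_id"] != row["feature_id"]
        score = -raw if flipped else raw
        keep = np.isfinite(score)
        curve = roc_curve(score[keep], y[keep])
        t, sen, spe = youden_threshold(curve)
        aucs.append(curve.auc)
        sens.append(sen)
        spes.append(spe)
        thrs.append(t)
    out["auc"] = aucs
    out["sensitivity"] = sens
    out["specificity"] = spes
    out["threshold"] = thrs
    return out


def select_markers(
    stats_table: pd.DataFrame,
    sen_min: float = 0.80,
    spe_min: float = 0.80,
    auc_min: float = 0.800,
) -> pd.DataFrame:
    """Keep pairs strictly exceeding all three ROC criteria."""
    keep = (
        (stats_table["sensitivity"] > sen_min)
        & (stats_table["specificity"] > spe_min)
        & (stats_table["auc"] > auc_min)
    )
    return stats_table.loc[keep].reset_index(drop=True)
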