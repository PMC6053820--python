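"""SVM-RFE ranking, panel assembly, and cross-validated panel performance.

Features (pair ratios) are ranked by recursive feature elimination driven
by a linear-kernel support vector machine: at each step the classifier is
refit on the surviving features (standardized to zero mean / unit
variance) and the feature with the smallest squared weight is eliminated;
rank 1 is the last survivor. A panel is a rank-prefix of features plus the
classifier refit on the full training set; its performance is estimated
from pooled out-of-fold decision values of a stratified k-fold (k = 10 by
default) cross-validation, with the operating threshold chosen by
Youden's J on those pooled values and then carried unchanged to any
validation cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import (
    DegenerateLabelsError,
    MissingFeatureError,
    ParameterError,
)
from .metrics import ConfusionMetrics, evaluate_panel
from .roc import roc_curve, youden_threshold

DEFAULT_C = 1.0


def _as_xy(features: pd.DataFrame, labels) -> tuple[np.ndarray, np.ndarray]:
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes must be present")
    if not np.isfinite(X).all():
        raise ParameterError("feature matrix must be finite (impute or drop NaNs)")
    return X, y


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    safe = np.where(scale == 0.0, 1.0, scale)
    return (X - mean) / safe, mean, scale


def svm_rfe_rank(features: pd.DataFrame, labels, C: float = DEFAULT_C) -> list[str]:
    """Rank features by SVM recursive feature elimination.

    Returns feature (pair) ids best-first. One feature is removed per
    iteration; ties in squared weight are broken by eliminating the
    lexicographically larger id first, so the ranking is deterministic.
    Constant features carry zero weight after standardization and fall out
    first, with a warning.
    """
    X, y = _as_xy(features, labels)
    if X.shape[1] < 1:
        raise ParameterError("need at least one feature")
    cols = list(features.columns)
    const = [c for c, s in zip(cols, X.std(axis=0)) if s == 0.0]
    if const:
        warnings.warn(f"constant feature(s) ranked last: {const[:5]}", stacklevel=2)

    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while len(remaining) > 1:
        Z, _, _ = _standardize(X[:, remaining])
        clf = SVC(kernel="linear", C=C)
        clf.fit(Z, y)
        w2 = np.ravel(clf.coef_) ** 2
        worst = np.min(w2)
        tied = [remaining[i] for i in np.flatnonzero(np.isclose(w2, worst))]
        drop = max(tied, key=lambda i: cols[i])
        eliminated.append(drop)
        remaining.remove(drop)
    order = remaining + eliminated[::-1]  # best first
    return [cols[i] for i in order]


@dataclass
class Panel:
    """A fitted ratio-pair panel: ranked pairs + linear classifier + threshold."""

    pair_ids: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    weights: np.ndarray
    intercept: float
    threshold: float
    C: float = DEFAULT_C
    kernel: str = "linear"
    cv_decision: pd.Series | None = field(default=None, repr=False)
    cv_metrics: ConfusionMetrics | None = None

    @property
    def size(self) -> int:
        return len(self.pair_ids)


def cross_validate_panel(
    features: pd.DataFrame,
    labels,
    k: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> pd.Series:
    """Pooled out-of-fold decision values from stratified k-fold CV.

    Each fold's classifier is trained on the other k-1 folds only, with
    standardization constants computed from those training folds, so no
    sample contributes to its own decision value. If the smaller class has
    fewer than k members, k is reduced with a warning.
    """
    X, y = _as_xy(features, labels)
    if k < 2:
        raise ParameterError("k must be >= 2")
    smallest = min(int(y.sum()), int((~y).sum()))
    if smallest < k:
        warnings.warn(f"reducing k from {k} to {smallest} (class size)", stacklevel=2)
        k = smallest
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dec = np.empty(len(y))
    for train, test in skf.split(X, y):
        Z, mean, scale = _standardize(X[train])
        safe = np.where(scale == 0.0, 1.0, scale)
        clf = SVC(kernel="linear", C=C)
        clf.fit(Z, y[train])
        dec[test] = clf.decision_function((X[test] - mean) / safe)
    return pd.Series(dec, index=features.index, name="cv_decision")


def build_panel(
    ranked: list[str],
    features: pd.DataFrame,
    labels,
    size: int | str = "auto",
    k: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
    max_size: int | None = None,
) -> Panel:
    """Assemble a panel from a rank-prefix and fit the final classifier.

    ``size="auto"`` scans prefixes 1..max_size (or all) and keeps the
    smallest prefix maximizing the pooled-CV AUC; an integer takes that
    prefix directly. The final classifier is refit on all training
    samples; the confusion threshold is Youden's J on the pooled CV
    decision values of the chosen prefix.
    """
    X, y = _as_xy(features[ranked], labels)
    n_avail = len(ranked)
    if isinstance(size, str):
        if size != "auto":
            raise ParameterError("size must be an integer or 'auto'")
        limit = n_avail if max_size is None else min(max_size, n_avail)
        best_auc, best_s, best_dec = -np.inf, None, None
        for s in range(1, limit + 1):
            dec = cross_validate_panel(features[ranked[:s]], y, k=k, seed=seed, C=C)
            curve = roc_curve(dec.to_numpy(), y)
            if curve.auc > best_auc + 1e-12:
                best_auc, best_s, best_dec = curve.auc, s, dec
        size = best_s
        cv_dec = best_dec
    else:
        if not 1 <= size <= n_avail:
            raise ParameterError(f"panel size {size} outside 1..{n_avail}")
        cv_dec = cross_validate_panel(features[ranked[:size]], y, k=k, seed=seed, C=C)

    chosen = list(ranked[:size])
    Z, mean, scale = _standardize(features[chosen].to_numpy(dtype=float))
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z, y)

    curve = roc_curve(cv_dec.to_numpy(), y)
    thr, _, _ = youden_threshold(curve)
    cv_metrics = evaluate_panel(cv_dec.to_numpy(), y, thr)
    return Panel(
        pair_ids=chosen,
        scaler_mean=mean,
        scaler_scale=scale,
        weights=np.ravel(clf.coef_).copy(),
        intercept=float(clf.intercept_[0]),
        threshold=float(thr),
        C=C,
        cv_decision=cv_dec,
        cv_metrics=cv_metrics,
    )


def apply_panel(panel: Panel, features: pd.DataFrame) -> pd.Series:
    """Decision values of the training-fitted panel on a cohort (no refit)."""
    missing = [p for p in panel.pair_ids if p not in features.columns]
    if missing:
        raise MissingFeatureError(f"cohort lacks panel pair(s): {missing}")
    X = features[panel.pair_ids].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ParameterError("cohort features must be finite for panel application")
    safe = np.where(panel.scaler_scale == 0.0, 1.0, panel.scaler_scale)
    Z = (X - panel.scaler_mean) / safe
    dec = Z @ panel.weights + panel.intercept
    return pd.Series(dec, index=features.index, name="decision")


def save_panel(panel: Panel, path) -> None:
    """Serialize a panel to portable YAML (no pickles)."""
    doc = {
        "pair_ids": list(panel.pair_ids),
        "scaler_mean": [float(v) for v in panel.scaler_mean],
        "scaler_scale": [float(v) for v in panel.scaler_scale],
        "weights": [float(v) for v in panel.weights],
        "intercept": float(panel.intercept),
        "threshold": float(panel.threshold),
        "C": float(panel.C),
        "kernel": panel.kernel,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_panel(path) -> Panel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Panel(
        pair_ids=list(doc["pair_ids"]),
        scaler_mean=np.asarray(doc["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(doc["scaler_scale"], dtype=float),
        weights=np.asarray(doc["weights"], dtype=float),
        intercept=float(doc["intercept"]),
        threshold=float(doc["threshold"]),
        C=float(doc.get("C", DEFAULT_C)),
        kernel=doc.get("kernel", "linear"),
    )
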