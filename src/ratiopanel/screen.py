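"""Per-pair two-group differential screen.

Each candidate feature is a pair's per-sample log2-scale ratio (dCT).
Groups are compared with a two-sample t-test (Student's equal-variance by
default, Welch optional), p-values are corrected for the hundreds of
thousands of pairs tested (Benjamini-Hochberg step-up by default,
Bonferroni optional), and candidates are kept when the fold change is at
least ``fc_min`` and the corrected p-value is at most ``q_max``.

Pairs are reported *oriented*: the member order is flipped where needed so
the contrast RATIO is non-negative, matching the convention of reporting
only positively oriented ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError
from .ratios import pair_id, split_pair_id

_CORRECTIONS = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}


def pair_t_test(x, y, variant: str = "student") -> float:
    """Two-sided two-sample t-test p-value on log2-scale ratio values.

    Degenerate zero-variance inputs are resolved deterministically:
    identical group means give p = 1, different means with zero pooled
    variance give p = 0 (an infinitely confident t statistic).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ParameterError("each group needs at least 2 values")
    if variant not in ("student", "welch"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return 1.0 if x.mean() == y.mean() else 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.pvalue)


def adjust_pvalues(p, method: str = "benjamini_hochberg") -> np.ndarray:
    """Multiple-testing adjustment, input order preserved.

    ``benjamini_hochberg`` is the step-up FDR procedure with enforced
    monotonicity; ``bonferroni`` multiplies by the number of tests
    (clipped at 1).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ParameterError("p-values must lie in [0, 1]")
    if method not in _CORRECTIONS:
        raise ParameterError(f"unknown correction {method!r}")
    return multipletests(p, method=_CORRECTIONS[method])[1]


def screen_pairs(
    features: pd.DataFrame,
    pos_mask: np.ndarray,
    neg_mask: np.ndarray,
    variant: str = "student",
    correction: str = "benjamini_hochberg",
) -> pd.DataFrame:
    """Vectorized differential screen of every pair feature for one contrast.

    ``features`` is the sample × pair dCT matrix; ``pos_mask``/``neg_mask``
    select the contrast's disease-like (X) and reference (Y) samples.
    Returns one row per pair with columns ``pair_id, numerator, denominator,
    p_value, p_adjusted, ratio, fold_change``, oriented so ratio >= 0.
    Samples with missing values are dropped pairwise per feature.
    """
    X = features.to_numpy()[pos_mask, :]
    Y = features.to_numpy()[neg_mask, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(X, Y, equal_var=(variant == "student"),
                              nan_policy="omit", axis=0)
        pvals = np.asarray(res.pvalue, dtype=float)
        ratio = np.nanmean(X, axis=0) - np.nanmean(Y, axis=0)
    # zero-variance degeneracies: identical means -> 1, else -> 0
    bad = ~np.isfinite(pvals)
    if bad.any():
        pvals[bad] = np.where(np.isclose(ratio[bad], 0.0), 1.0, 0.0)
    padj = adjust_pvalues(pvals, correction)

    pids = [split_pair_id(c) for c in features.columns]
    num = np.array([p[0] for p in pids], dtype=object)
    den = np.array([p[1] for p in pids], dtype=object)
    flip = ratio < 0
    num[flip], den[flip] = den[flip].copy(), num[flip].copy()
    ratio = np.abs(ratio)
    out = pd.DataFrame(
        {
            "pair_id": [pair_id(a, b) for a, b in zip(num, den)],
            "numerator": num,
            "denominator": den,
            "p_value": pvals,
            "p_adjusted": padj,
            "ratio": ratio,
            "fold_change": 2.0 ** ratio,
        }
    )
    out["feature_id"] = list(features.columns)  # pre-orientation column key
    return out


def select_candidates(
    stats_table: pd.DataFrame, fc_min: float = 2.0, q_max: float = 0.05
) -> pd.DataFrame:
    """Keep pairs with |FC| >= fc_min (oriented scale) and q <= q_max."""
    if fc_min < 1.0:
        raise ParameterError("fc_min must be >= 1 (oriented fold change)")
    keep = (stats_table["ratio"].abs() >= np.log2(fc_min)) & (
        stats_table["p_adjusted"] <= q_max
    )
    return stats_table.loc[keep].reset_index(drop=True)
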