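"""Ratio-pair feature construction: the normalization-free core.

Instead of normalizing each species to an external reference, every
feature is the within-sample ratio of two species. On the sequencing side
this is the log2 count ratio; on the qPCR side it is the CT difference

    dCT(miR1/miR2) = CT(miR2) - CT(miR1),

which equals the log2 abundance ratio of miR1 over miR2 under 100%
amplification efficiency (one cycle per doubling). The cross-group
statistic is

    RATIO(X vs Y) = mean dCT_X(miR1/miR2) - mean dCT_Y(miR1/miR2),

and the fold change is FC = 2**RATIO.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import AnnotationError, EmptyGroupError, ParameterError
from .io import CountMatrix, CtMatrix

DEFAULT_MIN_COPIES = 50
DEFAULT_EXCLUDE_CLASSES = frozenset({"pre_miRNA"})


def filter_by_abundance(m: CountMatrix, min_copies: int = DEFAULT_MIN_COPIES) -> CountMatrix:
    """Keep species with at least ``min_copies`` reads in any one sample.

    The rule is max-based: a species qualifies if *any* pooled sample
    reaches the copy threshold, so species absent from some pools survive.
    Idempotent; the sample axis is untouched.
    """
    if min_copies < 0:
        raise ParameterError("min_copies must be >= 0")
    keep = m.counts.max(axis=1) >= min_copies
    return CountMatrix(m.counts.loc[keep])


def enumerate_pairs(
    annotations: pd.DataFrame,
    retained_ids,
    exclude_classes=DEFAULT_EXCLUDE_CLASSES,
) -> list[tuple[str, str]]:
    """All unordered pairs of retained species outside the excluded classes.

    Precursor miRNAs are excluded by default: their mature products are
    measured separately and a precursor/product ratio is not a usable
    biomarker readout. Returns ``n*(n-1)/2`` pairs for ``n`` eligible ids,
    in the order induced by ``retained_ids``.
    """
    cls = annotations.set_index("species_id")["rna_class"]
    missing = [s for s in retained_ids if s not in cls.index]
    if missing:
        raise AnnotationError(f"unannotated species id(s): {missing[:5]}")
    eligible = [s for s in retained_ids if cls[s] not in set(exclude_classes)]
    return list(combinations(eligible, 2))


def log_ratio_from_counts(
    m: CountMatrix, pair: tuple[str, str], pseudocount: float = 0.5
) -> pd.Series:
    """Per-sample log2 count ratio for one pair, with a pseudocount.

    The abundance filter is max-based, so zeros can remain in individual
    pools; a pseudocount keeps the log finite there.
    """
    num, den = pair
    a = m.counts.loc[num].astype(float) + pseudocount
    b = m.counts.loc[den].astype(float) + pseudocount
    if (a <= 0).any() or (b <= 0).any():
        raise ParameterError(
            "zero count with non-positive pseudocount; use pseudocount > 0"
        )
    out = np.log2(a / b)
    out.name = pair_id(num, den)
    return out


def delta_ct(ct_mir1: float, ct_mir2: float) -> float:
    """dCT(miR1/miR2) = CT(miR2) - CT(miR1); larger = miR1 relatively up."""
    return ct_mir2 - ct_mir1


def pair_id(numerator: str, denominator: str) -> str:
    return f"{numerator}/{denominator}"


def split_pair_id(pid: str) -> tuple[str, str]:
    num, den = pid.split("/", 1)
    return num, den


def pair_features(
    ct: CtMatrix, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Sample × pair matrix of dCT values for many pairs at once.

    Row ``s``, column ``a/b`` holds ``CT_s(b) - CT_s(a)``. Samples missing
    either CT get NaN and are excluded pairwise from downstream statistics.
    """
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    arr = ct.ct.to_numpy()
    pos = {s: i for i, s in enumerate(ct.ct.index)}
    a_idx = np.fromiter((pos[s] for s in ia), dtype=int, count=len(ia))
    b_idx = np.fromiter((pos[s] for s in ib), dtype=int, count=len(ib))
    vals = arr[b_idx, :] - arr[a_idx, :]  # pairs × samples
    cols = [pair_id(a, b) for a, b in pairs]
    return pd.DataFrame(vals.T, index=ct.ct.columns, columns=cols)


def group_ratio(dct_x, dct_y) -> float:
    """RATIO(X vs Y): difference of the two group means of dCT."""
    x = np.asarray(dct_x, dtype=float)
    y = np.asarray(dct_y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise EmptyGroupError("both groups need at least one finite dCT value")
    return float(x.mean() - y.mean())


def fold_change(ratio: float) -> float:
    """FC = 2**RATIO (linear-scale group ratio of the pair ratio)."""
    return float(2.0 ** ratio)
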