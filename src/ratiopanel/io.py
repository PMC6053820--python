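"""Data containers and tab-separated readers/writers.

The pipeline works from three tabular inputs, all plain text:

* a species × pooled-sample **count matrix** from small-RNA sequencing
  (TSV, first column ``species_id``, non-negative integer cells);
* a species × individual-sample **CT matrix** from qRT-PCR (TSV, floats;
  technical replicates may appear as consecutive columns per sample and
  are collapsed by their arithmetic mean; missing values written ``NA``);
* a **sample metadata** table (CSV: ``sample_id,group,cohort``) and a
  **species annotation** table (TSV: ``species_id,rna_class``).

Containers are thin frozen wrappers around pandas DataFrames that enforce
the invariants (unique ids, non-negative integer counts, plausible CT
range) at construction time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateIdError,
    InputFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

GROUPS = ("LAC", "BENIGN", "CONTROL")
COHORTS = ("training", "validation")
RNA_CLASSES = ("mature_miRNA", "pre_miRNA", "snoRNA", "tRNA", "rRNA", "scRNA")

#: default plausible qPCR cycle-threshold range (cycles)
CT_RANGE = (5.0, 45.0)


def _check_unique(values, axis_name: str) -> None:
    dup = pd.Index(values)[pd.Index(values).duplicated()].unique()
    if len(dup):
        raise DuplicateIdError(
            f"duplicate {axis_name} id(s): {', '.join(map(str, dup[:5]))}"
        )


@dataclass(frozen=True)
class CountMatrix:
    """Read counts per small ncRNA species per (pooled) sequencing sample."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        df.index.name = "species_id"
        df.columns.name = None
        _check_unique(df.index, "species")
        _check_unique(df.columns, "sample")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise InputFormatError("count matrix must hold integer values")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise InputFormatError(
                f"negative count at species {df.index[r]!r}, sample {df.columns[c]!r}"
            )

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class CtMatrix:
    """qPCR cycle thresholds per species per individual sample.

    ``ct`` holds replicate-collapsed values (arithmetic mean of technical
    replicates); missing measurements are NaN and are excluded pairwise
    downstream.
    """

    ct: pd.DataFrame
    replicate_count: int = 1

    def __post_init__(self):
        self.ct.index.name = "species_id"
        self.ct.columns.name = None
        _check_unique(self.ct.index, "species")
        _check_unique(self.ct.columns, "sample")
        if self.replicate_count < 1:
            raise ValidationError("replicate_count must be >= 1")

    @property
    def species_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_missing(self) -> int:
        return int(self.ct.isna().to_numpy().sum())


def _check_ct_range(df: pd.DataFrame, ct_range, strict: bool) -> None:
    finite = df.to_numpy()[np.isfinite(df.to_numpy())]
    lo, hi = ct_range
    bad = ((finite < lo) | (finite > hi)).sum()
    if bad:
        msg = f"{bad} CT value(s) outside plausible range [{lo}, {hi}] cycles"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=3)


def read_count_matrix(path) -> CountMatrix:
    """Read a TSV count matrix (first column species ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    _check_unique(df.index, "species")
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"non-numeric count cell in {path}: {exc}") from exc
    if num.isna().any().any():
        raise InputFormatError(f"missing count cell in {path}")
    arr = num.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(arr != np.round(arr))[0]
        raise InputFormatError(
            f"non-integer count at species {num.index[r]!r}, sample {num.columns[c]!r}"
        )
    return CountMatrix(num.round().astype(np.int64))


def write_count_matrix(m: CountMatrix, path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="species_id")


def read_ct_matrix(
    path,
    replicates_per_sample: int = 1,
    ct_range=CT_RANGE,
    strict_range: bool = False,
) -> CtMatrix:
    """Read a TSV CT matrix, collapsing technical replicates by mean.

    With ``replicates_per_sample = r > 1`` the columns must come in
    consecutive blocks of ``r`` per biological sample; the sample id is the
    common prefix of the block's headers once a ``_r<k>`` suffix is
    stripped (falling back to the first header of the block). Missing CTs
    are encoded ``NA``; a block mean ignores missing replicates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise InputFormatError(f"non-numeric CT cell in {path}: {exc}") from exc
    r = int(replicates_per_sample)
    if r < 1:
        raise InputFormatError("replicates_per_sample must be >= 1")
    if df.shape[1] % r:
        raise InputFormatError(
            f"{df.shape[1]} CT columns not divisible by {r} replicates per sample"
        )
    if r > 1:
        blocks = [df.iloc[:, i : i + r] for i in range(0, df.shape[1], r)]
        names, cols = [], []
        for b in blocks:
            stripped = [h.rsplit("_r", 1)[0] for h in b.columns]
            names.append(stripped[0] if len(set(stripped)) == 1 else b.columns[0])
            with warnings.catch_warnings():  # all-NaN block mean is a valid NA
                warnings.simplefilter("ignore", RuntimeWarning)
                cols.append(b.mean(axis=1))
        df = pd.concat(cols, axis=1)
        df.columns = names
    _check_ct_range(df, ct_range, strict_range)
    return CtMatrix(df.astype(float), replicate_count=r)


def write_ct_matrix(m: CtMatrix, path) -> None:
    m.ct.to_csv(path, sep="\t", index_label="species_id", na_rep="NA")


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata CSV (sample_id,group,cohort)."""
    df = pd.read_csv(path, dtype=str)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"metadata lacks column(s): {sorted(missing)}")
    if df.empty:
        logger.warning("metadata table is empty")
        return df.reset_index(drop=True)
    _check_unique(df["sample_id"], "sample")
    bad = df.loc[~df["group"].isin(GROUPS)]
    if len(bad):
        raise ValidationError(
            f"unknown group label(s) {sorted(bad['group'].unique())} "
            f"in metadata row(s) {list(bad.index[:5])}; allowed: {GROUPS}"
        )
    bad = df.loc[~df["cohort"].isin(COHORTS)]
    if len(bad):
        raise ValidationError(
            f"unknown cohort label(s) {sorted(bad['cohort'].unique())}; "
            f"allowed: {COHORTS}"
        )
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read the species annotation TSV (species_id, rna_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    required = {"species_id", "rna_class"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"annotation lacks column(s): {sorted(missing)}")
    _check_unique(df["species_id"], "species")
    bad = df.loc[~df["rna_class"].isin(RNA_CLASSES)]
    if len(bad):
        raise ValidationError(
            f"unknown rna_class value(s) {sorted(bad['rna_class'].unique())}; "
            f"allowed: {RNA_CLASSES}"
        )
    return df.reset_index(drop=True)


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def align_samples(matrix_samples, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join matrix samples with metadata, reporting any mismatch by id.

    Never silently drops samples: every matrix sample must have exactly one
    metadata row. Metadata rows for samples absent from the matrix are
    allowed (a metadata file may describe both cohorts at once).
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in matrix_samples if s not in meta.index]
    if missing:
        raise ValidationError(
            f"sample(s) missing from metadata: {', '.join(missing[:5])}"
        )
    return meta.loc[list(matrix_samples)].reset_index()
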