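"""TPM normalization and the two-pronged sRNA presence/expression filter.

TPM (transcripts per million) is the length-normalized relative abundance
``TPM_i = 1e6 * (count_i / length_i) / sum_j (count_j / length_j)``; every
non-degenerate sample column sums to one million, which makes expression
comparable across libraries of different depth and across features of very
different lengths (sRNAs are much shorter than mRNAs).

An sRNA is retained in a condition when it is (i) present — nonzero TPM —
in at least ``min_replicates`` of that condition's replicate libraries and
(ii) expressed above a class-specific TPM threshold (defaults: 40 TPM for
antisense, 14 TPM for intergenic sRNAs, applied to the condition mean).
Filtering is evaluated per condition: an sRNA may pass in one condition
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "TPMMatrix",
    "tpm",
    "filter_srnas",
    "condition_summary",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_sample_sheet",
    "DEFAULT_TPM_THRESHOLDS",
    "DEFAULT_MIN_REPLICATES",
]

DEFAULT_TPM_THRESHOLDS: dict[str, float] = {"antisense": 40.0, "intergenic": 14.0}
DEFAULT_MIN_REPLICATES = 4

_SAMPLE_COLS = ("condition", "replicate")


def _validate_samples(values: pd.DataFrame, samples: pd.DataFrame) -> None:
    for col in _SAMPLE_COLS:
        if col not in samples.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    if list(values.columns) != list(samples.index):
        raise ValueError("sample sheet rows must match matrix columns (same order)")


@dataclass
class CountMatrix:
    """Feature x sample read counts with per-feature lengths and sample metadata.

    ``counts``: DataFrame indexed by feature id, columns = sample ids.
    ``lengths``: Series of feature lengths (nt), same index.
    ``samples``: DataFrame indexed by sample id with at least a
    ``condition`` and ``replicate`` column.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("counts index and lengths index differ")
        _validate_samples(self.counts, self.samples)
        if (self.lengths < 1).any():
            raise ValueError("feature lengths must be >= 1")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        if len(sel) == 0:
            raise KeyError(f"no samples with condition {condition!r}")
        return list(sel)


@dataclass
class TPMMatrix:
    """TPM-normalized twin of a :class:`CountMatrix` (same shape/metadata)."""

    tpm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_samples(self.tpm, self.samples)

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.index[self.samples["condition"] == condition]
        if len(sel) == 0:
            raise KeyError(f"no samples with condition {condition!r}")
        return list(sel)


def tpm(counts: CountMatrix) -> TPMMatrix:
    """Length-normalize counts to transcripts per million, per sample.

    An all-zero sample column yields an all-zero TPM column (with a
    warning) rather than NaNs.
    """
    rates = counts.counts.to_numpy(dtype=float) / counts.lengths.to_numpy(dtype=float)[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        bad = list(counts.counts.columns[zero_cols])
        warnings.warn(f"all-zero sample column(s) {bad}; TPM set to 0", stacklevel=2)
    safe = np.where(zero_cols, 1.0, totals)
    values = 1e6 * rates / safe
    values[:, zero_cols] = 0.0
    df = pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)
    return TPMMatrix(df, counts.samples.copy())


def condition_summary(mat: TPMMatrix, condition: str) -> pd.DataFrame:
    """Per-feature mean and sample standard deviation (ddof=1) in a condition."""
    cols = mat.condition_samples(condition)
    if len(cols) < 2:
        raise ValueError("condition_summary needs >= 2 replicates")
    sub = mat.tpm[cols]
    return pd.DataFrame({"mean_tpm": sub.mean(axis=1), "sd_tpm": sub.std(axis=1, ddof=1)})


def filter_srnas(
    mat: TPMMatrix,
    classes: Mapping[str, str],
    condition: str,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    thresholds: Mapping[str, float] = DEFAULT_TPM_THRESHOLDS,
    mode: str = "mean",
) -> pd.DataFrame:
    """Apply the presence + expression filter to the sRNAs of one condition.

    Parameters
    ----------
    classes
        Map feature id -> sRNA class ('antisense' or 'intergenic'); only
        these features are evaluated.
    mode
        'mean' applies the TPM threshold to the condition mean (default);
        'per_replicate' requires >= min_replicates individual replicates at
        or above the threshold.

    Returns a DataFrame (index = feature id) with columns ``srna_class``,
    ``n_detected``, ``mean_tpm``, ``sd_tpm``, ``passed``, ``reason``.
    """
    if mode not in ("mean", "per_replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    cols = mat.condition_samples(condition)
    if len(cols) < min_replicates:
        raise ValueError(
            f"condition {condition!r} has {len(cols)} replicates < min_replicates"
        )
    missing = [f for f in classes if f not in mat.tpm.index]
    if missing:
        raise KeyError(f"features absent from TPM matrix: {missing[:5]}")
    unknown = {c for c in classes.values() if c not in thresholds}
    if unknown:
        raise ValueError(f"no TPM threshold for class(es) {sorted(unknown)}")

    ids = list(classes)
    sub = mat.tpm.loc[ids, cols]
    n_detected = (sub > 0).sum(axis=1)
    mean_tpm = sub.mean(axis=1)
    sd_tpm = sub.std(axis=1, ddof=1) if len(cols) > 1 else pd.Series(np.nan, index=sub.index)
    thr = pd.Series({f: thresholds[classes[f]] for f in ids})
    detected = n_detected >= min_replicates
    if mode == "mean":
        expressed = mean_tpm >= thr
    else:
        expressed = (sub.ge(thr, axis=0)).sum(axis=1) >= min_replicates
    passed = detected & expressed
    reason = np.where(
        passed,
        "pass",
        np.where(~detected, "fail(detection)", "fail(expression)"),
    )
    return pd.DataFrame(
        {
            "srna_class": [classes[f] for f in ids],
            "n_detected": n_detected,
            "mean_tpm": mean_tpm,
            "sd_tpm": sd_tpm,
            "passed": passed,
            "reason": reason,
        },
        index=pd.Index(ids, name="feature"),
    )


# ---------------------------------------------------------------------------
# TSV I/O (counts table with a 'length' column; sidecar sample sheet)


def write_counts_tsv(counts: CountMatrix, counts_path, samples_path) -> None:
    out = counts.counts.copy()
    out.insert(0, "length", counts.lengths)
    out.to_csv(counts_path, sep="\t", index_label="feature")
    counts.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_sample_sheet(samples_path) -> pd.DataFrame:
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    for col in _SAMPLE_COLS:
        if col not in samples.columns:
            raise ValueError(f"sample sheet lacks required column {col!r}")
    return samples


def read_counts_tsv(counts_path, samples_path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col="feature")
    if "length" not in df.columns:
        raise ValueError("counts table lacks 'length' column")
    lengths = df["length"]
    counts = df.drop(columns="length")
    samples = read_sample_sheet(samples_path).loc[counts.columns]
    samples.index.name = "sample"
    return CountMatrix(counts, lengths, samples)
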