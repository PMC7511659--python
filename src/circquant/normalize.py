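"""Normalization of back-spliced read counts.

Six schemes are supported, all of the form ``n_ij = c_ij * S / d_j`` with a
per-sample denominator ``d_j``:

================== =====================================================
method              denominator
================== =====================================================
library_size        total filtered reads T_j
backspliced_sum     total back-spliced reads B_j
size_factor         median-of-ratios size factor f_j (S ignored)
library_size_excl   T_j minus rRNA and chloroplast reads
backspliced_sum_excl back-spliced reads excluding rRNA/chloroplast circles
marker_gene         raw reads on the endogenous marker gene (ACT2)
================== =====================================================

Because every scheme rescales each sample by a positive constant, within-
sample rank order is identical across schemes, and any correlation, fold
change or class assignment downstream is invariant to the scale constant S.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .model import CircCountMatrix, LibraryStats

__all__ = [
    "NormMethod",
    "NormalizedMatrix",
    "SizeFactors",
    "compute_size_factors",
    "normalize",
    "aggregate_replicates",
]


class NormMethod(str, Enum):
    """The six tested normalization schemes."""

    library_size = "library_size"
    backspliced_sum = "backspliced_sum"
    size_factor = "size_factor"
    library_size_excl = "library_size_excl"
    backspliced_sum_excl = "backspliced_sum_excl"
    marker_gene = "marker_gene"


@dataclass
class SizeFactors:
    """Median-of-ratios size factors.

    ``factors`` is a positive per-sample Series; ``reference`` holds the
    per-circRNA geometric means (the pseudo-reference sample) over which the
    ratios were taken. Only circRNAs with a nonzero count in every sample
    contribute.
    """

    factors: pd.Series
    reference: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")


class SparseMatrixError(ValueError):
    """No circRNA has nonzero counts in every sample."""


def compute_size_factors(counts: CircCountMatrix) -> SizeFactors:
    """Median-of-ratios size factors on the back-spliced count matrix.

    For each circRNA i with geometric mean g_i > 0 across samples (no zero
    anywhere), the ratio c_ij / g_i is formed; f_j is the median of these
    ratios within sample j.

    Raises
    ------
    SparseMatrixError
        If no circRNA is nonzero in every sample. Back-spliced count
        matrices are often too sparse for this estimator; normalize by the
        back-spliced sum instead.
    """
    if counts.n_samples < 2:
        raise ValueError("size factors require at least 2 samples")
    mat = counts.counts.to_numpy(dtype=float)
    eligible = (mat > 0).all(axis=1)
    if not eligible.any():
        raise SparseMatrixError(
            "no circRNA has nonzero counts in every sample; median-of-ratios "
            "is undefined — use the backspliced_sum method for sparse matrices"
        )
    sub = mat[eligible]
    log_geo = np.mean(np.log(sub), axis=1)
    ratios = sub / np.exp(log_geo)[:, None]
    factors = np.median(ratios, axis=0)
    sample_ids = [s.sample_id for s in counts.samples]
    reference = pd.Series(
        np.exp(log_geo), index=[cid for cid, e in zip(counts.id_strings, eligible) if e]
    )
    return SizeFactors(pd.Series(factors, index=sample_ids), reference)


@dataclass
class NormalizedMatrix:
    """Normalized abundances with the method tag and scale constant used."""

    values: pd.DataFrame
    samples: list
    method: NormMethod
    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")

    @property
    def id_strings(self):
        return list(self.values.index)

    def organ_columns(self, organ: str):
        return [s.sample_id for s in self.samples if s.organ == organ]


def _denominators(counts: CircCountMatrix, stats: LibraryStats | None,
                  method: NormMethod) -> pd.Series:
    sample_ids = [s.sample_id for s in counts.samples]
    if method == NormMethod.size_factor:
        return compute_size_factors(counts).factors
    if stats is None:
        raise ValueError(f"method {method.value} requires LibraryStats")
    t = stats.table.reindex(sample_ids)
    if t.isna().any().any():
        missing = [s for s in sample_ids if s not in stats.table.index]
        raise ValueError(f"LibraryStats missing samples {missing}")
    if method == NormMethod.library_size:
        return t["total_reads"]
    if method == NormMethod.backspliced_sum:
        return t["backspliced_reads"]
    if method == NormMethod.library_size_excl:
        return t["total_reads"] - t["rrna_reads"] - t["chloroplast_reads"]
    if method == NormMethod.backspliced_sum_excl:
        return t["backspliced_reads_excl"]
    if method == NormMethod.marker_gene:
        return t["marker_reads"]
    raise ValueError(f"unknown method {method!r}")


def normalize(counts: CircCountMatrix, stats: LibraryStats | None,
              method: NormMethod | str, scale: float = 1e6) -> NormalizedMatrix:
    """Normalize back-spliced counts by the chosen per-sample denominator.

    ``n_ij = c_ij * scale / d_j``; for ``size_factor`` the convention is
    ``n_ij = c_ij / f_j`` (scale ignored, recorded as 1). A denominator that
    is zero or negative raises ``ValueError`` naming the sample and method.
    """
    method = NormMethod(method)
    denom = _denominators(counts, stats, method)
    bad = denom.index[denom <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive denominator for method {method.value} in sample(s) {list(bad)}"
        )
    eff_scale = 1.0 if method == NormMethod.size_factor else float(scale)
    values = counts.counts.astype(float) * (eff_scale / denom)
    return NormalizedMatrix(values=values, samples=list(counts.samples),
                            method=method, scale=eff_scale)


def aggregate_replicates(norm: NormalizedMatrix, by: str = "organ"):
    """Mean and sample sd (ddof=1; 0 for a single replicate) per group.

    Returns ``(mean, sd)`` DataFrames with one column per group (organ by
    default), rows matching the normalized matrix.
    """
    groups: dict = {}
    for s in norm.samples:
        key = getattr(s, by)
        groups.setdefault(key, []).append(s.sample_id)
    means = {}
    sds = {}
    for key, cols in groups.items():
        if not cols:
            raise ValueError(f"group {key!r} has no samples")
        block = norm.values[cols]
        means[key] = block.mean(axis=1)
        sds[key] = block.std(axis=1, ddof=1).fillna(0.0) if len(cols) > 1 else 0.0
    mean_df = pd.DataFrame(means)
    sd_df = pd.DataFrame(sds, index=mean_df.index)
    if isinstance(sd_df, pd.DataFrame):
        sd_df = sd_df.fillna(0.0)
    return mean_df, sd_df
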