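"""Droplet digital PCR quantification.

A ddPCR reaction partitions the template into ~15,000-20,000 droplets; the
fraction of positive droplets estimates the mean occupancy per droplet by
Poisson statistics, lambda = -ln(1 - n_pos/n_total). The occupancy converts
to copies/uL of reaction and then to copies per microgram of input total RNA
(cp/ug) through the reaction volume and the RNA mass represented in one
reaction. Defaults follow the QX200 convention (0.85 nL droplets) and an RT
design loading 1 uL of a 20 uL reverse-transcription reaction primed with
1 ug of total RNA (0.05 ug per ddPCR reaction).

The limit of quantification (LoQ) is operationalized from replicate
dispersion: a measurement series whose sample standard deviation reaches its
mean (CV >= 1) is considered unreliable, and the LoQ is the smallest mean
among targets that are reliable in every sample type, snapped to one
significant figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DdpcrQuant",
    "LoqResult",
    "SaturationError",
    "lambda_from_droplets",
    "copies_per_ug",
    "quantify_droplets",
    "marker_normalize",
    "aggregate_ddpcr",
    "loq_from_replicates",
    "loq_from_summary",
    "MARKER_GENE_ID",
]

#: Endogenous reference gene used for ddPCR normalization (ACT2).
MARKER_GENE_ID = "AT3G18780"

DEFAULT_DROPLET_VOLUME_NL = 0.85
DEFAULT_REACTION_VOLUME_UL = 20.0
DEFAULT_RNA_MASS_UG = 0.05


class SaturationError(ValueError):
    """All droplets positive: concentration above the dynamic range."""


def lambda_from_droplets(n_pos: int, n_total: int) -> float:
    """Mean copies per droplet from the positive-droplet count.

    ``lambda = -ln((n_total - n_pos) / n_total)``; strictly increasing in
    ``n_pos`` at fixed ``n_total``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_pos < 0 or n_pos > n_total:
        raise ValueError(f"need 0 <= n_pos <= n_total, got {n_pos}/{n_total}")
    if n_pos == n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration above dynamic range"
        )
    return -math.log((n_total - n_pos) / n_total)


def copies_per_ug(lambda_: float,
                  droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
                  reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL,
                  rna_mass_ug: float = DEFAULT_RNA_MASS_UG) -> float:
    """Convert droplet occupancy to copies per microgram of input total RNA.

    ``conc [cp/uL] = lambda / (droplet_volume_nl * 1e-3)`` and
    ``cp/ug = conc * reaction_volume_ul / rna_mass_ug``. Linear in lambda.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    if droplet_volume_nl <= 0 or reaction_volume_ul <= 0 or rna_mass_ug <= 0:
        raise ValueError("volumes and RNA mass must be positive")
    conc_per_ul = lambda_ / (droplet_volume_nl * 1e-3)
    return conc_per_ul * reaction_volume_ul / rna_mass_ug


def cp_per_ug_to_lambda(cp_per_ug: float,
                        droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
                        reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL,
                        rna_mass_ug: float = DEFAULT_RNA_MASS_UG) -> float:
    """Inverse of :func:`copies_per_ug` (used by the simulator)."""
    conc_per_ul = cp_per_ug * rna_mass_ug / reaction_volume_ul
    return conc_per_ul * droplet_volume_nl * 1e-3


@dataclass
class DdpcrQuant:
    """Quantification of one target in one measurement."""

    target: str
    organ: str
    replicate: int
    lambda_: float
    conc_per_ul: float
    cp_per_ug: float
    rel_to_marker: float | None = None


def quantify_droplets(assays: pd.DataFrame,
                      droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
                      reaction_volume_ul: float = DEFAULT_REACTION_VOLUME_UL,
                      rna_mass_ug: float = DEFAULT_RNA_MASS_UG) -> pd.DataFrame:
    """Add ``lambda_``, ``conc_per_ul`` and ``cp_per_ug`` columns.

    Rows that already carry ``cp_per_ug`` (no droplet counts) are passed
    through unchanged.
    """
    out = assays.copy()
    if {"n_pos", "n_total"}.issubset(out.columns):
        lam = [lambda_from_droplets(int(p), int(t))
               for p, t in zip(out["n_pos"], out["n_total"])]
        out["lambda_"] = lam
        out["conc_per_ul"] = [x / (droplet_volume_nl * 1e-3) for x in lam]
        out["cp_per_ug"] = [
            copies_per_ug(x, droplet_volume_nl, reaction_volume_ul, rna_mass_ug) for x in lam
        ]
    elif "cp_per_ug" not in out.columns:
        raise ValueError("assay table needs n_pos/n_total or cp_per_ug")
    return out


def marker_normalize(targets: pd.DataFrame, marker: pd.DataFrame) -> pd.DataFrame:
    """Express target cp/ug relative to the reference gene.

    The marker is averaged over its technical repeats within each (organ,
    biological replicate); each target measurement in that replicate is
    divided by the matching marker mean. Invariant to any common rescaling
    of all cp/ug values.
    """
    marker_mean = (
        marker.groupby(["organ", "replicate"])["cp_per_ug"].mean().rename("marker_cp_per_ug")
    )
    if (marker_mean <= 0).any():
        bad = marker_mean.index[marker_mean <= 0].tolist()
        raise ValueError(f"marker mean cp/ug is zero for replicate(s) {bad}")
    out = targets.merge(marker_mean.reset_index(), on=["organ", "replicate"], how="left")
    if out["marker_cp_per_ug"].isna().any():
        bad = out.loc[out["marker_cp_per_ug"].isna(), ["organ", "replicate"]]
        raise ValueError(
            "no marker measurement for replicate(s) "
            f"{sorted(set(map(tuple, bad.to_numpy())))}"
        )
    out["rel_to_marker"] = out["cp_per_ug"] / out["marker_cp_per_ug"]
    return out


def aggregate_ddpcr(quant: pd.DataFrame, value: str = "cp_per_ug") -> pd.DataFrame:
    """Mean and sample sd (ddof=1) over biological replicates per target x organ."""
    g = quant.groupby(["target", "organ"])[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    return out


@dataclass
class LoqResult:
    """Limit of quantification derived from replicate dispersion."""

    threshold_cp_per_ug: float
    rule: str
    per_target: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.threshold_cp_per_ug <= 0:
            raise ValueError("LoQ threshold must be positive")


def _snap_one_sig_fig(x: float) -> float:
    if x <= 0:
        raise ValueError("cannot snap non-positive value")
    exp = math.floor(math.log10(x))
    return round(x / 10 ** exp) * 10 ** exp


def loq_from_summary(summary: pd.DataFrame) -> LoqResult:
    """LoQ from per-(target, sample type) means and sds.

    ``summary`` needs columns ``target``, ``organ`` (or any stratum label),
    ``mean``, ``sd``. A series is unreliable when sd >= mean (CV >= 1) or
    its mean is zero; the threshold is the smallest observed mean among
    targets that are reliable in every sample type, snapped to one
    significant figure.
    """
    s = summary.copy()
    if s.empty or s["target"].nunique() < 3:
        raise ValueError("need at least 3 targets spanning the low range")
    s["unreliable"] = (s["mean"] <= 0) | (s["sd"] >= s["mean"])
    flagged_targets = set(s.loc[s["unreliable"], "target"])
    reliable = s[~s["target"].isin(flagged_targets)]
    if reliable.empty:
        raise ValueError("all targets flagged unreliable: no quantifiable range")
    threshold = _snap_one_sig_fig(float(reliable["mean"].min()))
    rule = (
        "unreliable when sample sd >= mean (CV >= 1) or mean = 0; LoQ = smallest "
        "mean among targets reliable in every sample type, one significant figure"
    )
    return LoqResult(threshold_cp_per_ug=threshold, rule=rule, per_target=s)


def loq_from_replicates(measurements: pd.DataFrame) -> LoqResult:
    """LoQ from replicate-level cp/ug measurements.

    ``measurements`` needs columns ``target``, ``organ``, ``cp_per_ug`` with
    at least 2 replicates per (target, organ) series.
    """
    counts = measurements.groupby(["target", "organ"])["cp_per_ug"].count()
    if (counts < 2).any():
        bad = counts.index[counts < 2].tolist()
        raise ValueError(f"need >= 2 replicates per target and sample type; short: {bad}")
    summary = aggregate_ddpcr(measurements)
    return loq_from_summary(summary)
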