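"""Concordance of normalized RNA-seq counts with ddPCR, and threshold calibration.

Each normalization scheme is scored by the Pearson correlation between its
mean normalized read values and the ddPCR cp/ug means, pooled over all
(target, sample type) pairs and within each sample type. Correlations are
computed on the raw (untransformed) means; because normalization rescales
each sample by a positive constant, every cell is invariant to the scale
constant and to any common rescaling of the ddPCR units.

The detection threshold on the normalized-read scale is calibrated from the
ddPCR limit of quantification through a zero-intercept least-squares line
(a target absent from the RNA must yield zero expected reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ddpcr import LoqResult
from .model import ORGANS

__all__ = [
    "pearson",
    "ConcordanceTable",
    "concordance_table",
    "concordance_from_panel",
    "CalibrationResult",
    "calibrate_read_threshold",
]


class ConstantVectorError(ValueError):
    """Pearson correlation undefined for a constant vector."""


def pearson(x, y) -> float:
    """Sample Pearson product-moment correlation on raw paired values.

    Requires equal length >= 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class ConcordanceTable:
    """Pearson r per stratum (rows) and normalization method (columns).

    ``r`` holds full-precision coefficients; ``rounded()`` applies the 2-dp
    reporting convention. ``n_pairs`` gives the number of (target, sample
    type) pairs behind each cell.
    """

    r: pd.DataFrame
    n_pairs: pd.DataFrame

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        return self.r.round(decimals)


def concordance_table(ddpcr_means: pd.DataFrame, norm_means: dict,
                      pairing: dict, organs=ORGANS) -> ConcordanceTable:
    """Correlate ddPCR means with normalized means, overall and per organ.

    Parameters
    ----------
    ddpcr_means:
        Columns ``target``, ``organ``, ``cp_per_ug`` (mean over biological
        replicates).
    norm_means:
        Mapping of method name to a circRNA x organ DataFrame of mean
        normalized values (rows indexed by circRNA id string).
    pairing:
        Maps each ddPCR target to exactly one circRNA id string.
    """
    orphans = [t for t in ddpcr_means["target"].unique() if t not in pairing]
    if orphans:
        raise ValueError(f"ddPCR target(s) with no circRNA mapping: {orphans}")

    methods = list(norm_means)
    strata = ["all", *organs]
    r = pd.DataFrame(index=strata, columns=methods, dtype=float)
    n = pd.DataFrame(index=strata, columns=methods, dtype=int)
    for method, means in norm_means.items():
        xs, ys, organ_of = [], [], []
        for _, row in ddpcr_means.iterrows():
            circ = pairing[row["target"]]
            if circ not in means.index:
                raise ValueError(f"circRNA {circ} missing from {method} means")
            xs.append(float(row["cp_per_ug"]))
            ys.append(float(means.loc[circ, row["organ"]]))
            organ_of.append(row["organ"])
        xs = np.asarray(xs)
        ys = np.asarray(ys)
        organ_of = np.asarray(organ_of)
        r.loc["all", method] = pearson(xs, ys)
        n.loc["all", method] = len(xs)
        for organ in organs:
            m = organ_of == organ
            r.loc[organ, method] = pearson(xs[m], ys[m])
            n.loc[organ, method] = int(m.sum())
    return ConcordanceTable(r=r, n_pairs=n)


def concordance_from_panel(panel: pd.DataFrame, method_columns=None) -> ConcordanceTable:
    """Concordance table for a benchmark panel in the packaged layout.

    The panel carries the ddPCR means and the per-method normalized means in
    one table (see :func:`circquant.datasets.load_benchmark_panel`); each
    (name, organ) row is one pair.
    """
    from .datasets import BENCHMARK_METHOD_COLUMNS

    method_columns = method_columns or {
        m.value: col for m, col in BENCHMARK_METHOD_COLUMNS.items()
    }
    organs = list(dict.fromkeys(panel["organ"]))
    ddpcr_means = panel.rename(columns={"name": "target"})[["target", "organ", "cp_per_ug"]]
    pairing = {t: t for t in ddpcr_means["target"].unique()}
    norm_means = {}
    for method, col in method_columns.items():
        wide = panel.pivot(index="name", columns="organ", values=col)
        norm_means[method] = wide
    return concordance_table(ddpcr_means, norm_means, pairing, organs=organs)


@dataclass
class CalibrationResult:
    """Normalized-read detection threshold anchored to the ddPCR LoQ."""

    loq_cp_per_ug: float
    slope: float
    read_threshold: float

    def __post_init__(self) -> None:
        if self.read_threshold <= 0:
            raise ValueError("read threshold must be positive")


def _round_one_sig_fig(x: float) -> float:
    # nearest value at one significant figure, half away from zero;
    # a hard ceiling at this resolution would jump 10.01 -> 20, making the
    # threshold discontinuous in the fitted slope
    exp = math.floor(math.log10(x))
    mant = x / 10 ** exp
    return math.floor(mant + 0.5) * 10 ** exp


def calibrate_read_threshold(cp_per_ug, normalized, loq) -> CalibrationResult:
    """Map the ddPCR LoQ onto the normalized-read scale.

    Fits ``normalized = k * cp_per_ug`` (zero intercept, least squares) on
    the pairs at or above the LoQ and returns ``k * LoQ`` snapped to one
    significant figure.
    """
    loq_value = loq.threshold_cp_per_ug if isinstance(loq, LoqResult) else float(loq)
    if loq_value <= 0:
        raise ValueError("LoQ must be positive")
    x = np.asarray(cp_per_ug, dtype=float)
    y = np.asarray(normalized, dtype=float)
    mask = x >= loq_value
    if mask.sum() < 4:
        raise ValueError(
            f"need >= 4 pairs at or above the LoQ ({loq_value} cp/ug), have {int(mask.sum())}"
        )
    xs, ys = x[mask], y[mask]
    k = float(np.dot(xs, ys) / np.dot(xs, xs))
    if k <= 0:
        raise ValueError("no positive association between cp/ug and normalized reads")
    return CalibrationResult(
        loq_cp_per_ug=loq_value, slope=k, read_threshold=_round_one_sig_fig(k * loq_value)
    )
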