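"""Pairwise differential accumulation, abundance classes, circular-vs-linear.

Differential calls follow the two-fold / p <= 0.05 convention: for each
circRNA the fold change is computed on replicate-mean normalized values with
a pseudocount (keeping log2FC finite and direction-correct at zeros), and
the p-value comes from a two-sided Welch t-test on log2(value + pseudocount)
across replicates — robust to unequal variance at n = 4. No multiple-testing
correction is applied by default; a Benjamini-Hochberg option is available.

Abundance classes discretize each organ's detected values into high (top 5%
by ceil), medium (strictly above the 80th percentile, excluding high), low
(the rest) and not_detected (zero/absent). Row ordering for heatmaps uses
agglomerative clustering (average linkage, Euclidean distance on
log2(value + 1)).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .concordance import pearson
from .model import LinearCountMatrix
from .normalize import NormalizedMatrix

__all__ = [
    "pairwise_diff",
    "count_diff_by_pair",
    "classify_abundance",
    "cluster_order",
    "circ_linear_analysis",
    "CircLinearResult",
    "ABUNDANCE_CLASSES",
]

ABUNDANCE_CLASSES = ("high", "medium", "low", "not_detected")


def _replicate_values(norm: NormalizedMatrix, organ: str) -> pd.DataFrame:
    cols = norm.organ_columns(organ)
    if not cols:
        raise ValueError(f"no samples for organ {organ!r}")
    return norm.values[cols]


def pairwise_diff(norm: NormalizedMatrix, organ_a: str, organ_b: str,
                  analysis_ids=None, fc_cutoff: float = 2.0, alpha: float = 0.05,
                  pseudocount: float = 0.5, bh_correct: bool = False) -> pd.DataFrame:
    """Fold change and significance for one ordered organ pair (A vs B).

    Returns a DataFrame with ``mean_a``, ``mean_b``, ``log2fc``
    (= log2((mean_a + pc) / (mean_b + pc))), ``p_value`` and ``significant``
    (|log2FC| >= log2(fc_cutoff) and p <= alpha). With fewer than 2
    replicates in either organ the fold change is still reported but the
    p-value is NaN and the call is never significant.

    ``analysis_ids`` restricts rows to the analysis set (circRNAs passing
    the abundance filter in at least one of the organs, typically).
    """
    va = _replicate_values(norm, organ_a)
    vb = _replicate_values(norm, organ_b)
    if analysis_ids is not None:
        keep = [cid for cid in norm.id_strings if cid in set(analysis_ids)]
        va, vb = va.loc[keep], vb.loc[keep]
    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    if va.shape[1] >= 2 and vb.shape[1] >= 2:
        la = np.log2(va.to_numpy(dtype=float) + pseudocount)
        lb = np.log2(vb.to_numpy(dtype=float) + pseudocount)
        with warnings.catch_warnings():
            # identical near-constant rows (e.g. all zeros) trip a scipy
            # precision warning; their p-values are mapped to 1 below
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # constant identical rows yield nan from a 0/0 statistic: no evidence
        p = np.where(np.isnan(p), 1.0, p)
    else:
        p = np.full(len(mean_a), np.nan)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=va.index,
    )
    if bh_correct and not np.isnan(p).all():
        out["p_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
    with np.errstate(invalid="ignore"):
        out["significant"] = (
            (np.abs(out["log2fc"]) >= math.log2(fc_cutoff))
            & (out["p_value"] <= alpha)
        ).fillna(False)
    out.attrs["pair"] = (organ_a, organ_b)
    out.attrs["fc_cutoff"] = fc_cutoff
    out.attrs["alpha"] = alpha
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def all_pairs_diff(norm: NormalizedMatrix, organs=None, **kwargs) -> dict:
    """``pairwise_diff`` for every unordered organ pair (A earlier in list)."""
    if organs is None:
        organs = list(dict.fromkeys(s.organ for s in norm.samples))
    return {
        (a, b): pairwise_diff(norm, a, b, **kwargs)
        for a, b in itertools.combinations(organs, 2)
    }


def organ_specific_sets(results: dict, organs) -> dict:
    """CircRNAs significantly increased in one organ against every other.

    ``results`` maps unordered organ pairs (as produced by
    :func:`all_pairs_diff`) to their DataFrames. A circRNA is specific to
    organ ``o`` when each of its comparisons against the remaining organs is
    a significant increase in ``o``.
    """
    out = {}
    for organ in organs:
        candidate = None
        for other in organs:
            if other == organ:
                continue
            if (organ, other) in results:
                res = results[(organ, other)]
                up = set(res.index[res["significant"] & (res["log2fc"] > 0)])
            elif (other, organ) in results:
                res = results[(other, organ)]
                up = set(res.index[res["significant"] & (res["log2fc"] < 0)])
            else:
                raise KeyError(f"missing comparison between {organ} and {other}")
            candidate = up if candidate is None else candidate & up
        out[organ] = candidate or set()
    return out


def count_diff_by_pair(results: dict) -> pd.DataFrame:
    """Significant increase/decrease counts per ordered organ pair.

    For each pair (A, B): ``up`` counts significant calls with higher
    accumulation in A, ``down`` those higher in B; by antisymmetry
    up(A, B) == down(B, A).
    """
    rows = []
    for (a, b), res in results.items():
        sig = res[res["significant"]]
        rows.append(
            {
                "organ_a": a,
                "organ_b": b,
                "up": int((sig["log2fc"] > 0).sum()),
                "down": int((sig["log2fc"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["organ_a", "organ_b", "up", "down"])


def classify_abundance(per_organ_means: pd.DataFrame,
                       high_fraction: float = 0.05,
                       medium_percentile: float = 80.0) -> pd.DataFrame:
    """Discrete abundance classes per circRNA per organ.

    Per organ, over the detected circRNAs (value > 0): the top
    ``ceil(high_fraction * n)`` values are ``high``; values strictly above
    the ``medium_percentile``-th percentile of detected values that are not
    high are ``medium``; the rest are ``low``. Zero or missing values are
    ``not_detected``. Ties are broken by the stable circRNA-id row order, so
    the assignment is deterministic.
    """
    out = pd.DataFrame(
        "not_detected", index=per_organ_means.index, columns=per_organ_means.columns
    )
    for organ in per_organ_means.columns:
        values = per_organ_means[organ]
        detected = values[(values > 0) & values.notna()]
        n = len(detected)
        if n == 0:
            continue
        n_high = math.ceil(high_fraction * n)
        # stable sort: descending value, ties by original row order
        order = detected.iloc[np.argsort(-detected.to_numpy(), kind="stable")]
        high_ids = set(order.index[:n_high])
        cutoff = np.percentile(detected.to_numpy(), medium_percentile)
        for cid, v in detected.items():
            if cid in high_ids:
                out.loc[cid, organ] = "high"
            elif v > cutoff:
                out.loc[cid, organ] = "medium"
            else:
                out.loc[cid, organ] = "low"
    return out


def cluster_order(per_organ_means: pd.DataFrame, method: str = "average"):
    """Heatmap row order from agglomerative clustering.

    Average-linkage clustering on Euclidean distances between
    log2(value + 1) profiles; returns the leaf order as a list of row
    labels. Deterministic given the input row order.
    """
    if len(per_organ_means) < 2:
        return list(per_organ_means.index)
    mat = np.log2(per_organ_means.fillna(0.0).to_numpy(dtype=float) + 1.0)
    link = hierarchy.linkage(pdist(mat, metric="euclidean"), method=method)
    leaves = hierarchy.leaves_list(link)
    return [per_organ_means.index[i] for i in leaves]


@dataclass
class CircLinearResult:
    """Outcome of the circular-vs-linear comparison.

    ``pairs`` has one row per circRNA with a mapped, detected linear
    counterpart and per-organ ratios; ``r_overall``/``r_per_organ`` are
    Pearson correlations between circular and linear abundances;
    ``n_excluded`` counts circRNAs left out of the correlation (intergenic
    or linear partner undetected) — these stay in the ratio analysis with an
    absent linear value.
    """

    pairs: pd.DataFrame
    r_overall: float
    r_per_organ: dict
    n_excluded: int
    excluded_ids: list


def circ_linear_analysis(circ_means: pd.DataFrame, linear: LinearCountMatrix,
                         mapping: dict, circ_method: str | None = None,
                         enrichment_factor: float = 1.5) -> CircLinearResult:
    """Compare circRNA abundances with their linear counterparts.

    Parameters
    ----------
    circ_means:
        circRNA x organ mean normalized values.
    linear:
        Parent-gene linear abundances on a comparable normalized scale; if
        both ``circ_method`` and ``linear.method`` are set they must match,
        otherwise the comparison is refused (ratios presuppose comparable
        units).
    mapping:
        circRNA id -> parent gene id; ids absent from the mapping are
        intergenic.
    enrichment_factor:
        A circRNA is flagged ``enriched`` when its abundance is at least
        this multiple of the linear counterpart in at least one organ.
    """
    if circ_method is not None and linear.method is not None and circ_method != linear.method:
        raise ValueError(
            f"normalization mismatch: circ={circ_method!r} vs linear={linear.method!r}"
        )
    organs = list(circ_means.columns)
    rows = []
    xs, ys = [], []
    per_organ_xy = {o: ([], []) for o in organs}
    excluded = []
    for cid in circ_means.index:
        gene = mapping.get(cid)
        lin_row = None
        if gene is not None and gene in linear.abundances.index:
            lin_row = linear.abundances.loc[gene]
        if lin_row is None or (lin_row <= 0).all():
            excluded.append(cid)
        row = {"circ_id": cid, "gene_id": gene}
        enriched = False
        for organ in organs:
            c = float(circ_means.loc[cid, organ])
            l = float(lin_row[organ]) if lin_row is not None else np.nan
            row[f"circ_{organ}"] = c
            row[f"linear_{organ}"] = l
            row[f"ratio_{organ}"] = c / l if lin_row is not None and l > 0 else np.nan
            if lin_row is not None and l > 0 and c >= enrichment_factor * l:
                enriched = True
            elif (lin_row is None or l <= 0) and c > 0:
                # linear partner undetected while the circle is present
                enriched = True
            if lin_row is not None and l > 0:
                xs.append(c)
                ys.append(l)
                per_organ_xy[organ][0].append(c)
                per_organ_xy[organ][1].append(l)
        row["enriched"] = enriched
        rows.append(row)
    pairs = pd.DataFrame(rows).set_index("circ_id")
    r_overall = pearson(xs, ys) if len(xs) >= 3 else float("nan")
    r_per_organ = {
        o: (pearson(x, y) if len(x) >= 3 else float("nan"))
        for o, (x, y) in per_organ_xy.items()
    }
    return CircLinearResult(
        pairs=pairs,
        r_overall=r_overall,
        r_per_organ=r_per_organ,
        n_excluded=len(excluded),
        excluded_ids=excluded,
    )
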