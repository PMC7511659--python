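"""Candidate filtering chain and set analyses.

The chain mirrors standard circRNA practice: a minimum back-spliced read
support filter (evidence pooled over the replicates of a library type), a
two-caller confirmation (the secondary caller contributes only an id set),
an abundance threshold on replicate-averaged normalized values, and set
analyses — replicate reproducibility (Venn regions over four biological
replicates), nuclear/organelle genome partition, and organ-overlap sets.

All filters are row selections, so they commute; thresholds are inclusive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .model import DEFAULT_ORGANELLE_CHROMS, CircCountMatrix

__all__ = [
    "FilterReport",
    "filter_min_support",
    "intersect_callers",
    "VennResult",
    "replicate_reproducibility",
    "abundance_filter",
    "OverlapSets",
    "partition_and_overlap",
]


@dataclass
class FilterReport:
    """Bookkeeping for one filter stage: what went in, what survived."""

    stage: str
    n_in: int
    n_out: int
    removed: list

    def __post_init__(self) -> None:
        if self.n_out > self.n_in:
            raise ValueError("n_out cannot exceed n_in")
        if self.n_in - self.n_out != len(self.removed):
            raise ValueError("removed ids inconsistent with n_in - n_out")


def filter_min_support(counts: CircCountMatrix, k: int = 2,
                       per_replicate: bool = False):
    """Keep circRNAs supported by at least ``k`` back-spliced reads.

    By default the evidence is pooled over the replicates of each library
    type ((organ, protocol) group) and a circRNA survives when any one
    library type reaches ``k`` in summary. With ``per_replicate=True`` a
    single sample must reach ``k`` on its own.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if per_replicate:
        support = counts.counts.max(axis=1)
    else:
        groups: dict = {}
        for s in counts.samples:
            groups.setdefault(s.library_type, []).append(s.sample_id)
        pooled = pd.DataFrame(
            {str(g): counts.counts[cols].sum(axis=1) for g, cols in groups.items()}
        )
        support = pooled.max(axis=1)
    keep = support[support >= k].index
    removed = [cid for cid in counts.id_strings if cid not in set(keep)]
    out = counts.subset_ids(keep)
    report = FilterReport(
        stage=f"min_support(k={k}, per_replicate={per_replicate})",
        n_in=counts.n_circ, n_out=out.n_circ, removed=removed,
    )
    return out, report


def intersect_callers(primary: CircCountMatrix, confirm_ids):
    """Keep circRNAs confirmed by a second caller (exact coordinates).

    ``confirm_ids`` is a set of circRNA id strings from the confirming
    caller; counts are taken from the primary caller. An empty intersection
    is a warning, not an error.
    """
    confirm = {str(c) for c in confirm_ids}
    keep = [cid for cid in primary.id_strings if cid in confirm]
    removed = [cid for cid in primary.id_strings if cid not in confirm]
    if primary.n_circ and not keep:
        warnings.warn("no circRNA confirmed by the secondary caller", stacklevel=2)
    out = primary.subset_ids(keep)
    report = FilterReport(
        stage="intersect_callers", n_in=primary.n_circ, n_out=out.n_circ, removed=removed
    )
    return out, report


@dataclass
class VennResult:
    """Region counts for n-set overlap plus the fraction common to all sets.

    ``region_counts`` maps a membership tuple (one 0/1 per set, at least one
    1) to the number of elements exactly in that region; the counts sum to
    the size of the union.
    """

    region_counts: dict
    fraction_in_all: float
    n_union: int
    n_intersection: int


def replicate_reproducibility(per_replicate_sets) -> VennResult:
    """Venn decomposition of per-replicate detection sets.

    Designed for the four-biological-replicate layout (any number of sets
    is accepted). ``fraction_in_all`` is |intersection| / |union|, the share
    of candidates reproduced in every replicate.
    """
    sets = [set(s) for s in per_replicate_sets]
    if not sets:
        raise ValueError("need at least one set")
    union = set().union(*sets)
    inter = set.intersection(*sets) if sets else set()
    region_counts = {}
    for pattern in itertools.product((0, 1), repeat=len(sets)):
        if not any(pattern):
            continue
        region = union.copy()
        for s, bit in zip(sets, pattern):
            region = region & s if bit else region - s
        region_counts[pattern] = len(region)
    fraction = len(inter) / len(union) if union else 0.0
    return VennResult(
        region_counts=region_counts,
        fraction_in_all=fraction,
        n_union=len(union),
        n_intersection=len(inter),
    )


def abundance_filter(per_organ_means: pd.DataFrame, threshold: float = 10.0):
    """Detection sets from replicate-averaged normalized values.

    A circRNA passes for an organ when its mean is at least ``threshold``
    there ("at least" — the bound is inclusive). Returns ``(per_organ_sets,
    union)``; the union across organs defines the analysis set.

    The threshold lives on the normalized-read scale and must be calibrated
    for the scale constant in use (see
    :func:`circquant.concordance.calibrate_read_threshold`).
    """
    per_organ = {
        organ: set(per_organ_means.index[per_organ_means[organ] >= threshold])
        for organ in per_organ_means.columns
    }
    union = set().union(*per_organ.values()) if per_organ else set()
    return per_organ, union


@dataclass
class OverlapSets:
    """Genome partition and organ-overlap structure of a circRNA set."""

    nuclear: set
    organelle: set
    per_organ: dict
    ubiquitous: set = field(init=False)
    unique: dict = field(init=False)
    pairwise: dict = field(init=False)

    def __post_init__(self) -> None:
        organs = list(self.per_organ)
        sets = list(self.per_organ.values())
        self.ubiquitous = set.intersection(*sets) if sets else set()
        self.unique = {
            o: self.per_organ[o].difference(*(self.per_organ[p] for p in organs if p != o))
            if len(organs) > 1 else set(self.per_organ[o])
            for o in organs
        }
        self.pairwise = {
            (a, b): self.per_organ[a] & self.per_organ[b]
            for a, b in itertools.combinations(organs, 2)
        }

    def restrict(self, ids) -> "OverlapSets":
        ids = set(ids)
        return OverlapSets(
            nuclear=self.nuclear & ids,
            organelle=self.organelle & ids,
            per_organ={o: s & ids for o, s in self.per_organ.items()},
        )


def partition_and_overlap(circ_ids, per_organ_sets,
                          organelle_chroms=DEFAULT_ORGANELLE_CHROMS) -> OverlapSets:
    """Partition ids by genome of origin and compute organ-overlap sets.

    ``circ_ids`` are :class:`~circquant.model.CircId` objects; membership in
    the organelle partition is by chromosome name.
    """
    nuclear, organelle = set(), set()
    for cid in circ_ids:
        (organelle if cid.is_organelle(organelle_chroms) else nuclear).add(str(cid))
    return OverlapSets(
        nuclear=nuclear,
        organelle=organelle,
        per_organ={o: set(s) for o, s in per_organ_sets.items()},
    )
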