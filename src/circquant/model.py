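"""Domain types for circRNA back-splice junction quantification.

Coordinates are 1-based and fully closed, matching the ``chrom:start-end``
identifiers used throughout plant circRNA catalogues; conversion to BED
(0-based, half-open) happens only in the BED writer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CircId",
    "SampleMeta",
    "CircCountMatrix",
    "LibraryStats",
    "LinearCountMatrix",
    "CircIdError",
    "IntegrityError",
    "ORGANS",
    "DEFAULT_ORGANELLE_CHROMS",
    "parse_circ_id",
]

#: Sample types profiled in the reference experimental design.
ORGANS = ("seedling", "root", "leaf", "flower")

#: Chromosome names treated as organellar (chloroplast) by default.
DEFAULT_ORGANELLE_CHROMS = frozenset({"chloroplast", "Pt", "ChrC"})

_CIRC_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class CircIdError(ValueError):
    """Raised for malformed circRNA identifier strings."""


class IntegrityError(ValueError):
    """Raised when loaded data violate a structural invariant."""


@dataclass(frozen=True, order=True)
class CircId:
    """A back-splice junction interval, 1-based inclusive.

    The string form ``chrom:start-end`` round-trips through
    :func:`parse_circ_id`. Strand is carried for export but never used in
    quantification (back-spliced read counting is strand-agnostic).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default="unknown", compare=False)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CircIdError(f"coordinates must be >= 1: {self.chrom}:{self.start}-{self.end}")
        if self.start > self.end:
            raise CircIdError(
                f"start > end in circRNA id {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise CircIdError(f"invalid strand {self.strand!r}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def is_organelle(self, organelle_chroms=DEFAULT_ORGANELLE_CHROMS) -> bool:
        return self.chrom in organelle_chroms

    def to_bed_fields(self):
        """BED6 fields (0-based half-open); strand 'unknown' exports as '.'."""
        strand = self.strand if self.strand in ("+", "-") else "."
        return (self.chrom, self.start - 1, self.end, str(self), 0, strand)


def parse_circ_id(text: str) -> CircId:
    """Parse a ``chrom:start-end`` circRNA identifier.

    >>> parse_circ_id("5:1106879-1107381")
    CircId(chrom='5', start=1106879, end=1107381)
    """
    m = _CIRC_ID_RE.match(text.strip())
    if m is None:
        raise CircIdError(f"malformed circRNA id {text!r}; expected 'chrom:start-end'")
    return CircId(chrom=m.group("chrom"), start=int(m.group("start")), end=int(m.group("end")))


def _canon_protocol(protocol: str) -> str:
    # accept the typographic minus used in print
    p = protocol.replace("−", "-").replace("–", "-")
    if p not in ("R-", "R+"):
        raise ValueError(f"protocol must be 'R-' or 'R+', got {protocol!r}")
    return p


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: organ, biological replicate and protocol.

    ``protocol`` is ``"R-"`` (rRNA-depleted only) or ``"R+"`` (rRNA-depleted
    then RNase R-treated).
    """

    sample_id: str
    organ: str
    replicate: int
    protocol: str = "R-"

    def __post_init__(self) -> None:
        object.__setattr__(self, "protocol", _canon_protocol(self.protocol))
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")

    @property
    def library_type(self):
        """(organ, protocol) — replicates of one library preparation."""
        return (self.organ, self.protocol)


def _check_unique_samples(samples) -> None:
    keys = [(s.organ, s.replicate, s.protocol) for s in samples]
    if len(set(keys)) != len(keys):
        raise IntegrityError("duplicate (organ, replicate, protocol) among samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate sample_id among samples")


@dataclass
class CircCountMatrix:
    """Raw back-spliced read counts, circRNA x sample.

    ``counts`` is an integer DataFrame indexed by the string form of each
    :class:`CircId`, with one column per ``sample_id``. ``caller_support``
    maps each circRNA id string to the set of caller names that reported it.
    """

    circ_ids: list
    samples: list
    counts: pd.DataFrame
    caller_support: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique_samples(self.samples)
        id_strings = [str(c) for c in self.circ_ids]
        if len(set(id_strings)) != len(id_strings):
            raise IntegrityError("duplicate circRNA ids")
        if list(self.counts.index) != id_strings:
            raise IntegrityError("counts index does not match circ_ids")
        if list(self.counts.columns) != [s.sample_id for s in self.samples]:
            raise IntegrityError("counts columns do not match samples")
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.allclose(arr, np.round(arr)):
                raise IntegrityError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise IntegrityError("counts must be non-negative")
        self.caller_support = {
            cid: frozenset(self.caller_support.get(cid, frozenset())) for cid in id_strings
        }

    @property
    def id_strings(self):
        return [str(c) for c in self.circ_ids]

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_by_id(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset_ids(self, keep) -> "CircCountMatrix":
        """Row-select by circRNA id strings, preserving current order."""
        keep = set(keep)
        mask = [cid in keep for cid in self.id_strings]
        circ_ids = [c for c, m in zip(self.circ_ids, mask) if m]
        return CircCountMatrix(
            circ_ids=circ_ids,
            samples=list(self.samples),
            counts=self.counts.loc[[str(c) for c in circ_ids]].copy(),
            caller_support={str(c): self.caller_support[str(c)] for c in circ_ids},
        )

    def organ_columns(self, organ: str):
        return [s.sample_id for s in self.samples if s.organ == organ]


#: Canonical LibraryStats column names (per-sample denominators).
LIBRARY_STAT_COLUMNS = (
    "total_reads",
    "rrna_reads",
    "chloroplast_reads",
    "marker_reads",
    "backspliced_reads",
    "backspliced_reads_excl",
)


@dataclass
class LibraryStats:
    """Per-library denominators used by the normalization methods.

    Columns (index = sample_id):

    - ``total_reads`` (T): filtered reads in the library
    - ``rrna_reads`` (R): reads mapped to rRNA
    - ``chloroplast_reads`` (P): reads mapped to the chloroplast genome
    - ``marker_reads`` (A): raw reads mapped to the endogenous marker gene
      (ACT2 / AT3G18780 in the reference design)
    - ``backspliced_reads`` (B): total back-spliced reads
    - ``backspliced_reads_excl`` (B'): back-spliced reads excluding rRNA-
      and chloroplast-derived circRNAs
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_STAT_COLUMNS if c not in self.table.columns]
        if missing:
            raise IntegrityError(f"LibraryStats missing columns: {missing}")
        t = self.table
        if (t[list(LIBRARY_STAT_COLUMNS)] < 0).any().any():
            raise IntegrityError("LibraryStats values must be non-negative")
        bad = t.index[t["rrna_reads"] + t["chloroplast_reads"] > t["total_reads"]]
        if len(bad):
            raise IntegrityError(f"rRNA + chloroplast reads exceed total reads for {list(bad)}")
        bad = t.index[t["backspliced_reads_excl"] > t["backspliced_reads"]]
        if len(bad):
            raise IntegrityError(f"B' exceeds B for {list(bad)}")

    def __getitem__(self, column: str) -> pd.Series:
        return self.table[column]

    @property
    def sample_ids(self):
        return list(self.table.index)


@dataclass
class LinearCountMatrix:
    """Normalized linear-transcript abundances, parent gene x sample/organ.

    ``method`` optionally records the normalization tag so circular-vs-linear
    comparisons can verify that both matrices are on a comparable scale.
    """

    abundances: pd.DataFrame
    method: str | None = None

    def __post_init__(self) -> None:
        arr = self.abundances.to_numpy(dtype=float)
        if arr.size and (arr[~np.isnan(arr)] < 0).any():
            raise IntegrityError("linear abundances must be non-negative")

    @property
    def gene_ids(self):
        return list(self.abundances.index)
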