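"""Readers and writers for caller tables, library statistics and results.

Inputs are plain TSV (CIRI2-style candidate tables, per-library composition
statistics, droplet counts); outputs are deterministic TSVs plus a YAML
run-metadata file recording method tags, scale constants, thresholds and
seeds so that a run can be reproduced exactly.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    LIBRARY_STAT_COLUMNS,
    CircCountMatrix,
    CircId,
    IntegrityError,
    LibraryStats,
    SampleMeta,
    parse_circ_id,
)

__all__ = [
    "read_caller_table",
    "read_library_stats",
    "read_ddpcr_table",
    "merge_caller_tables",
    "write_results",
    "write_bed",
]

_SAMPLE_ID_RE = re.compile(r"^(?P<organ>[A-Za-z]+)_r(?P<rep>\d+)_(?P<proto>R[+-])$")


def infer_sample_meta(sample_id: str) -> SampleMeta:
    """Build a :class:`SampleMeta` from an ``organ_rN_R[+-]`` style id.

    Ids that do not follow the convention are kept opaque (the id itself is
    used as the organ label, replicate 1, protocol R-).
    """
    m = _SAMPLE_ID_RE.match(sample_id)
    if m:
        return SampleMeta(sample_id, m.group("organ"), int(m.group("rep")), m.group("proto"))
    return SampleMeta(sample_id, organ=sample_id, replicate=1, protocol="R-")


def _coerce_counts(frame: pd.DataFrame, path) -> pd.DataFrame:
    arr = frame.to_numpy()
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = frame.columns[numeric.isna().any()].tolist()
        raise IntegrityError(f"{path}: non-numeric counts in columns {bad}")
    arr = numeric.to_numpy(dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise IntegrityError(f"{path}: counts must be integers")
    if (arr < 0).any():
        raise IntegrityError(f"{path}: negative counts are not allowed")
    return numeric.round().astype(np.int64)


def read_caller_table(path, caller_name: str, samples=None) -> CircCountMatrix:
    """Read a back-splice caller candidate table into a count matrix.

    The TSV must carry either a ``circ_id`` column (``chrom:start-end``) or
    ``chrom``/``start``/``end`` columns; every remaining column (except an
    optional ``strand``) is taken as the junction-read count for one sample.
    Duplicate rows for the same coordinates are merged by summing counts.

    Parameters
    ----------
    caller_name:
        Recorded in ``caller_support`` for every circRNA in the file.
    samples:
        Optional explicit list of :class:`SampleMeta` matching the count
        columns; by default metadata are inferred from ``organ_rN_R[+-]``
        column names.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "circ_id" in df.columns:
        ids = [parse_circ_id(t) for t in df["circ_id"]]
        count_cols = [c for c in df.columns if c not in ("circ_id", "strand")]
    elif {"chrom", "start", "end"}.issubset(df.columns):
        strands = df["strand"] if "strand" in df.columns else ["unknown"] * len(df)
        ids = [
            CircId(str(c), int(s), int(e), str(st) if st in ("+", "-") else "unknown")
            for c, s, e, st in zip(df["chrom"], df["start"], df["end"], strands)
        ]
        count_cols = [c for c in df.columns if c not in ("chrom", "start", "end", "strand")]
    else:
        raise IntegrityError(
            f"{path}: need a 'circ_id' column or 'chrom'/'start'/'end' columns"
        )
    if not count_cols:
        raise IntegrityError(f"{path}: no count columns found")

    counts = _coerce_counts(df[count_cols], path)
    counts.index = [str(i) for i in ids]
    # merge duplicate coordinates by summing
    if counts.index.has_duplicates:
        counts = counts.groupby(level=0, sort=False).sum()
    id_map = {}
    for cid in ids:
        id_map.setdefault(str(cid), cid)
    circ_ids = [id_map[s] for s in counts.index]

    if samples is None:
        samples = [infer_sample_meta(c) for c in count_cols]
    elif [s.sample_id for s in samples] != count_cols:
        raise IntegrityError(f"{path}: sample list does not match count columns {count_cols}")
    support = {str(c): frozenset({caller_name}) for c in circ_ids}
    return CircCountMatrix(circ_ids=circ_ids, samples=samples, counts=counts, caller_support=support)


def merge_caller_tables(*matrices: CircCountMatrix) -> CircCountMatrix:
    """Union caller tables over exact coordinates.

    Counts are taken from the first table that reports each circRNA (the
    primary caller, by convention, is passed first); ``caller_support`` is
    the union over all tables and is independent of the argument order.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if [s.sample_id for s in m.samples] != [s.sample_id for s in first.samples]:
            raise IntegrityError("caller tables must share the same samples to merge")
    seen: dict = {}
    circ_ids = []
    rows = []
    support: dict = {}
    for m in matrices:
        for cid in m.circ_ids:
            key = str(cid)
            if key not in seen:
                seen[key] = True
                circ_ids.append(cid)
                rows.append(m.counts.loc[key])
            support.setdefault(key, set())
            support[key] |= set(m.caller_support.get(key, ()))
    counts = pd.DataFrame(rows, index=[str(c) for c in circ_ids])
    return CircCountMatrix(
        circ_ids=circ_ids,
        samples=list(first.samples),
        counts=counts,
        caller_support={k: frozenset(v) for k, v in support.items()},
    )


def read_library_stats(path) -> LibraryStats:
    """Read the per-library denominator table (keyed by ``sample_id``).

    Structural invariants (R + P <= T, B' <= B, non-negativity) are verified
    on load and raise :class:`IntegrityError` naming the offending sample.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise IntegrityError(f"{path}: missing 'sample_id' column")
    missing = [c for c in LIBRARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing columns {missing}")
    df = df.set_index("sample_id")
    return LibraryStats(df[list(LIBRARY_STAT_COLUMNS)].astype(float))


def read_ddpcr_table(path) -> pd.DataFrame:
    """Read a ddPCR measurement table.

    Required columns: ``target``, ``organ``, ``replicate`` and either droplet
    counts (``n_pos``, ``n_total``) or a pre-computed ``cp_per_ug``. Optional:
    ``is_marker`` (reference-gene rows) and ``technical_rep``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"target", "organ", "replicate"}
    if not required.issubset(df.columns):
        raise IntegrityError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    has_droplets = {"n_pos", "n_total"}.issubset(df.columns)
    if not has_droplets and "cp_per_ug" not in df.columns:
        raise IntegrityError(f"{path}: need n_pos/n_total or cp_per_ug")
    if has_droplets:
        if (df["n_pos"] < 0).any() or (df["n_pos"] > df["n_total"]).any():
            raise IntegrityError(f"{path}: require 0 <= n_pos <= n_total")
    if "is_marker" not in df.columns:
        df["is_marker"] = False
    return df


def _float_formatter(significant_digits: int):
    fmt = f"%.{significant_digits}g"

    def render(x):
        return fmt % x

    return render


def write_results(tables: dict, out_dir, metadata: dict | None = None,
                  significant_digits: int = 4) -> list:
    """Write result tables as deterministic TSVs plus run metadata.

    Floats are rendered with a fixed number of significant digits (default
    4); two runs with identical inputs produce byte-identical files.
    ``metadata`` (method tags, scale constants, thresholds, seed) is written
    to ``run_metadata.yaml`` with sorted keys.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    fmt = f"%.{significant_digits}g"
    for name, table in sorted(tables.items()):
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", float_format=fmt, lineterminator="\n")
        written.append(path)
    meta = dict(metadata or {})
    meta.setdefault("significant_digits", significant_digits)
    meta_path = out / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    written.append(meta_path)
    return written


def write_bed(circ_ids, path) -> None:
    """Export circRNA intervals as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        for cid in circ_ids:
            fields = cid.to_bed_fields()
            fh.write("\t".join(str(f) for f in fields) + "\n")
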