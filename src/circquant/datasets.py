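"""Packaged reference data.

``load_benchmark_panel`` returns the published 8-circRNA x 4-sample-type
benchmark: ddPCR means (cp/ug, 3 biological replicates) and the matching
normalized RNA-seq read values under all six normalization schemes. It is
the anchor for concordance evaluation and for the ddPCR reliability flags.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .normalize import NormMethod

__all__ = ["load_benchmark_panel", "BENCHMARK_METHOD_COLUMNS"]

#: Column name per normalization method in the benchmark panel.
BENCHMARK_METHOD_COLUMNS = {
    NormMethod.library_size: "library_size",
    NormMethod.backspliced_sum: "backspliced_sum",
    NormMethod.size_factor: "size_factor",
    NormMethod.library_size_excl: "library_size_excl",
    NormMethod.backspliced_sum_excl: "backspliced_sum_excl",
    NormMethod.marker_gene: "marker_gene",
}


def load_benchmark_panel() -> pd.DataFrame:
    """Load the ddPCR-anchored benchmark panel (32 rows).

    Columns: ``name`` (A-H), ``circ_id``, ``organ``, ``cp_per_ug`` and
    ``sd`` (ddPCR mean +/- sample sd over 3 biological replicates), then one
    column per normalization scheme with the mean normalized read value over
    4 biological replicates.
    """
    with resources.files("circquant.fixtures").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
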