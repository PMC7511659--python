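import numpy as np
import pandas as pd
import pytest

from circquant import CircCountMatrix, CircId, LibraryStats, SampleMeta


def build_matrix(arr, organ_reps=None, protocol="R-", chroms=None):
    """Toy count matrix; rows become synthetic nuclear circRNAs."""
    arr = np.asarray(arr, dtype=np.int64)
    if arr.ndim == 1:
        arr = arr[:, None]
    n_circ, n_samp = arr.shape
    if organ_reps is None:
        organ_reps = [("root", j + 1) for j in range(n_samp)]
    samples = [SampleMeta(f"{o}_r{r}_{protocol}", o, r, protocol) for o, r in organ_reps]
    chroms = chroms or ["1"] * n_circ
    ids = [CircId(chroms[i], 1000 * (i + 1), 1000 * (i + 1) + 500) for i in range(n_circ)]
    counts = pd.DataFrame(arr, index=[str(c) for c in ids],
                          columns=[s.sample_id for s in samples])
    return CircCountMatrix(circ_ids=ids, samples=samples, counts=counts)


def build_stats(matrix, total=1_000_000, rrna=10_000, chloro=20_000, marker=5_000,
                backspliced=None, backspliced_excl=None):
    """LibraryStats consistent with a toy matrix (same denominators everywhere)."""
    col_sums = matrix.counts.sum(axis=0)
    rows = {}
    for s in matrix.samples:
        b = backspliced if backspliced is not None else max(int(col_sums[s.sample_id]), 1)
        rows[s.sample_id] = {
            "total_reads": float(total),
            "rrna_reads": float(rrna),
            "chloroplast_reads": float(chloro),
            "marker_reads": float(marker),
            "backspliced_reads": float(b),
            "backspliced_reads_excl": float(backspliced_excl if backspliced_excl is not None else b),
        }
    return LibraryStats(pd.DataFrame(rows).T)


@pytest.fixture
def matrix_factory():
    return build_matrix


@pytest.fixture
def stats_factory():
    return build_stats


@pytest.fixture
def four_rep_matrix():
    """2 organs x 4 replicates, 3 circRNAs with distinct profiles."""
    rng = np.random.default_rng(11)
    arr = rng.poisson([[40], [12], [5]] * np.ones((3, 8))).astype(np.int64)
    organ_reps = [("root", r) for r in range(1, 5)] + [("leaf", r) for r in range(1, 5)]
    return build_matrix(arr, organ_reps)
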