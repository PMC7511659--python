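"""Pairwise organ comparisons, abundance classes, clustering, circ-vs-linear."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import circquant as cq
from circquant.model import LinearCountMatrix
from circquant.normalize import NormalizedMatrix, NormMethod
from circquant.model import SampleMeta


def norm_from_array(arr, organs=("root", "leaf"), n_reps=4, method=NormMethod.library_size):
    arr = np.asarray(arr, dtype=float)
    samples = [SampleMeta(f"{o}_r{r}_R-", o, r) for o in organs for r in range(1, n_reps + 1)]
    df = pd.DataFrame(arr, index=[f"c{i}" for i in range(arr.shape[0])],
                      columns=[s.sample_id for s in samples])
    return NormalizedMatrix(values=df, samples=samples, method=method, scale=1.0)


class TestPairwiseDiff:
    def test_identical_replicates_not_significant(self):
        row = [10, 12, 9, 11] * 2
        norm = norm_from_array([row])
        res = cq.pairwise_diff(norm, "root", "leaf")
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)
        assert not res["significant"].iloc[0]

    def test_forced_fourfold_effect_is_significant(self):
        rng = np.random.default_rng(1)
        a = 100 + rng.normal(0, 1e-6, 4)
        b = 25 + rng.normal(0, 1e-6, 4)
        norm = norm_from_array([np.concatenate([a, b])])
        res = cq.pairwise_diff(norm, "root", "leaf")
        assert res["log2fc"].iloc[0] == pytest.approx(2.0, abs=0.05)
        assert bool(res["significant"].iloc[0])

    def test_single_replicate_reports_fc_without_p(self):
        norm = norm_from_array([[40.0, 10.0]], organs=("root", "leaf"), n_reps=1)
        res = cq.pairwise_diff(norm, "root", "leaf")
        assert res["log2fc"].iloc[0] == pytest.approx(math.log2(40.5 / 10.5))
        assert np.isnan(res["p_value"].iloc[0])
        assert not res["significant"].iloc[0]

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        norm = norm_from_array(np.exp(rng.normal(3, 1, size=(200, 8))))
        ab = cq.pairwise_diff(norm, "root", "leaf")
        ba = cq.pairwise_diff(norm, "leaf", "root")
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p_value"], ba["p_value"])
        assert (ab["significant"] == ba["significant"]).all()

    def test_analysis_set_restriction(self):
        rng = np.random.default_rng(2)
        norm = norm_from_array(np.exp(rng.normal(3, 1, size=(10, 8))))
        res = cq.pairwise_diff(norm, "root", "leaf", analysis_ids={"c1", "c5"})
        assert list(res.index) == ["c1", "c5"]

    def test_null_type_one_error_rate(self):
        """Same lognormal in both organs: p <= 0.05 calls near nominal."""
        null = cq.simulate_null_matrix(n_circ=1000, seed=3)
        res = cq.pairwise_diff(null, "organ_a", "organ_b")
        rate = float((res["p_value"] <= 0.05).mean())
        assert 0.02 <= rate <= 0.08


class TestCountDiffByPair:
    def test_all_zero_when_nothing_significant(self):
        rng = np.random.default_rng(7)
        norm = norm_from_array(np.full((5, 8), 10.0) + rng.normal(0, 0.5, (5, 8)))
        results = cq.all_pairs_diff(norm)
        counts = cq.count_diff_by_pair(results)
        assert (counts[["up", "down"]].to_numpy() == 0).all()

    def test_up_down_antisymmetry(self):
        rng = np.random.default_rng(8)
        arr = np.exp(rng.normal(2.0, 1.5, size=(300, 8)))
        norm = norm_from_array(arr)
        ab = cq.pairwise_diff(norm, "root", "leaf")
        ba = cq.pairwise_diff(norm, "leaf", "root")
        counts = cq.count_diff_by_pair({("root", "leaf"): ab, ("leaf", "root"): ba})
        up_ab = counts.set_index(["organ_a", "organ_b"]).loc[("root", "leaf"), "up"]
        down_ba = counts.set_index(["organ_a", "organ_b"]).loc[("leaf", "root"), "down"]
        assert up_ab == down_ba

    def test_planted_up_counts(self):
        base = np.full((40, 8), 20.0)
        rng = np.random.default_rng(9)
        base *= np.exp(rng.normal(0, 0.05, base.shape))
        base[:16, :4] *= 8.0  # exactly 16 circles raised in the first organ
        norm = norm_from_array(base)
        res = cq.pairwise_diff(norm, "root", "leaf")
        counts = cq.count_diff_by_pair({("root", "leaf"): res})
        assert counts.loc[0, "up"] == 16 and counts.loc[0, "down"] == 0


class TestClassifyAbundance:
    def test_twenty_equal_spaced_values(self):
        means = pd.DataFrame({"root": np.arange(1.0, 21.0)},
                             index=[f"c{i}" for i in range(20)])
        classes = cq.classify_abundance(means)
        vc = classes["root"].value_counts()
        assert vc.get("high", 0) == 1
        assert vc.get("medium", 0) == 3
        assert vc.get("low", 0) == 16

    def test_partition_counts_on_random_data(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(1, 400))
            means = pd.DataFrame({"root": np.exp(rng.normal(2, 1, n))},
                                 index=[f"c{i}" for i in range(n)])
            classes = cq.classify_abundance(means)["root"]
            vc = classes.value_counts()
            n_detected = int((means["root"] > 0).sum())
            assert vc.get("high", 0) == math.ceil(0.05 * n_detected)
            assert vc.get("high", 0) + vc.get("medium", 0) + vc.get("low", 0) == n_detected

    def test_ties_resolved_deterministically(self):
        means = pd.DataFrame({"root": np.full(40, 7.0)},
                             index=[f"c{i}" for i in range(40)])
        a = cq.classify_abundance(means)
        b = cq.classify_abundance(means)
        assert a.equals(b)
        assert (a["root"] == "high").sum() == math.ceil(0.05 * 40)
        # first rows in stable order take the high slots
        assert a["root"].iloc[0] == "high" and a["root"].iloc[1] == "high"

    def test_absent_is_not_detected_regardless_of_other_organs(self):
        means = pd.DataFrame(
            {"root": [50.0, 10.0, 5.0], "leaf": [0.0, 12.0, 3.0]},
            index=["a", "b", "c"],
        )
        classes = cq.classify_abundance(means)
        assert classes.loc["a", "leaf"] == "not_detected"
        assert classes.loc["a", "root"] == "high"


def brute_force_average_linkage_merges(mat):
    """Naive agglomeration on Euclidean distances; returns merged member sets."""
    clusters = {i: frozenset([i]) for i in range(len(mat))}
    merges = []
    next_id = len(mat)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([
                np.linalg.norm(mat[i] - mat[j])
                for i in clusters[a] for j in clusters[b]
            ])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append({clusters[a], clusters[b]})
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return merges


class TestClusterOrder:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(13)
        arr = np.exp(rng.normal(3, 1, size=(6, 4)))
        arr[4] = arr[1]
        means = pd.DataFrame(arr, index=[f"c{i}" for i in range(6)],
                             columns=["seedling", "root", "leaf", "flower"])
        order = cq.cluster_order(means)
        assert abs(order.index("c1") - order.index("c4")) == 1

    def test_separated_blocks_stay_contiguous(self):
        rng = np.random.default_rng(14)
        low = np.exp(rng.normal(0.5, 0.1, size=(5, 3)))
        high = np.exp(rng.normal(6.0, 0.1, size=(5, 3)))
        means = pd.DataFrame(np.vstack([low, high]),
                             index=[f"c{i}" for i in range(10)],
                             columns=["root", "leaf", "flower"])
        order = cq.cluster_order(means)
        positions = [order.index(f"c{i}") for i in range(5)]
        assert max(positions) - min(positions) == 4  # low block contiguous

    def test_merge_sequence_matches_brute_force(self):
        rng = np.random.default_rng(15)
        arr = np.exp(rng.normal(2, 1.2, size=(6, 4)))
        means = pd.DataFrame(arr, index=[f"c{i}" for i in range(6)],
                             columns=["seedling", "root", "leaf", "flower"])
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import pdist

        log = np.log2(arr + 1.0)
        link = hierarchy.linkage(pdist(log), method="average")
        members = {i: frozenset([i]) for i in range(6)}
        scipy_merges = []
        for k, (a, b, _, _) in enumerate(link):
            a, b = int(a), int(b)
            scipy_merges.append({members[a], members[b]})
            members[6 + k] = members[a] | members[b]
        assert scipy_merges == brute_force_average_linkage_merges(log)
        # and the public ordering is a permutation consistent with the tree
        order = cq.cluster_order(means)
        assert sorted(order) == sorted(means.index)

    def test_single_row_is_trivial(self):
        means = pd.DataFrame({"root": [1.0]}, index=["only"])
        assert cq.cluster_order(means) == ["only"]


class TestCircLinear:
    ORGANS = ["seedling", "root", "leaf", "flower"]

    def _means(self, arr, ids):
        return pd.DataFrame(arr, index=ids, columns=self.ORGANS)

    def test_identical_profiles_give_unit_correlation(self):
        rng = np.random.default_rng(16)
        arr = np.exp(rng.normal(3, 1, size=(8, 4)))
        circ = self._means(arr, [f"c{i}" for i in range(8)])
        linear = LinearCountMatrix(self._means(arr.copy(), [f"g{i}" for i in range(8)]))
        mapping = {f"c{i}": f"g{i}" for i in range(8)}
        res = cq.circ_linear_analysis(circ, linear, mapping)
        assert res.r_overall == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in res.r_per_organ.values())
        assert not res.pairs["enriched"].any()  # ratio exactly 1 < 1.5

    def test_enrichment_rule_fires_on_single_organ(self):
        circ = self._means([[3.0, 0.0, 0.0, 0.0]], ["c0"])
        linear = LinearCountMatrix(self._means([[1.0, 10.0, 10.0, 10.0]], ["g0"]))
        res = cq.circ_linear_analysis(circ, linear, {"c0": "g0"})
        assert bool(res.pairs.loc["c0", "enriched"])  # 3 >= 1.5 * 1 in one organ

    def test_intergenic_excluded_from_correlation_kept_in_table(self):
        rng = np.random.default_rng(18)
        arr = np.exp(rng.normal(3, 1, size=(6, 4)))
        circ = self._means(arr, [f"c{i}" for i in range(6)])
        linear = LinearCountMatrix(self._means(arr[:5] * 2.0, [f"g{i}" for i in range(5)]))
        mapping = {f"c{i}": f"g{i}" for i in range(5)}  # c5 intergenic
        res = cq.circ_linear_analysis(circ, linear, mapping)
        assert res.n_excluded == 1 and res.excluded_ids == ["c5"]
        assert "c5" in res.pairs.index
        assert np.isnan(res.pairs.loc["c5", "ratio_root"])

    def test_mismatched_normalization_refused(self):
        circ = self._means([[1.0, 1.0, 1.0, 1.0]] * 3, ["c0", "c1", "c2"])
        linear = LinearCountMatrix(
            self._means([[1.0] * 4] * 3, ["g0", "g1", "g2"]), method="backspliced_sum"
        )
        with pytest.raises(ValueError, match="mismatch"):
            cq.circ_linear_analysis(circ, linear, {f"c{i}": f"g{i}" for i in range(3)},
                                    circ_method="library_size")


class TestOrganSpecificSets:
    def test_planted_organ_specific_detected(self):
        rng = np.random.default_rng(19)
        organs = ("seedling", "root", "leaf", "flower")
        arr = np.full((30, 16), 20.0) * np.exp(rng.normal(0, 0.1, (30, 16)))
        arr[:3, 4:8] *= 10.0  # three root-specific circles
        norm = norm_from_array(arr, organs=organs)
        results = cq.all_pairs_diff(norm, organs=list(organs))
        calls = cq.organ_specific_sets(results, organs)
        assert calls["root"] == {"c0", "c1", "c2"}
        assert all(not calls[o] for o in organs if o != "root")
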