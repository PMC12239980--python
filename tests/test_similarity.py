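"""Jaccard/concordance arithmetic, tiering, trajectory rule, clustering."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from correaevo.similarity import (
    assign_tier,
    classify_trajectory,
    cluster_cases,
    concordance_with_egc,
    genetic_distance,
    jaccard,
    linkage_to_newick,
    patient_similarity,
)

sets_of_ints = st.frozensets(st.integers(0, 40), max_size=25)


class TestSetStatistics:
    def test_jaccard_examples(self):
        assert jaccard({1, 2, 3}, {1, 2, 3}) == 1.0
        assert jaccard({1, 2}, {3, 4}) == 0.0
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == 0.5

    def test_empty_sets_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            assert jaccard(frozenset(), frozenset()) == 0.0

    def test_genetic_distance_examples(self):
        assert genetic_distance({1, 2, 3}, {1, 2, 3}) == 0
        assert genetic_distance({"A", "B", "C"}, {"B", "C", "D"}) == 2

    @given(a=sets_of_ints, b=sets_of_ints)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_jaccard_distance_relation(self, a, b):
        union = len(a | b)
        if union:
            assert jaccard(a, b) == pytest.approx(
                1.0 - genetic_distance(a, b) / union)

    @given(a=sets_of_ints, b=sets_of_ints, c=sets_of_ints)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_distance_triangle_inequality(self, a, b, c):
        assert genetic_distance(a, c) <= \
            genetic_distance(a, b) + genetic_distance(b, c)


def sets_with_overlap(shared, a_only, b_only):
    a = {f"s{i}" for i in range(shared)} | {f"a{i}" for i in range(a_only)}
    b = {f"s{i}" for i in range(shared)} | {f"b{i}" for i in range(b_only)}
    return a, b


class TestConcordance:
    @pytest.mark.parametrize("shared,union,expected", [
        # mutation level: IM, LGIN, HGIN vs EGC
        (73, 3821, 1.91), (904, 4259, 21.23), (955, 3487, 27.39),
        # CNV level
        (658, 15220, 4.32), (919, 7638, 12.03), (950, 10334, 9.19),
    ])
    def test_stagewise_concordance_percentages(self, shared, union, expected):
        a, b = sets_with_overlap(shared, union - shared, 0)
        got_shared, got_union, pct = concordance_with_egc(a, b)
        assert (got_shared, got_union) == (shared, union)
        assert pct == expected

    def test_identical_sets_give_hundred_percent(self):
        a, b = sets_with_overlap(10, 0, 0)
        assert concordance_with_egc(a, b)[2] == 100.00

    def test_empty_union_flagged(self):
        with pytest.warns(UserWarning):
            _, _, pct = concordance_with_egc(set(), set())
        assert np.isnan(pct)


class TestTierAssignment:
    @pytest.mark.parametrize("conc,tier,n", [
        ({"IM": 1.0, "LGIN": 22.0, "HGIN": 25.0}, "CT1", 2),
        ({"IM": 1.0, "LGIN": 5.0, "HGIN": 21.0}, "CT2", 1),
        ({"IM": 19.99, "LGIN": 19.99, "HGIN": 19.99}, "CT3", 0),
        ({"IM": 20.0, "LGIN": 20.0, "HGIN": 0.0}, "CT1", 2),  # boundary >=
    ])
    def test_ct_rule(self, conc, tier, n):
        result = assign_tier(conc)
        assert (result.tier, result.n_similar_stages) == (tier, n)

    def test_missing_stage_named_in_error(self):
        with pytest.raises(ValueError, match="HGIN"):
            assign_tier({"IM": 5.0, "LGIN": 10.0})

    def test_raising_threshold_is_monotone_toward_ct3(self, rng):
        order = {"CT1": 0, "CT2": 1, "CT3": 2}
        for _ in range(100):
            conc = {s: float(rng.uniform(0, 60)) for s in ("IM", "LGIN", "HGIN")}
            low = assign_tier(conc, threshold=15.0)
            high = assign_tier(conc, threshold=30.0)
            assert order[high.tier] >= order[low.tier]


class TestTrajectoryRule:
    @pytest.mark.parametrize("triple,model", [
        ((0.10, 0.40, 0.30), "linear"),
        ((0.40, 0.10, 0.30), "punctuated"),
        ((0.05, 0.05, 0.50), "independent"),
        ((0.20, 0.20, 0.10), "linear"),       # J_HE == J_LE resolves linear
        ((0.05, 0.05, 0.05), "linear"),       # tie with J_LH resolves non-independent
    ])
    def test_rule_examples(self, triple, model):
        assert classify_trajectory(*triple, floor=0.15).model == model

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_trajectory(1.2, 0.1, 0.1)

    @given(j_le=st.floats(0, 1).map(lambda x: round(x, 3)),
           j_he=st.floats(0, 1).map(lambda x: round(x, 3)),
           j_lh=st.floats(0, 1).map(lambda x: round(x, 3)),
           c=st.floats(0.05, 1.0).map(lambda x: round(x, 3)))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_scale_free(self, j_le, j_he, j_lh, c):
        base = classify_trajectory(j_le, j_he, j_lh, floor=0.15)
        scaled = classify_trajectory(c * j_le, c * j_he, c * j_lh,
                                     floor=c * 0.15)
        assert scaled.model == base.model


def brute_force_average_linkage(points):
    """O(n^3) agglomerative average linkage on Euclidean distances."""
    clusters = {i: [i] for i in range(len(points))}
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(points)) for j in range(i + 1, len(points))
    }

    def d(ci, cj):
        members_i, members_j = clusters[ci], clusters[cj]
        return float(np.mean([
            np.linalg.norm(points[a] - points[b])
            for a in members_i for b in members_j]))

    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = min(((d(i, j), i, j) for i in clusters for j in clusters
                    if i < j))
        h, i, j = best
        heights.append(h)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return heights


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        df = pd.DataFrame([[10.0, 20.0, 30.0]] * 2 + [[50.0, 60.0, 70.0]],
                          index=["P01", "P02", "P03"],
                          columns=["IM", "LGIN", "HGIN"])
        result = cluster_cases(df, n_clusters=2)
        assert result.linkage[0, 2] == 0.0
        assert result.flat_clusters["P01"] == result.flat_clusters["P02"]

    def test_outlier_joins_last(self):
        rows = [[1.0, 1.0], [1.2, 1.1], [0.9, 1.05], [50.0, 60.0]]
        df = pd.DataFrame(rows, index=list("abcd"), columns=["x", "y"])
        result = cluster_cases(df)
        assert result.leaf_order[0] == "d" or result.leaf_order[-1] == "d"
        # the final merge's height involves the outlier's large distance
        assert result.linkage[-1, 2] > 10

    def test_linkage_heights_match_brute_force(self, rng):
        points = rng.uniform(0, 100, size=(10, 3))
        df = pd.DataFrame(points, index=[f"P{i:02d}" for i in range(10)],
                          columns=["IM", "LGIN", "HGIN"])
        result = cluster_cases(df)
        expected = brute_force_average_linkage(points)
        assert np.allclose(sorted(result.linkage[:, 2]), sorted(expected))

    def test_nan_cells_rejected_naming_patients(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]], index=["P09", "P10"],
                          columns=["IM", "LGIN"])
        with pytest.raises(ValueError, match="P09"):
            cluster_cases(df)

    def test_newick_export_parses(self, rng):
        from Bio import Phylo
        points = rng.uniform(0, 10, size=(5, 2))
        df = pd.DataFrame(points, index=[f"P{i}" for i in range(5)],
                          columns=["a", "b"])
        result = cluster_cases(df)
        newick = linkage_to_newick(result.linkage, list(df.index))
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == \
            sorted(df.index)


class TestPatientSimilarity:
    def test_normal_subtraction_removes_artifact_sharing(self, small_cohort):
        cohort, _ = small_cohort
        patient = cohort[0]
        with_nm = patient_similarity(patient, subtract_normal=True)
        without = patient_similarity(patient, subtract_normal=False)
        nm_keys = patient.samples["NM"].variant_keys()
        if nm_keys:  # artifacts shared across all stages inflate similarity
            assert without.pairwise_jaccard[("IM", "EGC")] >= \
                with_nm.pairwise_jaccard[("IM", "EGC")]

    def test_symmetry_and_self_consistency(self, small_cohort):
        cohort, _ = small_cohort
        result = patient_similarity(cohort[1])
        for (a, b), j in result.pairwise_jaccard.items():
            assert result.pairwise_jaccard[(b, a)] == j
            assert 0.0 <= j <= 1.0
        for stage, (shared, union) in result.shared_counts.items():
            assert result.concordance_with_egc[stage] == pytest.approx(
                round(100.0 * shared / union, 2))
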