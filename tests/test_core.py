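"""Containers, readers/writers and table-level preprocessing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from riparia.core import (
    CommunityTable,
    DistanceMatrix,
    PhyloTree,
    SampleFrame,
    alpha_diversity,
    bray_curtis,
    prevalence_filter,
    rarefy,
)
from riparia import io as rio


# ---------------------------------------------------------------------- io
class TestCommunityTableIO:
    def test_round_trip_taxa_rows(self, toy_table, tmp_path):
        path = tmp_path / "otu.tsv"
        rio.write_community_table(toy_table, path)
        back = rio.read_community_table(path)
        assert back.sample_ids == toy_table.sample_ids
        assert back.taxon_ids == toy_table.taxon_ids
        np.testing.assert_array_equal(back.counts, toy_table.counts)

    def test_round_trip_samples_rows(self, toy_table, tmp_path):
        path = tmp_path / "otu.tsv"
        rio.write_community_table(toy_table, path, orientation="samples_rows")
        back = rio.read_community_table(path, orientation="samples_rows")
        np.testing.assert_array_equal(back.counts, toy_table.counts)

    def test_duplicate_taxon_id_is_reported(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("taxon\ts1\ts2\nT1\t1\t2\nT1\t3\t4\n")
        with pytest.raises(ValueError, match="T1"):
            rio.read_community_table(path)

    def test_negative_and_non_numeric_cells_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("taxon\ts1\ts2\nT1\t1\t-2\nT2\t3\t4\n")
        with pytest.raises(ValueError, match="T1"):
            rio.read_community_table(path)
        path.write_text("taxon\ts1\ts2\nT1\t1\tx\nT2\t3\t4\n")
        with pytest.raises(ValueError, match="non-numeric"):
            rio.read_community_table(path)

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("# comment\ntaxon\ts1\ts2\nT1\t1\t2\nT2\t3\t4\n")
        table = rio.read_community_table(path)
        assert table.n_taxa == 2 and table.n_samples == 2


class TestTreeAndSamples:
    def test_patristic_distances_by_hand(self, small_tree):
        dm = small_tree.patristic_distances(["A", "B", "C"])
        assert dm.data[0, 1] == pytest.approx(2.0)
        assert dm.data[0, 2] == pytest.approx(4.0)
        assert small_tree.n_tips == 3

    def test_mismatch_report(self, small_tree):
        assert small_tree.mismatch_report(["A", "B", "C"]) == {
            "only_in_tree": [],
            "only_in_table": [],
        }
        rep = small_tree.mismatch_report(["A", "X"])
        assert rep["only_in_table"] == ["X"] and "B" in rep["only_in_tree"]

    def test_lengthless_tree_rejected(self):
        with pytest.raises(ValueError, match="length"):
            PhyloTree.from_newick(["((A,B),C);"])

    def test_sample_frame_mismatch_lists_difference(self, toy_table, tmp_path):
        path = tmp_path / "meta.csv"
        pd.DataFrame(
            {"season": ["wet", "dry"], "group": ["FP1", "FP2"]},
            index=["s1", "s2"],
        ).to_csv(path)
        with pytest.raises(ValueError, match="s3"):
            rio.read_samples(path, table=toy_table)

    def test_samples_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"season": ["wet", "dry"], "group": ["FP1", "FP2"],
             "temperature": [25.0, 6.0], "pH": [8.1, 7.9]},
            index=["s1", "s2"],
        )
        frame = SampleFrame(df)
        path = tmp_path / "meta.csv"
        rio.write_samples(frame, path)
        back = rio.read_samples(path)
        pd.testing.assert_frame_equal(back.data, frame.data, check_names=False)


# -------------------------------------------------------------- rarefaction
class TestRarefy:
    def test_sample_at_exact_depth_unchanged(self):
        t = CommunityTable([[3, 7], [10, 30]], ["a", "b"], ["T1", "T2"])
        out = rarefy(t, 10, seed=0)
        np.testing.assert_array_equal(out.counts[0], [3, 7])

    def test_row_sums_equal_depth_and_shallow_dropped(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(6, 20))
        counts[2] = 0  # too shallow
        t = CommunityTable(counts, [f"s{i}" for i in range(6)],
                           [f"T{i}" for i in range(20)])
        out = rarefy(t, 100, seed=3)
        assert "s2" not in out.sample_ids
        assert np.all(out.counts.sum(axis=1) == 100)

    def test_deterministic_given_seed(self):
        t = CommunityTable([[600, 400]], ["s"], ["T1", "T2"])
        a = rarefy(t, 100, seed=7).counts
        b = rarefy(t, 100, seed=7).counts
        np.testing.assert_array_equal(a, b)

    def test_matches_hypergeometric_expectation(self):
        # sample [600, 400] subsampled to 100: first-taxon count is
        # Hypergeom(N=1000, K=600, n=100) with mean 60
        t = CommunityTable([[600, 400]] * 1, ["s"], ["T1", "T2"])
        draws = np.array(
            [rarefy(t, 100, seed=s).counts[0, 0] for s in range(3000)]
        )
        mean = hypergeom(1000, 600, 100).mean()
        se = hypergeom(1000, 600, 100).std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean) < 3 * se + 1e-9

    def test_bad_depth(self, toy_table):
        with pytest.raises(ValueError):
            rarefy(toy_table, 0, seed=0)


# ------------------------------------------------------------- prevalence
class TestPrevalenceFilter:
    @pytest.mark.parametrize("present,kept", [(12, True), (11, False)])
    def test_boundary_at_20_percent_of_60(self, present, kept):
        counts = np.zeros((60, 2), dtype=int)
        counts[:present, 0] = 1
        counts[:, 1] = 1  # always kept
        t = CommunityTable(counts, [f"s{i}" for i in range(60)], ["X", "Y"])
        out = prevalence_filter(t, 0.2)
        assert ("X" in out.taxon_ids) is kept

    def test_full_prevalence_requirement(self, toy_table):
        out = prevalence_filter(toy_table, 1.0)
        assert out.taxon_ids == ["D"]  # only D present in all three samples

    def test_idempotent(self, toy_table):
        once = prevalence_filter(toy_table, 0.5)
        twice = prevalence_filter(once, 0.5)
        assert once.taxon_ids == twice.taxon_ids

    def test_empty_result_warns(self, toy_table):
        empty = CommunityTable(
            np.zeros((3, 2), dtype=int), ["a", "b", "c"], ["T1", "T2"]
        )
        with pytest.warns(UserWarning):
            prevalence_filter(empty, 0.5)


# ---------------------------------------------------------------- alpha/beta
class TestDiversity:
    def test_shannon_uniform_four_taxa(self):
        t = CommunityTable([[1, 1, 1, 1]], ["s"], list("ABCD"))
        assert alpha_diversity(t)["shannon"][0] == pytest.approx(np.log(4))

    def test_shannon_single_taxon_zero(self):
        t = CommunityTable([[9, 0]], ["s"], ["A", "B"])
        out = alpha_diversity(t)
        assert out["shannon"][0] == 0.0 and out["richness"][0] == 1

    def test_all_zero_sample(self):
        t = CommunityTable([[0, 0]], ["s"], ["A", "B"])
        out = alpha_diversity(t)
        assert out.loc["s"].tolist() == [0.0, 0.0]

    def test_faith_pd_star_tree(self):
        star = PhyloTree.from_newick(["(A:1,B:1,C:1);"])
        t = CommunityTable([[1, 1, 1]], ["s"], ["A", "B", "C"])
        out = alpha_diversity(t, star)
        assert out["faith_pd"][0] == pytest.approx(3.0)

    def test_faith_pd_all_tips_equals_total_branch_length(self, balanced8_tree):
        t = CommunityTable(
            np.ones((1, 8), dtype=int), ["s"], list("ABCDEFGH")
        )
        pd_val = alpha_diversity(t, balanced8_tree)["faith_pd"][0]
        assert pd_val == pytest.approx(balanced8_tree.total_branch_length())

    def test_bray_curtis_hand_values(self):
        t = CommunityTable([[1, 2, 3], [3, 2, 1], [1, 2, 3], [0, 0, 6]],
                           list("wxyz"), list("ABC"))
        dm = bray_curtis(t)
        assert dm.data[0, 1] == pytest.approx(4 / 12)
        assert dm.data[0, 2] == 0.0
        disjoint = CommunityTable([[5, 0], [0, 5]], ["u", "v"], ["A", "B"])
        assert bray_curtis(disjoint).data[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_taxon_permutation_invariant(self, toy_table):
        perm = ["C", "A", "D", "B"]
        a = bray_curtis(toy_table).data
        b = bray_curtis(toy_table.select_taxa(perm)).data
        np.testing.assert_allclose(a, b)
        assert a.min() >= 0 and a.max() <= 1

    def test_two_all_zero_samples_distance_zero_with_warning(self):
        t = CommunityTable([[0, 0], [0, 0]], ["u", "v"], ["A", "B"])
        with pytest.warns(UserWarning):
            dm = bray_curtis(t)
        assert dm.data[0, 1] == 0.0


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(np.array([[0, 1], [2, 0]]), ["a", "b"])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(np.array([[1.0, 0], [0, 0]]), ["a", "b"])

    def test_condensed_round_trip(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dm = DistanceMatrix(m, list("abc"))
        np.testing.assert_array_equal(dm.condensed(), [1, 2, 3])
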