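"""Phylogenetic binning, betaNRI/RC-Bray null models, process partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riparia.assembly import (
    PROCESSES,
    AssemblyModel,
    beta_mpd,
    bin_taxa,
    bnri,
    classify_pair,
    partition_processes,
    process_env_correlation,
    rc_bray,
    PhyloBin,
)
from riparia.core import PhyloTree, SampleFrame
from riparia.simulate import AssemblySimConfig, simulate_assembly, simulate_tree


def beta_mpd_oracle(f_k, f_l, d):
    """O(n^2) double-sum evaluation of the abundance-weighted betaMPD."""
    f_k = np.asarray(f_k, float) / np.sum(f_k)
    f_l = np.asarray(f_l, float) / np.sum(f_l)
    total = 0.0
    for i in range(len(f_k)):
        for j in range(len(f_l)):
            total += 0.5 * (f_k[i] * f_l[j] + f_l[i] * f_k[j]) * d[i, j]
    return total


class TestBinTaxa:
    def test_balanced_eight_tips_two_bins_of_four(self, balanced8_tree):
        bins = bin_taxa(balanced8_tree, list("ABCDEFGH"), n_min=4)
        members = sorted(tuple(b.members) for b in bins)
        assert members == [tuple("ABCD"), tuple("EFGH")]

    def test_n_min_larger_than_taxa_single_bin(self, balanced8_tree):
        with pytest.warns(UserWarning):
            bins = bin_taxa(balanced8_tree, list("ABCD"), n_min=24)
        assert len(bins) == 1 and sorted(bins[0].members) == list("ABCD")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bins_partition_analysed_taxa(self, seed):
        tree = simulate_tree(80, seed=seed)
        taxa = tree.tip_names[:65]  # subset: forces strays
        bins = bin_taxa(tree, taxa, n_min=12)
        union = list(itertools.chain.from_iterable(b.members for b in bins))
        assert sorted(union) == sorted(taxa)
        assert len(union) == len(set(union))

    def test_deterministic(self):
        tree = simulate_tree(50, seed=7)
        a = [b.members for b in bin_taxa(tree, tree.tip_names, n_min=10)]
        b = [b.members for b in bin_taxa(tree, tree.tip_names, n_min=10)]
        assert a == b


class TestBetaMpd:
    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_matches_double_sum_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.uniform(0, 2, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        f_k = rng.dirichlet(np.ones(n))
        f_l = rng.dirichlet(np.ones(n))
        assert beta_mpd(f_k, f_l, d) == pytest.approx(
            beta_mpd_oracle(f_k, f_l, d), abs=1e-10
        )

    def test_star_tree_closed_form(self):
        # all tip pairs at distance 2c, identical abundance vectors:
        # betaMPD = 2c * (1 - sum f_i^2)
        c = 1.5
        n = 6
        d = np.full((n, n), 2 * c)
        np.fill_diagonal(d, 0.0)
        f = np.random.default_rng(0).dirichlet(np.ones(n))
        assert beta_mpd(f, f, d) == pytest.approx(2 * c * (1 - np.sum(f**2)))

    def test_symmetry_and_single_taxon(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        f_k, f_l = [0.3, 0.7], [0.6, 0.4]
        assert beta_mpd(f_k, f_l, d) == pytest.approx(beta_mpd(f_l, f_k, d))
        assert beta_mpd([1.0], [1.0], np.zeros((1, 1))) == 0.0

    def test_absent_bin_rejected(self):
        with pytest.raises(ValueError):
            beta_mpd([0.0, 0.0], [0.5, 0.5], np.zeros((2, 2)))


class TestBnri:
    def test_star_tree_degenerate_null_gives_zero(self):
        n = 5
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        counts = np.random.default_rng(0).integers(1, 20, size=(4, n))
        z = bnri(counts, d, [(0, 1), (2, 3)], n_null=100, seed=0)
        np.testing.assert_allclose(z, 0.0)

    def test_seeded_reproducible(self):
        rng = np.random.default_rng(1)
        n = 12
        d = rng.uniform(0, 2, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        counts = rng.integers(0, 30, size=(6, n))
        pairs = list(itertools.combinations(range(6), 2))
        a = bnri(counts, d, pairs, n_null=150, seed=5)
        b = bnri(counts, d, pairs, n_null=150, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_n_null_floor(self):
        with pytest.raises(ValueError):
            bnri(np.ones((2, 3)), np.zeros((3, 3)), [(0, 1)], n_null=50)


class TestRcBray:
    def test_identical_communities_fully_negative(self):
        # obs BC = 0; any null pair differing at all pushes RC to -1
        counts = np.tile([5, 5, 5, 5, 5, 5, 0, 0, 0, 0], (2, 1))
        rc = rc_bray(counts, [(0, 1)], n_null=200, seed=0)
        assert rc[0] <= -0.9

    def test_bounds_and_reproducibility(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 25, size=(8, 15))
        pairs = list(itertools.combinations(range(8), 2))
        rc = rc_bray(counts, pairs, n_null=120, seed=9)
        assert np.all(rc >= -1) and np.all(rc <= 1)
        np.testing.assert_array_equal(rc, rc_bray(counts, pairs, n_null=120, seed=9))


class TestClassifyPair:
    @pytest.mark.parametrize(
        "z,rc,expected",
        [
            (-2.5, 0.1, "HoS"),
            (2.5, -0.99, "HeS"),
            (0.5, 0.97, "DL"),
            (0.0, -0.97, "HD"),
            (0.0, 0.0, "DR"),
            (-1.96, 0.99, "DL"),  # boundary falls to the stochastic side
            (1.96, 0.0, "DR"),
            (0.0, 0.95, "DR"),
            (0.0, -0.95, "DR"),
        ],
    )
    def test_threshold_rules(self, z, rc, expected):
        assert classify_pair(z, rc) == expected

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_exactly_one_process(self, z, rc):
        assert classify_pair(z, rc) in PROCESSES

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.0)


class TestPartition:
    def test_single_bin_counting(self):
        calls = pd.DataFrame(
            {
                "sample_k": ["a"] * 4,
                "sample_l": ["b"] * 4,
                "bin": ["Bin1"] * 4,
                "process": ["DL", "DL", "DR", "HoS"],
            }
        )
        bins = [PhyloBin("Bin1", ["T1"], weight=1.0)]
        part = partition_processes(calls, bins)
        assert part.bin_fractions.loc["Bin1", "DL"] == pytest.approx(0.5)
        assert part.bin_fractions.loc["Bin1", "DR"] == pytest.approx(0.25)
        assert part.bin_fractions.loc["Bin1", "HoS"] == pytest.approx(0.25)

    def test_two_equal_bins_community_average(self):
        calls = pd.DataFrame(
            {
                "sample_k": ["a", "a"],
                "sample_l": ["b", "b"],
                "bin": ["Bin1", "Bin2"],
                "process": ["HoS", "HeS"],
            }
        )
        bins = [PhyloBin("Bin1", ["T1"], 0.5), PhyloBin("Bin2", ["T2"], 0.5)]
        part = partition_processes(calls, bins)
        assert part.community["HoS"] == pytest.approx(0.5)
        assert part.community["HeS"] == pytest.approx(0.5)
        assert part.community.sum() == pytest.approx(1.0, abs=1e-9)

    def test_fraction_vectors_sum_to_one(self):
        rng = np.random.default_rng(0)
        calls = pd.DataFrame(
            {
                "sample_k": rng.choice(list("abcd"), 50),
                "sample_l": rng.choice(list("efgh"), 50),
                "bin": rng.choice(["Bin1", "Bin2", "Bin3"], 50),
                "process": rng.choice(PROCESSES, 50),
            }
        )
        bins = [PhyloBin(f"Bin{i}", [f"T{i}"], w)
                for i, w in zip(range(1, 4), (0.2, 0.5, 0.3))]
        part = partition_processes(calls, bins)
        np.testing.assert_allclose(part.bin_fractions.sum(axis=1), 1.0)
        assert part.community.sum() == pytest.approx(1.0, abs=1e-9)


class TestEnvCorrelation:
    def _frame(self, n, temps):
        data = pd.DataFrame(
            {
                "season": ["wet"] * n,
                "group": ["FP1"] * n,
                "temperature": temps,
            },
            index=[f"s{i}" for i in range(n)],
        )
        return SampleFrame(data)

    def test_planted_monotone_relationship(self):
        n = 20
        temps = np.linspace(5, 30, n)
        frame = self._frame(n, temps)
        pairs = list(itertools.combinations(range(n), 2))
        pw = pd.DataFrame(
            {
                "sample_k": [f"s{i}" for i, _ in pairs],
                "sample_l": [f"s{j}" for _, j in pairs],
            }
        )
        pair_mean = np.array([(temps[i] + temps[j]) / 2 for i, j in pairs])
        rng = np.random.default_rng(0)
        hos = (pair_mean - pair_mean.min()) / np.ptp(pair_mean)
        hos = 0.8 * hos + 0.05 + rng.normal(0, 0.02, len(pairs))
        for p in PROCESSES:
            pw[p] = hos if p == "HoS" else (1 - hos) / 4
        out = process_env_correlation(pw, frame, variables=["temperature"])
        row = out[(out.variable == "temperature") & (out.process == "HoS")].iloc[0]
        assert row.rho > 0.9 and row.p < 0.05

    def test_constant_weights_flagged_zero(self):
        n = 6
        frame = self._frame(n, np.arange(n, dtype=float))
        pw = pd.DataFrame(
            {"sample_k": ["s0"] * 3, "sample_l": ["s1", "s2", "s3"]}
        )
        for p in PROCESSES:
            pw[p] = 0.2
        out = process_env_correlation(pw, frame, variables=["temperature"])
        assert (out.rho == 0).all() and (out.p == 1).all()

    def test_output_shape(self):
        n = 8
        frame = self._frame(n, np.arange(n, dtype=float))
        pairs = list(itertools.combinations(range(n), 2))
        pw = pd.DataFrame(
            {
                "sample_k": [f"s{i}" for i, _ in pairs],
                "sample_l": [f"s{j}" for _, j in pairs],
            }
        )
        rng = np.random.default_rng(1)
        for p in PROCESSES:
            pw[p] = rng.uniform(size=len(pairs))
        out = process_env_correlation(pw, frame)
        assert len(out) == len(frame.env_columns) * len(PROCESSES)
        assert {"rho", "p", "q"} <= set(out.columns)


class TestAssemblyModel:
    def test_end_to_end_structures(self):
        tree = simulate_tree(60, seed=11)
        cfg = AssemblySimConfig(regime="drift", n_samples=10, depth=1000, seed=4)
        table, frame = simulate_assembly(cfg, tree)
        model = AssemblyModel(table, tree, frame=frame, n_min=12, n_null=100)
        assert sum(b.weight for b in model.bins) == pytest.approx(1.0)
        res = model.fit(seed=0)
        assert set(res.calls["process"]) <= set(PROCESSES)
        part = res.partition("all")
        assert part.community.sum() == pytest.approx(1.0, abs=1e-9)
        pw = res.pair_weights()
        np.testing.assert_allclose(pw[list(PROCESSES)].sum(axis=1), 1.0)
        assert "community-level fractions" in res.summary()

    def test_top_k_restricts_taxa(self):
        tree = simulate_tree(60, seed=11)
        cfg = AssemblySimConfig(regime="drift", n_samples=8, depth=800, seed=4)
        table, frame = simulate_assembly(cfg, tree)
        model = AssemblyModel(table, tree, n_min=10, top_k=30, n_null=100)
        assert model.table.n_taxa == 30
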