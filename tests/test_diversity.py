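"""Abundance filter, diversity statistics and candidate selection.

The hand-built 5-miRNA x 6-sample fixture (conftest) carries hand-computed
expected values for every stage; randomized tests compare against brute-force
re-counts and closed-form statistics computed independently here.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from isomirdiv.diversity import (
    DiversityComparison,
    IsomirCountTable,
    contingency_chi_square,
    differential_diversity,
    diversity_grouping,
    diversity_matrix,
    eligible_mirnas,
    filter_low_abundance,
    intersect_comparisons,
    pooled_category_counts,
    rpm,
    select_candidates,
)


def random_table(rng, n_mirnas=6, n_iso=4, n_samples=5):
    idx = pd.MultiIndex.from_tuples(
        [(f"m{i}", 0, j) for i in range(n_mirnas) for j in range(n_iso)],
        names=["mirna", "offset5", "offset3"],
    )
    counts = pd.DataFrame(
        rng.integers(0, 300, size=(n_mirnas * n_iso, n_samples)),
        index=idx,
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return IsomirCountTable(counts)


class TestFilter:
    def test_strict_boundary_on_hand_table(self, hand_table):
        filtered = filter_low_abundance(hand_table)
        kept = set(filtered.counts.index)
        assert ("mC", 0, 0) not in kept      # max exactly 100: removed
        assert ("mB", 0, 2) not in kept      # max 50: removed
        assert ("mD", 0, 0) in kept          # single sample at 101: retained
        assert len(filtered.counts) == 10
        assert list(filtered.counts.columns) == list(hand_table.counts.columns)

    def test_matches_bruteforce_recount(self, rng):
        table = random_table(rng)
        for min_reads, min_samples in [(100, 1), (50, 2), (0, 1)]:
            got = set(filter_low_abundance(table, min_reads, min_samples).counts.index)
            expected = {
                key
                for key, row in table.counts.iterrows()
                if (row > min_reads).sum() >= min_samples
            }
            assert got == expected

    @given(t1=st.integers(0, 200), t2=st.integers(0, 200))
    def test_monotone_in_threshold(self, t1, t2):
        rng = np.random.default_rng(5)
        table = random_table(rng)
        lo, hi = sorted([t1, t2])
        rows_hi = set(filter_low_abundance(table, hi).counts.index)
        rows_lo = set(filter_low_abundance(table, lo).counts.index)
        assert rows_hi <= rows_lo


class TestRpm:
    def test_values(self):
        assert rpm(0, 5_000_000) == 0
        assert rpm(1_000_000, 1_000_000) == 1e6
        assert rpm(100, 8_900_000) == pytest.approx(11.235955, abs=1e-5)

    def test_depth_must_be_positive(self):
        with pytest.raises(ValueError):
            rpm(10, 0)


class TestDiversityMatrix:
    def test_hand_values(self, hand_table):
        div = diversity_matrix(filter_low_abundance(hand_table))
        expected = pd.DataFrame(
            [
                [3, 2, 1, 1, 4, 4],
                [2, 2, 2, 2, 1, 2],
                [1, 0, 0, 0, 0, 0],
                [3, 3, 2, 2, 3, 3],
            ],
            index=pd.Index(["mA", "mB", "mD", "mE"], name="mirna"),
            columns=hand_table.counts.columns,
        )
        pd.testing.assert_frame_equal(div, expected, check_dtype=False)

    def test_matches_percell_recount(self, rng):
        table = random_table(rng)
        div = diversity_matrix(table, presence_min=10)
        for mirna in div.index:
            sub = table.counts.xs(mirna, level="mirna", drop_level=False)
            for s in div.columns:
                assert div.loc[mirna, s] == int((sub[s] >= 10).sum())


class TestPooledCategories:
    def test_hand_values_and_partition(self, hand_table):
        filtered = filter_low_abundance(hand_table)
        cat_t = pooled_category_counts(filtered, "tumor")
        cat_n = pooled_category_counts(filtered, "normal")
        assert cat_t.tolist() == [1, 3, 0]
        assert cat_n.tolist() == [0, 3, 0]  # mD unobserved in normals
        # the categories partition the tallied miRNAs
        assert cat_t.sum() == 4 and cat_n.sum() == 3

    def test_ten_isoforms_fall_in_top_band(self):
        idx = pd.MultiIndex.from_tuples(
            [("m1", 0, j) for j in range(10)] + [("m2", 0, 0)],
            names=["mirna", "offset5", "offset3"],
        )
        counts = pd.DataFrame({"s1": [200] * 11}, index=idx)
        samples = pd.DataFrame({"tissue": ["tumor"]}, index=pd.Index(["s1"], name="sample_id"))
        cats = pooled_category_counts(IsomirCountTable(counts, samples), "tumor")
        assert cats[">=10"] == 1 and cats["1"] == 1

    def test_missing_tissue_errors(self, hand_table):
        with pytest.raises(ValueError):
            pooled_category_counts(hand_table, "plasma")


class TestChiSquare:
    def test_2x2_closed_form(self):
        a, b, c, d = 30.0, 70.0, 55.0, 45.0
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, _ = contingency_chi_square([a, b], [c, d])
        assert stat == pytest.approx(expected, abs=1e-10)

    def test_identical_rows_give_zero(self):
        stat, p = contingency_chi_square([10, 20, 30], [10, 20, 30])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_symmetric_under_row_swap(self, rng):
        a = rng.integers(5, 100, size=4).astype(float)
        b = rng.integers(5, 100, size=4).astype(float)
        assert contingency_chi_square(a, b)[0] == pytest.approx(
            contingency_chi_square(b, a)[0]
        )

    def test_zero_expected_cell_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            contingency_chi_square([10, 0], [20, 0])


class TestEligibility:
    def test_median_boundary(self):
        div = pd.DataFrame(
            [[3, 3, 3], [2, 2, 2]],
            index=pd.Index(["at3", "at2"], name="mirna"),
            columns=["a", "b", "c"],
        )
        assert eligible_mirnas(div) == ["at3"]

    def test_hand_table(self, hand_table):
        div = diversity_matrix(filter_low_abundance(hand_table))
        assert eligible_mirnas(div, 3) == ["mE"]

    def test_matches_median_recomputation(self, rng):
        div = pd.DataFrame(
            rng.integers(0, 8, size=(10, 7)),
            index=pd.Index([f"m{i}" for i in range(10)], name="mirna"),
        )
        got = set(eligible_mirnas(div, 3))
        expected = {m for m in div.index if np.median(div.loc[m]) >= 3}
        assert got == expected


class TestGrouping:
    def test_tie_rule(self):
        labels = diversity_grouping(pd.Series([1, 2, 3, 4, 5], index=list("abcde")))
        assert labels.tolist() == ["less", "less", "less", "more", "more"]
        labels = diversity_grouping(pd.Series([1, 5], index=["a", "b"]))
        assert labels.tolist() == ["less", "more"]

    def test_degenerate_split_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = diversity_grouping(pd.Series([3, 3, 3]))
        assert (labels == "less").all()

    def test_matches_direct_comparison(self, rng):
        vals = pd.Series(rng.integers(0, 6, size=15))
        labels = diversity_grouping(vals)
        med = vals.median()
        for i, v in vals.items():
            assert labels[i] == ("more" if v > med else "less")


def welch_oracle(x, y):
    """Welch t-test recomputed from the textbook formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestDifferentialDiversity:
    def test_hand_table_welch(self, hand_table):
        div = diversity_matrix(filter_low_abundance(hand_table))
        groups = hand_table.samples["tissue"]
        comps = differential_diversity(
            div.loc[eligible_mirnas(div)], groups, alpha=0.01,
            group_a="tumor", group_b="normal",
        )
        assert len(comps) == 1
        c = comps[0]
        # tumor (3,3,2,2) vs normal (3,3): hand Welch t=-1.7320508, df=3
        assert c.mean_a == 2.5 and c.mean_b == 3.0
        assert c.fold_change == pytest.approx(2.5 / 3)
        assert c.p_value == pytest.approx(0.18169011, abs=1e-6)
        assert not c.significant

    def test_matches_oracle_to_1e12(self, rng):
        x = rng.normal(3, 1, size=12)
        y = rng.normal(4, 2, size=9)
        div = pd.DataFrame(
            [np.concatenate([x, y])],
            index=pd.Index(["m1"], name="mirna"),
            columns=[f"a{i}" for i in range(12)] + [f"b{i}" for i in range(9)],
        )
        groups = pd.Series(["ga"] * 12 + ["gb"] * 9, index=div.columns)
        c = differential_diversity(div, groups, alpha=0.05)[0]
        _, p = welch_oracle(x, y)
        assert c.p_value == pytest.approx(p, abs=1e-12)

    def test_identical_constant_groups_p_one(self):
        div = pd.DataFrame(
            [[2, 2, 2, 2]], index=pd.Index(["m1"], name="mirna"), columns=list("abcd")
        )
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        c = differential_diversity(div, groups, alpha=0.05)[0]
        assert c.p_value == 1.0 and not c.significant


class TestSelection:
    def make(self, name, fc, sig=True):
        return DiversityComparison(name, fc, 1.0, fc, 0.001 if sig else 0.5, sig)

    def test_strict_two_sided_band(self):
        comps = [
            self.make("at_boundary", 2.0),
            self.make("above", 2.5),
            self.make("below_half", 0.4),
            self.make("at_half", 0.5),
            self.make("not_sig", 3.0, sig=False),
        ]
        assert select_candidates(comps) == ["above", "below_half"]

    def test_intersection(self):
        assert intersect_comparisons(["a", "b", "c"], ["d", "c", "b"]) == ["b", "c"]
        assert intersect_comparisons(["a"], ["b"]) == []
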