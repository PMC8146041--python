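"""Agreement statistics: outliers, routed correlation, Wilcoxon, ANOVA, SE."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from scipy import stats as sps

from thermapheno import stats as st


def enumerate_wilcoxon_p(d: np.ndarray, w_observed: float) -> float:
    """Brute-force two-sided p: all 2^n sign assignments of the ranked |d|."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    ws = np.array(
        [ranks[np.array(signs) > 0].sum() for signs in product([-1, 1], repeat=len(d))]
    )
    cdf = np.mean(ws <= w_observed)
    sf = np.mean(ws >= w_observed)
    return min(1.0, 2.0 * min(cdf, sf))


class TestIqrOutliers:
    def test_textbook_outlier_flagged(self):
        out = st.iqr_outliers(list(range(1, 11)) + [100])
        assert list(out) == [10]  # index of the value 100

    def test_constant_values_no_outliers(self):
        assert st.iqr_outliers([5.0] * 8) == []

    def test_symmetric_data_without_extremes(self):
        vals = np.array([-3, -2, -1, 0, 0, 1, 2, 3], dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        expected = [
            i for i, v in enumerate(vals)
            if v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr
        ]
        assert list(st.iqr_outliers(vals)) == expected == []

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            st.iqr_outliers([1, 2, 3])


class TestRouteCorrelation:
    def test_collinear_routes_to_pearson(self):
        x = np.linspace(1.0, 10.0, 40)
        res, rep = st.route_correlation(x, 2 * x + 1)
        assert rep.parametric_ok
        assert res.method == "pearson"
        assert res.coefficient == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonlinear_routes_to_spearman(self):
        x = np.linspace(0.0, 5.0, 40)
        res, rep = st.route_correlation(x, np.exp(x))
        assert not rep.parametric_ok
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared is None

    def test_spearman_equals_rank_then_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        res, _ = st.route_correlation(x, y)
        oracle, _ = sps.pearsonr(sps.rankdata(x), sps.rankdata(y))
        assert res.spearman_r == pytest.approx(oracle, abs=1e-14)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            st.route_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestWilcoxon:
    def test_all_positive_n5_exact_p(self):
        res = st.wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1])
        assert res.statistic == 15.0  # W+ at its extreme
        assert res.p_value == pytest.approx(2 / 2**5)
        assert res.method == "exact"

    def test_swapping_sides_mirrors_statistic_same_p(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 2.0])
        b = np.array([2.0, 2.0, 2.0, 2.0, 2.0, 2.0])
        r1 = st.wilcoxon_signed_rank(a, b)
        r2 = st.wilcoxon_signed_rank(b, a)
        n = r1.n_used
        assert r2.statistic == n * (n + 1) / 2 - r1.statistic
        assert r1.p_value == pytest.approx(r2.p_value)

    @pytest.mark.parametrize("trial", range(12))
    def test_exact_p_matches_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(3, 11))
        a = rng.integers(0, 6, n).astype(float)
        b = rng.integers(0, 6, n).astype(float)
        d = a - b
        if np.all(d == 0):
            return
        res = st.wilcoxon_signed_rank(a, b)
        assert res.p_value == pytest.approx(
            enumerate_wilcoxon_p(d, res.statistic), abs=1e-12
        )

    def test_zero_differences_dropped_and_counted(self):
        res = st.wilcoxon_signed_rank([1, 2, 3, 4, 9], [1, 2, 3, 1, 2])
        assert res.n_zeros == 3
        assert res.n_used == 2

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_signed_rank([1, 2], [1, 2])

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.5, 1, 40)
        b = rng.normal(0.0, 1, 40)
        res = st.wilcoxon_signed_rank(a, b)
        assert res.method == "normal"
        # cross-check against the scipy implementation of the same test
        ref = sps.wilcoxon(a, b, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


class TestLog1p:
    def test_anchor_values(self):
        assert st.log1p_transform([0.0])[0] == 0.0
        assert st.log1p_transform([np.e - 1])[0] == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st_.lists(st_.floats(0, 1e6), min_size=2, max_size=20))
    def test_order_preserved(self, vals):
        out = st.log1p_transform(sorted(vals))
        assert np.all(np.diff(out) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            st.log1p_transform([-0.1])


def balanced_design(rng, n_per_cell=4, interaction=0.0, noise=1.0):
    rows = []
    a_eff = {"A": -1.0, "B": 1.0}
    b_eff = {"X": -2.0, "Y": 0.0, "Z": 2.0}
    for a in a_eff:
        for b in b_eff:
            for _ in range(n_per_cell):
                y = (
                    10.0 + a_eff[a] + b_eff[b]
                    + interaction * a_eff[a] * b_eff[b]
                    + noise * rng.normal()
                )
                rows.append({"a": a, "b": b, "y": y})
    return pd.DataFrame(rows)


def twoway_ss_oracle(df):
    """Direct mean-decomposition sums of squares for a balanced design."""
    gm = df["y"].mean()
    ssa = sum(len(g) * (g["y"].mean() - gm) ** 2 for _, g in df.groupby("a"))
    ssb = sum(len(g) * (g["y"].mean() - gm) ** 2 for _, g in df.groupby("b"))
    sscell = sum(
        len(g) * (g["y"].mean() - gm) ** 2 for _, g in df.groupby(["a", "b"])
    )
    return ssa, ssb, sscell - ssa - ssb


class TestTwoWayAnova:
    def test_additive_noise_free_design_zero_interaction(self):
        df = balanced_design(np.random.default_rng(0), interaction=0.0, noise=0.0)
        # add reproducible within-cell spread that is identical across cells,
        # keeping cell means exactly additive
        wiggle = np.tile([-0.5, 0.5, -0.25, 0.25], 6)
        df["y"] = df["y"] + wiggle
        tab = st.two_way_anova(df, "y", "a", "b")
        assert tab.table.loc["a:b", "sum_sq"] == pytest.approx(0.0, abs=1e-18)
        assert tab.table.loc["a:b", "F"] == pytest.approx(0.0, abs=1e-12)

    def test_balanced_ss_match_decomposition_oracle(self):
        df = balanced_design(np.random.default_rng(5))
        tab = st.two_way_anova(df, "y", "a", "b")
        ssa, ssb, ssab = twoway_ss_oracle(df)
        assert tab.term("a")["sum_sq"] == pytest.approx(ssa, rel=1e-9)
        assert tab.term("b")["sum_sq"] == pytest.approx(ssb, rel=1e-9)
        assert tab.table.loc["a:b", "sum_sq"] == pytest.approx(ssab, rel=1e-9)

    def test_full_decomposition_sums_to_total(self):
        df = balanced_design(np.random.default_rng(7))
        tab = st.two_way_anova(df, "y", "a", "b")
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert tab.table["sum_sq"].sum() == pytest.approx(total, rel=1e-9)

    def test_row_permutation_invariance(self):
        df = balanced_design(np.random.default_rng(8))
        tab1 = st.two_way_anova(df, "y", "a", "b")
        tab2 = st.two_way_anova(
            df.sample(frac=1.0, random_state=1).reset_index(drop=True), "y", "a", "b"
        )
        pd.testing.assert_frame_equal(tab1.table, tab2.table)

    def test_empty_cell_error_names_cell(self):
        df = balanced_design(np.random.default_rng(9))
        df = df[~((df["a"] == "B") & (df["b"] == "Z"))]
        with pytest.raises(ValueError, match="a='B', b='Z'"):
            st.two_way_anova(df, "y", "a", "b")


class TestOneWayAnova:
    def test_identical_group_means_f_zero(self):
        df = pd.DataFrame(
            {"g": ["a"] * 3 + ["b"] * 3, "y": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}
        )
        tab = st.one_way_anova(df, "y", "g")
        assert tab.term("g")["F"] == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        df = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8, "y": np.concatenate([a, b])})
        tab = st.one_way_anova(df, "y", "g")
        t = sps.ttest_ind(a, b, equal_var=True)
        assert tab.term("g")["F"] == pytest.approx(t.statistic**2, rel=1e-9)

    def test_three_groups_match_ss_oracle(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "g": np.repeat(["a", "b", "c"], 6),
                "y": np.concatenate(
                    [rng.normal(m, 1, 6) for m in (0.0, 1.0, 2.5)]
                ),
            }
        )
        tab = st.one_way_anova(df, "y", "g")
        gm = df["y"].mean()
        ss_between = sum(
            len(g) * (g["y"].mean() - gm) ** 2 for _, g in df.groupby("g")
        )
        assert tab.term("g")["sum_sq"] == pytest.approx(ss_between, rel=1e-9)

    def test_tiny_group_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            st.one_way_anova(df, "y", "g")


class TestStandardError:
    def test_constant_sample(self):
        assert st.standard_error([1, 1, 1, 1]) == 0.0

    def test_two_point_sample(self):
        assert st.standard_error([0, 2]) == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        vals=st_.lists(st_.floats(-1e3, 1e3), min_size=2, max_size=20),
        k=st_.floats(-100, 100),
    )
    def test_homogeneity(self, vals, k):
        se = st.standard_error(vals)
        assert st.standard_error([k * v for v in vals]) == pytest.approx(
            abs(k) * se, rel=1e-9, abs=1e-9
        )

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            st.standard_error([1.0])


class TestCompareCv:
    def test_automated_vs_manual_cv_block(self):
        rng = np.random.default_rng(4)
        manual = rng.uniform(0.1, 0.4, 30)
        automated = manual + rng.uniform(0.5, 2.0, 30)
        block = st.compare_cv(manual, automated)
        assert block["mean_cv_automated_pct"] > block["mean_cv_manual_pct"]
        assert block["wilcoxon_p"] < 0.001
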