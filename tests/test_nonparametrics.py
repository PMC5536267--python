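"""Nonparametric suite: Friedman, Wilcoxon, Šidák, Cochran, McNemar, Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps
from statsmodels.stats.contingency_tables import cochrans_q as sm_cochrans_q

import effortdisc as ed


class TestFriedman:
    def test_rank_consistent_three_by_three(self):
        """Closed form: (12/(nk(k+1))) * sum(R_j^2) - 3n(k+1) = 6."""
        m = pd.DataFrame([[1, 2, 3], [4, 5, 6], [0.1, 0.5, 0.9]])
        res = ed.friedman(m)
        assert res.statistic == pytest.approx(6.0)
        assert list(res.mean_ranks.values()) == [1.0, 2.0, 3.0]
        assert res.df == 2

    def test_identical_columns_give_zero(self):
        m = pd.DataFrame(np.tile([[4.0, 4.0, 4.0]], (5, 1)))
        res = ed.friedman(m)
        assert res.statistic == 0.0 and res.p_raw == 1.0

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(8, 4)))
        a = ed.friedman(m)
        b = ed.friedman(m.sample(frac=1, random_state=0))
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(12, 4))
        ours = ed.friedman(pd.DataFrame(m))
        ref = sps.friedmanchisquare(*m.T)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_raw == pytest.approx(ref.pvalue)

    def test_incomplete_rows_dropped(self):
        m = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        m.iloc[0, 0] = np.nan
        res = ed.friedman(m)
        assert res.extra["n"] == 3


class TestWilcoxon:
    def test_hand_computed_no_ties(self):
        """d = (1..5): W+ = 15, mean 7.5, var 13.75 -> Z = 2.0226."""
        y = np.zeros(5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = ed.wilcoxon_paired(x, y)
        assert res.statistic == pytest.approx(7.5 / np.sqrt(13.75), rel=1e-6)

    def test_all_tied(self):
        x = np.ones(10)
        res = ed.wilcoxon_paired(x, x)
        assert res.statistic == 0.0 and res.r == 0.0
        assert res.extra["tied"] == 10 and res.extra["tied_pct"] == 100.0

    def test_effect_size_convention(self):
        """r = |Z| / sqrt(2 N): the convention reproducing r = .30 from
        Z = 4.56 at N = 114 pairs."""
        assert 4.56 / np.sqrt(2 * 114) == pytest.approx(0.302, abs=5e-4)
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 40)
        y = rng.normal(0.0, 1.0, 40)
        res = ed.wilcoxon_paired(x, y)
        assert res.r == pytest.approx(abs(res.statistic) / np.sqrt(80))

    def test_better_tied_worse_counts(self):
        x = np.array([3.0, 2.0, 2.0, 1.0])
        y = np.array([1.0, 2.0, 2.0, 2.0])
        res = ed.wilcoxon_paired(x, y)
        assert (res.extra["better"], res.extra["tied"],
                res.extra["worse"]) == (1, 2, 1)


class TestSidak:
    def test_worked_value(self):
        assert ed.sidak(0.05, 3) == pytest.approx(0.142625)

    def test_edges(self):
        assert ed.sidak(0.0, 10) == 0.0
        assert ed.sidak(0.9999, 6) == pytest.approx(1.0, abs=1e-3)
        assert ed.sidak(1.0, 2) == 1.0

    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 40))
    def test_adjustment_never_below_raw(self, p, m):
        adj = ed.sidak(p, m)
        assert p <= adj <= 1.0

    @given(p=st.floats(0.0, 0.99), m=st.integers(1, 20))
    def test_monotone_in_m(self, p, m):
        assert ed.sidak(p, m + 1) >= ed.sidak(p, m)


class TestCochranQ:
    def test_identical_columns(self):
        m = pd.DataFrame(np.tile([[1, 1, 1]], (6, 1)))
        assert ed.cochran_q(m).statistic == 0.0

    def test_hand_computed_four_by_three(self):
        """Failures only in the first model for 2 of 4 units: Q = 4 by
        Q = k(k-1) sum(Cj - C)^2 / (k sum(Ri) - sum(Ri^2))."""
        m = pd.DataFrame([[1, 0, 0], [1, 0, 0], [0, 0, 0], [0, 0, 0]])
        assert ed.cochran_q(m).statistic == pytest.approx(4.0)

    def test_all_zero_row_leaves_q_unchanged(self):
        m = pd.DataFrame([[1, 0, 0], [1, 0, 0], [0, 0, 0], [0, 0, 0]])
        m2 = pd.concat([m, pd.DataFrame([[0, 0, 0]])], ignore_index=True)
        assert ed.cochran_q(m2).statistic == pytest.approx(
            ed.cochran_q(m).statistic)

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(21)
        m = (rng.uniform(size=(25, 4)) < [0.2, 0.4, 0.5, 0.7]).astype(int)
        ours = ed.cochran_q(pd.DataFrame(m))
        ref = sm_cochrans_q(m, return_object=True)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.p_raw == pytest.approx(ref.pvalue)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            ed.cochran_q(pd.DataFrame([[0, 2], [1, 0]]))


class TestMcNemar:
    @pytest.mark.parametrize("b,c,expected", [
        (0, 25, 23.04), (0, 15, 13.0667), (5, 5, 0.1)])
    def test_continuity_corrected_values(self, b, c, expected):
        assert ed.mcnemar(b, c).statistic == pytest.approx(expected, abs=1e-3)

    def test_symmetry(self):
        assert ed.mcnemar(3, 11).statistic == ed.mcnemar(11, 3).statistic

    def test_no_discordant_pairs_flagged(self):
        res = ed.mcnemar(0, 0)
        assert np.isnan(res.statistic) and res.extra["undefined"]


class TestSpearman:
    def test_monotone_relationships(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert ed.spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
        assert ed.spearman(x, -x ** 3).statistic == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        res = ed.spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = ed.spearman(x, y).statistic
        b = ed.spearman(np.exp(x), y ** 3 + 5 * y).statistic
        assert a == pytest.approx(b)


class TestSuite:
    def test_degenerate_matrices_give_zero_statistics(self):
        const = pd.DataFrame(np.full((6, 3), 2.5))
        assert ed.friedman(const).statistic == 0.0
        assert ed.wilcoxon_paired(const[0], const[1]).statistic == 0.0
        assert ed.cochran_q(pd.DataFrame(np.zeros((6, 3)))).statistic == 0.0

    def test_report_structure_and_flattening(self, small_fits):
        report = ed.run_comparison_suite(small_fits)
        assert set(report["domains"]) == {"physical", "cognitive"}
        dom = report["domains"]["physical"]
        assert "one_parameter_models" in dom
        assert "magnitude_effect_l" in dom
        assert "l_correlations" in dom
        assert "l" in report["cross_domain"]
        flat = ed.flatten_report(report)
        assert {"context", "test", "statistic", "p_raw"} <= set(flat.columns)
        assert len(flat) > 10
        # adjusted p never below raw p wherever both are reported
        both = flat.dropna(subset=["p_adjusted"])
        assert (both["p_adjusted"] >= both["p_raw"] - 1e-12).all()

    def test_pairwise_blocks_report_effect_sizes(self, small_fits):
        report = ed.run_comparison_suite(small_fits)
        block = report["domains"]["physical"]["one_parameter_models"]
        for result in block["pairwise_wilcoxon"].values():
            assert 0.0 <= result["r"] <= 1.0
            assert result["better"] + result["tied"] + result["worse"] \
                == result["n_pairs"]
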