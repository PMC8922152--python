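import numpy as np
import pytest
import scipy.stats

from revtopics import (PrimaryTopicAssignment, enumerate_fisher_p,
                       fisher_exact, one_way_anova, percent, rating_summary,
                       share_table, welch_t)


class TestPercent:
    @pytest.mark.parametrize("n,total,expected", [
        (94, 461, 20.4), (244, 915, 26.7), (102, 461, 22.1),
        (104, 461, 22.6), (71, 461, 15.4), (90, 461, 19.5),
        (166, 915, 18.1), (181, 915, 19.8), (182, 915, 19.9),
        (142, 915, 15.5),
        (1, 8, 12.5), (1, 800, 0.1),
    ])
    def test_printed_style_one_decimal_half_up(self, n, total, expected):
        assert percent(n, total) == expected

    def test_half_up_not_bankers(self):
        assert percent(25, 1000) == 2.5
        assert percent(125, 1000) == 12.5
        assert percent(1, 16) == 6.3  # 6.25 rounds up

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percent(1, 0)


class TestShareTable:
    def assignments(self):
        return ([PrimaryTopicAssignment(f"d{i}", i % 3) for i in range(30)]
                + [PrimaryTopicAssignment("dropped", None)])

    def test_counts_shares_and_margins(self):
        strata = {f"d{i}": ("x" if i < 18 else "y") for i in range(30)}
        tab = share_table(self.assignments(), strata, ["x", "y"], n_topics=3)
        assert tab.counts["x"].sum() == 18 and tab.counts["y"].sum() == 12
        assert tab.counts["total"].sum() == 30
        # each of the K rounded shares can be off by at most 0.05
        assert tab.percents["x"].sum() == pytest.approx(100.0, abs=3 * 0.05)

    def test_single_topic_is_100_percent(self):
        a = [PrimaryTopicAssignment(f"d{i}", 0) for i in range(5)]
        tab = share_table(a, {f"d{i}": "s" for i in range(5)}, ["s"])
        assert tab.percents.loc[0, "s"] == 100.0

    def test_missing_stratum_excluded_from_column_not_total(self):
        strata = {"d0": "x"}
        a = [PrimaryTopicAssignment("d0", 0), PrimaryTopicAssignment("d1", 0)]
        tab = share_table(a, strata, ["x"], n_topics=1)
        assert tab.counts.loc[0, "x"] == 1 and tab.counts.loc[0, "total"] == 2


class TestFisherExact:
    def test_homogeneous_2x2(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_diagonal_2x2_enumerated(self):
        res = fisher_exact([[3, 0], [0, 3]])
        assert res.p_value == pytest.approx(0.1)

    @pytest.mark.parametrize("table", [
        [[3, 0], [0, 3]], [[8, 2], [1, 5]], [[10, 3], [6, 9]],
        [[1, 9], [11, 3]], [[4, 4], [4, 4]],
    ])
    def test_2x2_matches_scipy_oracle(self, table):
        ours = fisher_exact(table).p_value
        theirs = scipy.stats.fisher_exact(np.array(table)).pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_rxc_monte_carlo_close_to_enumeration(self):
        table = [[3, 1, 2], [1, 3, 1], [2, 1, 3]]
        exact = enumerate_fisher_p(table)
        res = fisher_exact(table, mc_reps=40_000, seed=7)
        assert res.mc_se is not None
        assert abs(res.p_value - exact) <= 3 * res.mc_se

    def test_rxc_enumeration_homogeneous_is_1(self):
        assert enumerate_fisher_p([[2, 2], [2, 2]]) == pytest.approx(
            fisher_exact([[2, 2], [2, 2]]).p_value)

    def test_zero_margin_named(self):
        with pytest.raises(ValueError, match="row|column"):
            fisher_exact([[0, 0], [3, 2]])

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 2]])


class TestWelchT:
    def test_identical_groups(self):
        res = welch_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # means 2 and 5, both variances 1: t = -3 / sqrt(2/3)
        res = welch_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.6742, abs=1e-4)
        assert res.df[0] == pytest.approx(4.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0, 8.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1], [2, 3])
        with pytest.raises(ValueError):
            welch_t([2, 2], [3, 3])


class TestAnova:
    def test_equal_means_f_zero(self):
        res = one_way_anova([[1, 2, 3], [2, 2, 2], [1, 3, 2]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equals_pooled_t_squared(self):
        a, b = [1.0, 2.0, 4.0, 3.0], [2.0, 5.0, 6.0]
        res = one_way_anova([a, b])
        t = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t.statistic ** 2, abs=1e-9)
        assert res.df == (1.0, 5.0)

    def test_hand_ss_decomposition_zero_within(self):
        # between-group MS = 4/2... within MS = 0 -> F infinite
        res = one_way_anova([[1, 1], [2, 2], [3, 3]])
        assert np.isinf(res.statistic) and res.p_value == pytest.approx(0.0)

    def test_hand_ss_decomposition(self):
        groups = [[1.0, 2.0], [2.0, 4.0], [5.0, 7.0]]
        grand = np.mean(np.concatenate(groups))
        ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum()
                        for g in groups)
        f_manual = (ss_between / 2) / (ss_within / 3)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f_manual, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 2]])
        with pytest.raises(ValueError):
            one_way_anova([[1, 2], []])


class TestRatingSummary:
    def make(self, pairs, strata=None):
        assignments = [PrimaryTopicAssignment(f"d{i}", t)
                       for i, (t, _) in enumerate(pairs)]
        ratings = {f"d{i}": r for i, (_, r) in enumerate(pairs)}
        strata = strata or {f"d{i}": "s" for i in range(len(pairs))}
        return assignments, ratings, strata

    def test_single_record_sd_missing(self):
        a, r, s = self.make([(0, 4)])
        summary = rating_summary(a, r, s, ["s"], n_topics=1)
        assert summary.table.loc[0, ("overall", "mean")] == pytest.approx(4.0)
        assert np.isnan(summary.table.loc[0, ("overall", "sd")])

    def test_two_records_hand_sd(self):
        a, r, s = self.make([(0, 3), (0, 5)])
        summary = rating_summary(a, r, s, ["s"], n_topics=1)
        assert summary.table.loc[0, ("overall", "mean")] == pytest.approx(4.0)
        assert summary.table.loc[0, ("overall", "sd")] == pytest.approx(
            np.sqrt(2), abs=5e-3)

    def test_missing_ratings_counted(self):
        a, r, s = self.make([(0, 3), (0, None), (1, 4)])
        summary = rating_summary(a, r, s, ["s"], n_topics=2)
        assert summary.n_missing_rating == 1
        assert summary.table.loc["total", ("overall", "n")] == 2

    def test_anova_p_across_strata(self):
        pairs = [(0, r) for r in (1, 1, 2, 5, 5, 4)]
        strata = {f"d{i}": ("young" if i < 3 else "old") for i in range(6)}
        a, r, _ = self.make(pairs)
        summary = rating_summary(a, r, strata, ["young", "old"], n_topics=1)
        groups = [[1, 1, 2], [5, 5, 4]]
        assert summary.anova_p[0] == pytest.approx(
            one_way_anova(groups).p_value)
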