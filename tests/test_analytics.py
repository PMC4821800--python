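"""Corpus analytics: breakdowns, trends, bias ratios, tests and correlations."""

import numpy as np
import pytest
from scipy import stats

from micemeta.analytics import (
    BiasRatio,
    CATEGORIES,
    SexBreakdown,
    binomial_proportion_test,
    journal_reporting_index,
    reporting_breakdown,
    reporting_category,
    sex_bias_ratio,
    sex_breakdown,
    spearman_rank_corr,
    trend_slope,
    two_way_anova_no_replication,
    yearly_trend,
)
from micemeta.models import (
    AgeValue,
    DocAnnotation,
    InputError,
    Mention,
    MetadataRecord,
    MetadataTable,
    UndefinedMetricError,
)


def ann(doc_id, sex="none", age=False):
    sex_m = None
    if sex != "none":
        sex_m = Mention(doc_id=doc_id, start=0, end=3, surface="xxx", kind="sex",
                        rule_id="r", sex_category=sex)
    return DocAnnotation(doc_id=doc_id, sex_status=sex, sex_mention=sex_m,
                         age_status="reported" if age else "none",
                         age_value=AgeValue(6, 6, "week") if age else None)


class TestReportingBreakdown:
    def test_four_way_partition(self):
        anns = [ann("d1", sex="female", age=True), ann("d2", sex="male"),
                ann("d3", age=True), ann("d4")]
        [s] = reporting_breakdown(anns)
        assert s.counts == {"both_reported": 1, "sex_only": 1, "age_only": 1, "none": 1}
        assert all(p == 25.0 for p in s.percentages.values())

    def test_empty_corpus(self):
        assert reporting_breakdown([]) == []

    def test_counts_sum_to_stratum_size(self):
        meta = MetadataTable({f"d{i}": MetadataRecord(
            year=2000 + i % 3, journal="J", disease_groups=frozenset({"cancer"}),
            subgroups=frozenset()) for i in range(30)})
        anns = [ann(f"d{i}", sex="female" if i % 2 else "none", age=bool(i % 3))
                for i in range(30)]
        summaries = reporting_breakdown(anns, meta, "year")
        assert sum(s.total for s in summaries) == 30
        for s in summaries:
            assert sum(s.counts.values()) == s.total

    def test_unknown_stratify_field(self):
        with pytest.raises(InputError, match="unknown stratify"):
            reporting_breakdown([ann("d1")], MetadataTable({}), "phase_of_moon")

    def test_category_assignment_is_exclusive(self):
        for a in [ann("x", sex="both", age=True), ann("x", sex="male"),
                  ann("x", age=True), ann("x")]:
            assert reporting_category(a) in CATEGORIES


class TestYearlyTrend:
    def test_normalization(self):
        anns = [ann(f"d{i}", sex="none") for i in range(5)] + \
               [ann(f"d{i+5}", sex="female", age=True) for i in range(5)]
        meta = MetadataTable({f"d{i}": MetadataRecord(
            year=2005, journal="J", disease_groups=frozenset(), subgroups=frozenset())
            for i in range(10)})
        trend = yearly_trend(reporting_breakdown(anns, meta, "year"))
        assert trend[2005]["none"] == 0.5
        assert sum(trend[2005].values()) == pytest.approx(1.0)

    def test_monotone_input_gives_monotone_fractions(self):
        # constructed: none-fraction decreases 0.9, 0.6, 0.3 across years
        meta_records, anns = {}, []
        for j, (year, k_none) in enumerate([(2000, 9), (2001, 6), (2002, 3)]):
            for i in range(10):
                d = f"d{j}_{i}"
                meta_records[d] = MetadataRecord(year=year, journal="J",
                                                 disease_groups=frozenset(),
                                                 subgroups=frozenset())
                anns.append(ann(d) if i < k_none else ann(d, sex="female", age=True))
        trend = yearly_trend(reporting_breakdown(anns, MetadataTable(meta_records), "year"))
        fracs = [trend[y]["none"] for y in (2000, 2001, 2002)]
        assert fracs == sorted(fracs, reverse=True)


class TestTrendSlope:
    def test_two_point_line(self):
        assert trend_slope([(2000, 1.0), (2010, 0.55)]) == pytest.approx(-0.045)

    def test_constant_series(self):
        assert trend_slope([(2000, 0.3), (2001, 0.3), (2002, 0.3)]) == pytest.approx(0.0)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        years = np.arange(1994, 2015, dtype=float)
        fracs = rng.uniform(0, 1, size=years.size)
        got = trend_slope(list(zip(years, fracs)))
        # Sigma-formula oracle
        xbar, ybar = years.mean(), fracs.mean()
        expected = ((years - xbar) * (fracs - ybar)).sum() / ((years - xbar) ** 2).sum()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_year_rejected(self):
        with pytest.raises(InputError):
            trend_slope([(2000, 0.5)])


class TestSexBias:
    def test_female_majority(self):
        r = sex_bias_ratio(SexBreakdown("s", female=45, male=20, both=3, not_reported=2))
        assert r == BiasRatio("s", "female", 2.25)

    def test_ratio_echoes_354(self):
        r = sex_bias_ratio(SexBreakdown("s", female=354, male=100, both=0, not_reported=0))
        assert r.direction == "female" and r.ratio == pytest.approx(3.54)

    def test_tie(self):
        r = sex_bias_ratio(SexBreakdown("s", female=7, male=7, both=0, not_reported=0))
        assert (r.direction, r.ratio) == ("none", 1.0)

    def test_scale_invariance(self):
        a = sex_bias_ratio(SexBreakdown("s", female=9, male=4, both=0, not_reported=0))
        b = sex_bias_ratio(SexBreakdown("s", female=90, male=40, both=0, not_reported=0))
        assert (a.direction, a.ratio) == (b.direction, pytest.approx(b.ratio))

    def test_zero_counts_signalled(self):
        with pytest.raises(UndefinedMetricError):
            sex_bias_ratio(SexBreakdown("s", female=0, male=0, both=5, not_reported=5))
        with pytest.raises(UndefinedMetricError):
            sex_bias_ratio(SexBreakdown("s", female=10, male=0, both=0, not_reported=0))


class TestBinomialProportion:
    def test_symmetric_counts(self):
        p_hat, p_value, lo, hi = binomial_proportion_test(50, 50)
        assert p_hat == 0.5
        assert p_value == pytest.approx(1.0)
        assert lo < 50 < hi

    def test_extreme_counts_match_exact_tail(self):
        # all 10 one-sided: two-sided exact p = 2 * 0.5**10
        _, p_value, _, _ = binomial_proportion_test(10, 0)
        assert p_value == pytest.approx(min(1.0, 2 * 0.5 ** 10))

    def test_ci_shrinks_as_inverse_sqrt_n(self):
        _, _, lo1, hi1 = binomial_proportion_test(300, 200)
        _, _, lo4, hi4 = binomial_proportion_test(1200, 800)
        assert (hi4 - lo4) == pytest.approx((hi1 - lo1) / 2, rel=1e-9)

    def test_clopper_pearson_flag(self):
        _, _, lo, hi = binomial_proportion_test(60, 40, ci_method="exact")
        ci = stats.binomtest(60, 100, 0.5).proportion_ci(confidence_level=0.95,
                                                         method="exact")
        assert (lo, hi) == (pytest.approx(100 * ci.low), pytest.approx(100 * ci.high))

    def test_zero_total_rejected(self):
        with pytest.raises(InputError):
            binomial_proportion_test(0, 0)


def _anova_oracle(x):
    """Textbook SS formulas computed independently, cell by cell."""
    x = np.asarray(x, dtype=float)
    r, c = x.shape
    grand = x.sum() / (r * c)
    ss_rows = sum(c * (x[i, :].sum() / c - grand) ** 2 for i in range(r))
    ss_cols = sum(r * (x[:, j].sum() / r - grand) ** 2 for j in range(c))
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(r) for j in range(c))
    return ss_rows, ss_cols, ss_total - ss_rows - ss_cols


class TestTwoWayAnova:
    def test_constant_table_signals_undefined_f(self):
        res = two_way_anova_no_replication([[5.0, 5.0], [5.0, 5.0]])
        assert res.rows.ss == 0 and res.cols.ss == 0
        assert res.rows.f is None and res.rows.p_value is None

    def test_hand_computed_2x3_table(self):
        # rows {1,2,3} and {2,4,6}: worked by the SS formulas by hand
        res = two_way_anova_no_replication([[1, 2, 3], [2, 4, 6]])
        ss_rows, ss_cols, ss_resid = _anova_oracle([[1, 2, 3], [2, 4, 6]])
        assert res.rows.ss == pytest.approx(ss_rows)
        assert res.cols.ss == pytest.approx(ss_cols)
        assert res.residual.ss == pytest.approx(ss_resid)
        assert res.rows.df == 1 and res.cols.df == 2 and res.residual.df == 2
        assert res.rows.f == pytest.approx(res.rows.ms / res.residual.ms)

    def test_row_permutation_invariance(self):
        table = [[1.0, 4.0, 2.0], [3.0, 8.0, 5.0], [2.0, 6.0, 9.0]]
        res = two_way_anova_no_replication(table)
        perm = two_way_anova_no_replication([table[2], table[0], table[1]])
        assert perm.rows.ss == pytest.approx(res.rows.ss)
        assert perm.cols.ss == pytest.approx(res.cols.ss)

    def test_ss_decomposition_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = int(rng.integers(2, 8))
            c = int(rng.integers(2, 8))
            x = rng.uniform(0, 100, size=(r, c))
            res = two_way_anova_no_replication(x)
            total = res.rows.ss + res.cols.ss + res.residual.ss
            assert total == pytest.approx(res.ss_total, rel=1e-9)
            o_rows, o_cols, o_resid = _anova_oracle(x)
            assert res.rows.ss == pytest.approx(o_rows, rel=1e-9)
            assert res.cols.ss == pytest.approx(o_cols, rel=1e-9)
            assert res.residual.ss == pytest.approx(o_resid, rel=1e-9)

    def test_statsmodels_cross_check(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 100, size=(4, 5))
        res = two_way_anova_no_replication(x)
        rows = [(i, j, x[i, j]) for i in range(4) for j in range(5)]
        df = pd.DataFrame(rows, columns=["row", "col", "value"])
        fit = ols("value ~ C(row) + C(col)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res.rows.f == pytest.approx(table.loc["C(row)", "F"], rel=1e-9)
        assert res.cols.p_value == pytest.approx(table.loc["C(col)", "PR(>F)"], rel=1e-9)

    def test_too_small_table_rejected(self):
        with pytest.raises(InputError):
            two_way_anova_no_replication([[1.0, 2.0]])


class TestJournalIndexAndSpearman:
    def test_index_quotient(self):
        assert journal_reporting_index(30, 10) == 3.0
        assert journal_reporting_index(0, 10) == 0.0

    def test_zero_denominator_signalled(self):
        with pytest.raises(UndefinedMetricError):
            journal_reporting_index(10, 0)

    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r, _ = spearman_rank_corr(x, [10, 20, 30, 40])
        assert r == pytest.approx(1.0)
        r, _ = spearman_rank_corr(x, [40, 30, 20, 10])
        assert r == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 10, size=10)
        y = rng.uniform(0, 10, size=10)
        r, _ = spearman_rank_corr(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert r == pytest.approx(oracle, rel=1e-9)

    def test_guards(self):
        with pytest.raises(InputError):
            spearman_rank_corr([1, 2], [3, 4])
        with pytest.raises(UndefinedMetricError):
            spearman_rank_corr([1, 1, 1], [2, 3, 4])


class TestStratifiedSexBreakdown:
    def test_counts_sum(self):
        meta = MetadataTable({f"d{i}": MetadataRecord(
            year=2010, journal="J", disease_groups=frozenset({"cancer"}),
            subgroups=frozenset({"genetics"})) for i in range(12)})
        anns = [ann(f"d{i}", sex=["female", "male", "both", "none"][i % 4])
                for i in range(12)]
        [b] = sex_breakdown(anns, meta, "disease_group")
        assert (b.female, b.male, b.both, b.not_reported) == (3, 3, 3, 3)
        assert b.total == 12
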