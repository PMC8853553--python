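"""Statistics battery: frozen oracles, null calibration, ROUT behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glomorph as g
from glomorph.stereology import per_profile_glv


class TestNormality:
    def test_well_specified_null_passes(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            res = g.test_normality(rng.standard_normal(10_000))
            assert min(res["kolmogorov_smirnov"], res["dagostino_pearson"],
                       res["shapiro_wilk"]) > 0.01

    def test_clipped_cohort_volumes_are_non_gaussian(self, cohorts):
        # the ischemic left mode makes the clipped GLV distribution
        # sharply non-normal
        glv = per_profile_glv(cohorts["k2c1_clipped"])
        res = g.test_normality(glv)
        assert min(res["kolmogorov_smirnov"], res["dagostino_pearson"],
                   res["shapiro_wilk"]) < 1e-4

    def test_constant_vector_is_degenerate(self):
        res = g.test_normality(np.ones(20))
        assert res["degenerate"]
        assert np.isnan(res["shapiro_wilk"])

    def test_small_sample_omits_dagostino(self):
        res = g.test_normality([1.0, 2.0, 1.5, 2.5, 1.8, 2.2, 1.9])
        assert "dagostino_pearson" not in res
        assert "dagostino_pearson" in res["omitted"]

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            g.test_normality([1.0, 2.0])


class TestCompareTwo:
    def test_welch_textbook_example(self):
        # hand-computed: t = -1/sqrt(5/3/4 + 5/3/4) = -1.0954, df = 6
        res = g.compare_two([1, 2, 3, 4], [2, 3, 4, 5], force="welch_t")
        assert res.statistic == pytest.approx(-1.0954, abs=1e-4)
        assert res.details["df"] == pytest.approx(6.0)

    def test_mann_whitney_exact_separated_triples(self):
        # U = 0; exhaustive ranks give two-sided p = 2/C(6,3) = 0.1
        res = g.compare_two([1, 2, 3], [4, 5, 6], force="mann_whitney")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert not res.significant

    def test_identical_samples(self):
        res = g.compare_two([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], force="welch_t")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_auto_selects_mann_whitney_for_skewed_data(self):
        rng = np.random.default_rng(5)
        a = np.exp(rng.standard_normal(300) * 2.0)   # heavy lognormal
        b = np.exp(rng.standard_normal(300) * 2.0) + 1.0
        res = g.compare_two(a, b)
        assert res.test_name == "mann_whitney"
        assert res.details["auto"]

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            g.compare_two([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=20),
           st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_welch_antisymmetric_under_swap(self, a, b):
        r1 = g.compare_two(a, b, force="welch_t")
        r2 = g.compare_two(b, a, force="welch_t")
        if not np.isnan(r1.statistic):
            assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-9, abs=1e-12)
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9, abs=1e-12)

    def test_mann_whitney_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        a, b = rng.exponential(1.0, 40), rng.exponential(1.4, 35)
        p1 = g.compare_two(a, b, force="mann_whitney").p_value
        p2 = g.compare_two(np.log(a), np.log(b), force="mann_whitney").p_value
        assert p1 == pytest.approx(p2)

    def test_type_one_error_of_default_path(self):
        # Gaussian null, n=20 per group, 2000 simulations: the automatic
        # Welch/Mann-Whitney selection keeps the level near alpha = 0.01
        rng = np.random.default_rng(99)
        rejections = sum(
            g.compare_two(rng.standard_normal(20), rng.standard_normal(20)).significant
            for _ in range(2000))
        assert rejections / 2000 <= 0.015


class TestCompareMany:
    def test_separated_groups(self):
        rng = np.random.default_rng(1)
        groups = [x + 0.01 * rng.standard_normal(5) for x in (0.0, 1.0, 2.0)]
        res = g.compare_many(groups)
        assert res.test_name == "anova_posthoc"
        assert res.p_value < 1e-4
        assert all(p["significant"] for p in res.details["posthoc"])

    def test_null_level(self):
        rng = np.random.default_rng(42)
        rej = sum(g.compare_many([rng.standard_normal(30) for _ in range(3)]).significant
                  for _ in range(500))
        assert rej / 500 <= 0.03

    def test_two_groups_fall_through_to_welch(self):
        res = g.compare_many([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        assert res.test_name == "welch_t"


class TestCompareFrequencies:
    def test_closed_form_two_by_two(self):
        res = g.compare_frequencies(10, 100, 30, 100)
        assert res.statistic == pytest.approx(12.5)
        assert res.significant

    def test_equal_proportions(self):
        res = g.compare_frequencies(15, 150, 10, 100)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_rare_lesion_excess_detected(self):
        # 12/2400 vs 0/2400, the clipped-kidney hyalinosis scale
        res = g.compare_frequencies(12, 2400, 0, 2400)
        assert res.p_value < 0.01

    def test_thin_cells_use_exact_fallback(self):
        res = g.compare_frequencies(2, 50, 0, 50)
        assert res.details["exact"]
        assert res.p_value == pytest.approx(0.495, abs=0.01)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            g.compare_frequencies(5, 4, 0, 10)


class TestRout:
    def test_planted_outlier_removed(self):
        values = [1, 1.1, 0.9, 1.05, 0.95, 1.02, 0.98, 1.03, 0.97, 10]
        kept, outliers = g.remove_outliers_rout(values, q_pct=1.0)
        assert list(outliers) == [10]
        assert len(kept) == 9

    def test_identical_values_yield_no_outliers(self):
        kept, outliers = g.remove_outliers_rout(np.ones(15))
        assert outliers.size == 0
        assert kept.size == 15

    def test_small_sample_no_op_with_warning(self):
        with pytest.warns(UserWarning, match="ROUT skipped"):
            kept, outliers = g.remove_outliers_rout([1.0, 2.0, 3.0])
        assert outliers.size == 0

    def test_false_removal_rate_under_null(self):
        # clean normal samples: points removed at no more than ~Q = 1%
        rng = np.random.default_rng(7)
        removed = sum(g.remove_outliers_rout(rng.standard_normal(20))[1].size
                      for _ in range(2000))
        assert removed / (2000 * 20) <= 0.01

    def test_ten_sigma_contaminant_power(self):
        rng = np.random.default_rng(13)
        hits = 0
        for _ in range(300)        :
            x = rng.standard_normal(20)
            x[0] = 10.0
            _, out = g.remove_outliers_rout(x)
            hits += 10.0 in out
        assert hits / 300 >= 0.95


class TestPercentChange:
    def test_examples(self):
        assert g.percent_change([61.0], [100.0]) == pytest.approx(-39.0)
        assert g.percent_change([5.0, 5.0], [5.0, 5.0]) == 0.0
        # +240% is the same statement as 3.4-fold
        pct = g.percent_change([6.8], [2.0])
        assert pct == pytest.approx(240.0)
        assert 1 + pct / 100 == pytest.approx(3.4)

    def test_accepts_summaries(self):
        t = g.summarize([2.0, 4.0])
        c = g.summarize([1.0, 3.0])
        assert g.percent_change(t, c) == pytest.approx(50.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            g.percent_change([1.0, 2.0], [-1.0, 1.0])


class TestSummaries:
    def test_sem_definition(self):
        s = g.summarize([1.0, 2.0, 3.0, 4.0])
        assert s.n == 4
        assert s.sem == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            g.summarize([1.0])
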