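"""Classical tests, routing, and the rank-indexed FDR rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from megconn.group_analysis import (
    correlate,
    fdr_correct,
    independent_t,
    ks_normality,
    mann_whitney,
    run_group_comparison,
    t_from_summary,
)
from megconn.io_core import CohortTable, ParameterError


class TestPooledT:
    def test_hand_computed_small_samples(self):
        # means 2 vs 5, both SD 1 -> t = -3 / sqrt(2/3)
        r = independent_t([1, 2, 3], [4, 5, 6])
        assert r.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert round(r.statistic, 3) == -3.674

    def test_summary_equals_raw_to_machine_precision(self, rng):
        a = rng.standard_normal(22) * 3 + 1
        b = rng.standard_normal(18) * 2
        raw = independent_t(a, b)
        summ = t_from_summary(a.mean(), a.std(ddof=1), a.size,
                              b.mean(), b.std(ddof=1), b.size)
        assert summ.statistic == pytest.approx(raw.statistic, abs=1e-12)
        assert summ.p == pytest.approx(raw.p, abs=1e-12)

    def test_agrees_with_scipy_equal_var(self, rng):
        a = rng.standard_normal(15)
        b = rng.standard_normal(12) + 0.5
        r = independent_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_identical_samples_zero_t(self):
        r = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        assert t_from_summary(1, 0, 5, 1, 0, 5).statistic == 0.0
        assert np.isinf(t_from_summary(2, 0, 5, 1, 0, 5).statistic)


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p == pytest.approx(0.1)
        assert r.note == "exact"

    def test_identical_samples_p_one(self):
        r = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.p == pytest.approx(1.0)

    @given(st.integers(0, 2**15 - 1))
    def test_u_statistics_sum_identity(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal(6)
        b = rng.standard_normal(5)
        ua = mann_whitney(a, b).statistic
        ub = mann_whitney(b, a).statistic
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_exact_close_to_asymptotic_at_n6(self, rng):
        diffs = []
        for _ in range(20):
            a = rng.standard_normal(6)
            b = rng.standard_normal(6) + 0.5
            p_exact = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue
            p_asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue
            diffs.append(abs(p_exact - p_asym))
        assert max(diffs) < 0.02


class TestNormalityScreen:
    def test_normal_samples_pass(self):
        passes = 0
        for seed in range(30):
            x = np.random.default_rng(seed).standard_normal(200)
            passes += ks_normality(x).p > 0.05
        assert passes >= 27

    def test_exponential_samples_fail(self):
        fails = 0
        for seed in range(30):
            x = np.random.default_rng(seed).exponential(size=200)
            fails += ks_normality(x).p < 0.05
        assert fails >= 27

    def test_statistic_bounded(self, rng):
        r = ks_normality(rng.uniform(size=50))
        assert 0.0 <= r.statistic <= 1.0

    def test_constant_sample_non_normal_with_warning(self):
        with pytest.warns(UserWarning):
            r = ks_normality(np.ones(10))
        assert r.p == 0.0


class TestCorrelate:
    def test_linear_map_perfect_pearson(self):
        x = np.arange(10.0)
        r = correlate(x, 2 * x + 1, "pearson")
        assert r.statistic == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one(self):
        x = np.linspace(-2, 2, 15)
        y = x**3
        assert correlate(x, y, "spearman").statistic == pytest.approx(1.0)
        assert correlate(x, y, "pearson").statistic < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ParameterError):
            correlate(np.ones(10), np.arange(10.0), "pearson")


class TestFdr:
    def test_hand_worked_step_up_example(self):
        sig, ranks, thr, cutoff = fdr_correct([0.01, 0.02, 0.04, 0.2])
        np.testing.assert_allclose(thr, [0.0125, 0.025, 0.0375, 0.05])
        assert sig.tolist() == [True, True, False, False]
        assert cutoff == 0.02

    def test_all_ones_nothing_significant(self):
        sig, *_ = fdr_correct([1.0, 1.0, 1.0])
        assert not sig.any()

    def test_tied_p_values_get_average_rank(self):
        _, ranks, thr, _ = fdr_correct([0.02, 0.02, 0.5])
        np.testing.assert_allclose(ranks, [1.5, 1.5, 3.0])
        np.testing.assert_allclose(thr[:2], 0.05 * 1.5 / 3)

    def test_step_up_rejects_below_cutoff_even_over_own_threshold(self):
        # classic BH behaviour: rank-1 p exceeds its own threshold but is
        # swept in by the rank-2 acceptance
        sig, _, thr, cutoff = fdr_correct([0.03, 0.04])
        assert sig.tolist() == [True, True]
        assert thr[0] == pytest.approx(0.025)
        assert cutoff == 0.04

    def test_empty_input(self):
        sig, ranks, thr, cutoff = fdr_correct([])
        assert sig.size == 0 and cutoff == 0.0

    @given(st.integers(0, 2**15 - 1))
    def test_matches_benjamini_hochberg_when_distinct(self, seed):
        rng = np.random.default_rng(seed)
        p = np.unique(rng.uniform(size=12))
        rng.shuffle(p)
        sig, *_ = fdr_correct(p)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert sig.tolist() == ref.tolist()

    @given(st.integers(0, 2**15 - 1))
    def test_never_rejects_more_than_uncorrected(self, seed):
        p = np.random.default_rng(seed).uniform(size=10)
        sig, *_ = fdr_correct(p)
        assert sig.sum() <= (p < 0.05).sum()

    def test_invariant_to_input_order(self, rng):
        p = rng.uniform(size=9)
        sig, *_ = fdr_correct(p)
        perm = rng.permutation(9)
        sig2, *_ = fdr_correct(p[perm])
        assert sig2.tolist() == sig[perm].tolist()


def _toy_cohort(rng, delta=0.0):
    rows = []
    for i in range(12):
        group = "patient" if i < 6 else "control"
        scores = {s: float(rng.normal(100, 10)) for s in
                  ("VCI", "PRI", "WMI", "PSI", "FSIQ")}
        rows.append({"subject_id": f"S{i:02d}", "group": group, "age": 8,
                     "sex": "M", "course_months": 1.0, "n_seizures": 1,
                     **scores})
    metrics = []
    for i in range(12):
        for band in ("alpha", "beta"):
            shift = delta if (i < 6 and band == "beta") else 0.0
            metrics.append({"subject_id": f"S{i:02d}", "band": band,
                            "SA": rng.normal(2, 0.1) + shift,
                            "DA": rng.normal(4, 0.3),
                            "LA": rng.normal(3, 0.2),
                            "CA": rng.normal(0.5, 0.05) + shift})
    return CohortTable(subjects=pd.DataFrame(rows),
                       metrics=pd.DataFrame(metrics))


class TestGroupComparison:
    def test_single_variable_family_threshold_is_alpha(self, rng):
        cohort = _toy_cohort(rng)
        out = run_group_comparison(cohort, score_vars=("FSIQ",),
                                   metric_vars=())
        assert len(out) == 1
        assert out["rank_threshold"].iloc[0] == pytest.approx(0.05)

    def test_planted_metric_shift_detected(self, rng):
        cohort = _toy_cohort(rng, delta=1.0)
        out = run_group_comparison(cohort, score_vars=(),
                                   metric_vars=("CA",))
        beta = out[(out["comparison"] == "CA") & (out["band"] == "beta")]
        alpha_row = out[(out["comparison"] == "CA") & (out["band"] == "alpha")]
        assert bool(beta["significant"].iloc[0])
        assert not bool(alpha_row["significant"].iloc[0])

    def test_two_group_requirement(self, rng):
        cohort = _toy_cohort(rng)
        cohort.subjects.loc[:, "group"] = "patient"
        with pytest.raises(ParameterError):
            run_group_comparison(cohort)

    def test_significance_consistent_with_reported_cutoff(self, rng):
        out = run_group_comparison(_toy_cohort(rng, delta=0.6))
        for _, row in out.iterrows():
            assert row["significant"] == (row["p"] <= row["fdr_threshold"])
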