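import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from lifelines.statistics import logrank_test

import oracles
from mircoop.survstats import km_estimate, logrank_compare, optimize_cutoff


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = km_estimate([2.0, 5.0, 7.0], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_three_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0], atol=1e-15)

    def test_censored_case_recomputed_product_limit(self):
        # times (1, 2+, 3): S(1) = 2/3, then the last subject's event at 3
        # with one at risk drives S(3) = 2/3 * (1 - 1/1) = 0
        km = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3, abs=1e-12)
        assert km.survival_at(3.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_on_tied_mixed_data(self):
        times = [3, 5, 5, 5, 8, 8, 10, 12, 12, 15]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0]
        km = km_estimate(times, events)
        ref = oracles.bruteforce_km(times, events)
        assert list(km.times) == [t for t, *_ in ref]
        for (tj, n, d, s), sv, nr, ne in zip(ref, km.survival, km.n_risk, km.n_event):
            assert nr == n and ne == d
            assert sv == pytest.approx(s, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_matches_bruteforce_tabulation(self, twelve_sample_surv):
        labels, times, events = twelve_sample_surv
        cmp_ = logrank_compare(labels, times, events)
        chi2, o1, e1, o2, e2 = oracles.bruteforce_logrank(labels, times, events)
        assert cmp_.chi2 == pytest.approx(chi2, abs=1e-10)
        assert cmp_.o1 == o1 and cmp_.o2 == o2
        assert cmp_.e1 == pytest.approx(e1, abs=1e-12)
        assert cmp_.e1 + cmp_.e2 == pytest.approx(cmp_.o1 + cmp_.o2, abs=1e-9)
        assert cmp_.hr == pytest.approx((o1 / e1) / (o2 / e2), abs=1e-10)

    def test_duplicated_group_exactly_null(self):
        t = np.array([1.0, 3.0, 4.0, 7.0, 9.0])
        e = np.array([1, 1, 0, 1, 1])
        cmp_ = logrank_compare(
            np.r_[np.ones(5, int), np.zeros(5, int)], np.r_[t, t], np.r_[e, e]
        )
        assert cmp_.chi2 == 0.0
        assert cmp_.hr == 1.0

    def test_label_swap_inverts_hr(self, twelve_sample_surv):
        labels, times, events = twelve_sample_surv
        a = logrank_compare(labels, times, events)
        b = logrank_compare(1 - labels, times, events)
        assert b.chi2 == pytest.approx(a.chi2, rel=1e-12)
        assert b.hr == pytest.approx(1.0 / a.hr, rel=1e-12)

    def test_agrees_with_lifelines(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.7).astype(int)
        g = rng.integers(0, 2, 80)
        mine = logrank_compare(g, t, e)
        ref = logrank_test(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    @given(st.sampled_from([1.0, 2.0, 0.5]), st.floats(0.1, 5.0))
    def test_monotone_time_transform_invariance(self, power, scale):
        labels = np.array([1, 1, 1, 0, 0, 0, 1, 0])
        times = np.array([3.0, 5.0, 8.0, 2.0, 5.0, 9.0, 11.0, 12.0])
        events = np.array([1, 0, 1, 1, 1, 0, 1, 1])
        a = logrank_compare(labels, times, events)
        b = logrank_compare(labels, scale * times**power, events)
        assert b.chi2 == pytest.approx(a.chi2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            logrank_compare([1, 1, 1], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_no_events_reports_undefined(self):
        cmp_ = logrank_compare([1, 0, 1, 0], [1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        assert np.isnan(cmp_.chi2)
        assert np.isnan(cmp_.hr)
        assert cmp_.hr_reason != ""


class TestOptimizeCutoff:
    def test_only_median_split_feasible(self):
        # 10 distinct values, grid {0.25, 0.5, 0.75}: the quartile thresholds
        # put 3 samples on the small side (3 < 0.35 * 10), so under
        # min_group_frac = 0.35 only the median split survives feasibility
        values = np.arange(1.0, 11.0)
        times = np.array([2.0, 3, 4, 5, 6, 7, 8, 9, 10, 11])
        events = np.ones(10, int)
        res = optimize_cutoff(values, times, events, grid=[0.25, 0.5, 0.75],
                              min_group_frac=0.35)
        assert res.quantile == 0.5
        assert res.cutoff == np.quantile(values, 0.5)
        assert res.n_low == 5 and res.n_high == 5
        grid = res.grid_evaluated
        assert grid.shape[0] == 3
        assert grid["feasible"].tolist() == [False, True, False]

    def test_perfect_marker_recovers_planted_split(self):
        rng = np.random.default_rng(4)
        n = 60
        group = np.r_[np.ones(15, int), np.zeros(45, int)]
        values = np.where(group == 1, -2.0, 0.0) + 0.01 * rng.standard_normal(n)
        times = np.where(group == 1, rng.exponential(2, n), rng.exponential(30, n))
        events = np.ones(n, int)
        res = optimize_cutoff(values, times, events)
        low = values <= res.cutoff
        assert (low == (group == 1)).all()

    def test_reports_search_multiplicity(self):
        rng = np.random.default_rng(5)
        res = optimize_cutoff(
            rng.standard_normal(50), rng.exponential(10, 50), np.ones(50, int)
        )
        assert res.n_candidates == (res.grid_evaluated["feasible"]).sum()
        assert res.cutoff in set(res.grid_evaluated["threshold"])

    def test_no_feasible_candidate_errors(self):
        values = np.zeros(10)
        with pytest.raises(ValueError, match="feasible"):
            optimize_cutoff(values, np.arange(1.0, 11.0), np.ones(10, int),
                            grid=[0.1], min_group_frac=0.4)
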