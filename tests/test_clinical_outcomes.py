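"""Survival machinery: KM product-limit, log-rank risk-table oracle, Cox
Newton step oracle, lifelines cross-checks, cutoff scan and RECIST tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdac_clonevo import (
    cox_ph,
    cutoff_scan,
    km_estimator,
    logrank_test,
    median_survival,
    response_association,
    simulate_survival,
)


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = km_estimator([1.0, 2.0, 3.0], [0, 0, 0])
        assert len(km) == 0  # no steps: S(t) = 1 throughout

    def test_three_events_product_limit(self):
        km = km_estimator([1, 2, 3], [1, 1, 1])
        assert km["survival"].tolist() == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km["n_at_risk"].tolist() == [3, 2, 1]

    def test_duplicate_event_times_single_step(self):
        km = km_estimator([1, 1, 2], [1, 1, 1])
        assert len(km) == 2
        assert km["n_events"].tolist() == [2, 1]
        assert km["survival"].iloc[0] == pytest.approx(1 / 3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([-1.0, 2.0], [1, 1])

    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=20, unique=True))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_closed_form_with_unique_event_times(self, times):
        """One event per distinct time: S = prod(1 - 1/n_i) exactly."""
        km = km_estimator(times, [1] * len(times))
        n = len(times)
        expected = 1.0
        for i, _ in enumerate(sorted(times)):
            expected *= 1 - 1 / (n - i)
            assert km["survival"].iloc[i] == pytest.approx(expected, abs=1e-12)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        km = km_estimator(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in km.iterrows():
            assert kmf.predict(row["time"]) == pytest.approx(row["survival"], abs=1e-10)

    def test_median_survival(self):
        assert median_survival([1, 2, 3, 4], [1, 1, 1, 1]) == 2.0
        assert median_survival([1, 2], [0, 0]) == np.inf


def hand_logrank_oracle(times, events, in_a):
    """Risk-table enumeration: O-E and hypergeometric variance per event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    in_a = np.asarray(in_a, bool)
    o = e = v = 0.0
    for t in sorted(set(times[events == 1])):
        n = (times >= t).sum()
        na = (in_a & (times >= t)).sum()
        d = ((times == t) & (events == 1)).sum()
        da = ((times == t) & (events == 1) & in_a).sum()
        o += da
        e += d * na / n
        if n > 1:
            v += d * (na / n) * (1 - na / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


class TestLogrank:
    def test_worked_example_matches_hand_oracle_exactly(self):
        """A = {1,2,3}, B = {4,5,6}, all events: O_A = 3, E_A = 1/2 + 2/5 +
        1/4 = 1.15, V = 0.6775."""
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        group = [0, 0, 0, 1, 1, 1]
        res = logrank_test(times, events, group)
        assert res.observed_a == 3
        assert res.expected_a == pytest.approx(1.15, abs=1e-12)
        assert res.statistic == pytest.approx((3 - 1.15) ** 2 / 0.6775, abs=1e-12)
        assert res.statistic == pytest.approx(
            hand_logrank_oracle(times, events, [True] * 3 + [False] * 3), abs=1e-12)

    def test_identical_groups_degenerate(self):
        res = logrank_test([1, 2, 3, 1, 2, 3], [1] * 6, [0] * 3 + [1] * 3)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        for _ in range(5):
            t = rng.exponential(10, 60)
            e = rng.integers(0, 2, 60)
            g = rng.integers(0, 2, 60)
            if len(np.unique(g)) < 2:
                continue
            ours = logrank_test(t, e, g)
            ll = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
            assert ours.statistic == pytest.approx(ll.test_statistic, abs=1e-8)
            assert ours.p == pytest.approx(ll.p_value, abs=1e-8)

    def test_invariance_under_monotone_time_relabeling(self, rng):
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        g = np.arange(40) % 2
        a = logrank_test(t, e, g)
        b = logrank_test(t**2, e, g)  # strictly monotone transform
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def test_single_newton_step_matches_hand_calculation(self):
        """Times 1,2,3 all events, x = (1,0,0), beta = 0: U = 2/3, I = 2/9,
        so one Newton step lands at beta = 3."""
        df = pd.DataFrame(dict(os_months=[1.0, 2.0, 3.0], event=[1, 1, 1],
                               x=[1.0, 0.0, 0.0]))
        res = cox_ph(df, ["x"], max_iter=1, tol=0.0)
        assert res.summary.loc["x", "coef"] == pytest.approx(3.0, abs=1e-10)

    def test_matches_lifelines_breslow(self, rng):
        from lifelines import CoxPHFitter

        n = 120
        x1 = rng.normal(size=n)
        x2 = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.5 * x1 - 0.3 * x2))
        e = (rng.random(n) < 0.8).astype(int)
        df = pd.DataFrame(dict(os_months=t, event=e, x1=x1, x2=x2))
        ours = cox_ph(df, ["x1", "x2"])
        cph = CoxPHFitter().fit(df, duration_col="os_months", event_col="event")
        for c in ("x1", "x2"):
            assert ours.summary.loc[c, "coef"] == pytest.approx(
                cph.params_[c], abs=1e-4)
            assert ours.summary.loc[c, "se"] == pytest.approx(
                cph.standard_errors_[c], abs=1e-4)

    def test_constant_covariate_named_in_error(self):
        df = pd.DataFrame(dict(os_months=[1, 2, 3, 4], event=[1, 1, 1, 1],
                               grade=[2.0, 2.0, 2.0, 2.0]))
        with pytest.raises(ValueError, match="grade"):
            cox_ph(df, ["grade"])

    def test_separation_flagged(self):
        # perfect separation: all events in one covariate class first
        df = pd.DataFrame(dict(os_months=[1, 2, 3, 10, 11, 12], event=[1] * 6,
                               x=[1.0, 1.0, 1.0, 0.0, 0.0, 0.0]))
        res = cox_ph(df, ["x"], max_iter=100)
        assert res.monotone_likelihood_warning

    def test_two_group_rate_ratio_limit(self, rng):
        """Without censoring the Cox HR for a binary covariate approaches the
        exponential rate ratio."""
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
        df = pd.DataFrame(dict(os_months=t, event=np.ones(n, int), x=x))
        res = cox_ph(df, ["x"])
        assert res.summary.loc["x", "hr"] == pytest.approx(2.0, rel=0.10)


class TestCutoffScan:
    def test_admissibility_constraint_exact(self, rng):
        """A 5 vs 55 split at N = 60 with min_group_frac = 0.10 is
        inadmissible (5 < 6)."""
        bf = np.concatenate([np.full(30, 0.11), np.full(25, 0.20), np.full(5, 0.30)])
        t = rng.exponential(10, 60)
        e = np.ones(60, int)
        scan = cutoff_scan(bf, t, e)
        row25 = scan.table[scan.table.cutoff == 0.25].iloc[0]
        assert row25.n_high == 5 and not row25.admissible
        row15 = scan.table[scan.table.cutoff == 0.15].iloc[0]
        assert row15.n_high == 30 and row15.n_low == 30 and row15.admissible

    def test_no_admissible_cutoff_returns_none(self, rng):
        bf = np.full(20, 0.50)  # every cutoff puts all patients in one group
        scan = cutoff_scan(bf, rng.exponential(10, 20), np.ones(20, int))
        assert scan.chosen_cutoff is None
        assert not scan.table.admissible.any()

    def test_scan_is_bit_reproducible(self, rng):
        bf = rng.uniform(0.05, 0.5, 60)
        t, e = simulate_survival(bf, 0.22, 5.0, 0.07, 0.01, 48.0, rng)
        a = cutoff_scan(bf, t, e)
        b = cutoff_scan(bf, t, e)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.chosen_cutoff == b.chosen_cutoff

    def test_chosen_cutoff_is_lowest_admissible_significant(self, rng):
        bf = rng.uniform(0.05, 0.5, 80)
        t, e = simulate_survival(bf, 0.22, 8.0, 0.07, 0.01, 48.0, rng)
        scan = cutoff_scan(bf, t, e)
        if scan.chosen_cutoff is not None:
            tab = scan.table
            sig = tab[tab.admissible & (tab.p < scan.alpha)]
            assert scan.chosen_cutoff == sig.cutoff.min()

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            cutoff_scan([0.1] * 5, [1] * 5, [1] * 5)


class TestResponseAssociation:
    def test_planted_linear_coupling(self, rng):
        bf = rng.uniform(0.0, 0.6, 40)
        change = -50 + 150 * bf + rng.normal(0, 15, 40)
        res = response_association(pd.Series(bf), pd.Series(change), cutoff=0.22)
        assert res.r > 0.5 and res.r_p < 0.01
        assert res.mean_change_high > res.mean_change_low
        assert res.ranksum_p < 0.05

    def test_degenerate_identical_groups(self):
        bf = pd.Series([0.1, 0.15, 0.2, 0.3, 0.35, 0.4])
        change = pd.Series([5.0] * 6)
        res = response_association(bf, change, cutoff=0.22)
        assert res.undefined
        assert res.ranksum_p == 1.0

    def test_small_groups_skip_ranksum(self):
        bf = pd.Series([0.1, 0.1, 0.1, 0.1, 0.5])
        change = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        res = response_association(bf, change, cutoff=0.22)
        assert np.isnan(res.ranksum_p)
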