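"""Kaplan–Meier, log-rank, Cox PH and nested-model machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from ihcsig import (
    NOT_REACHED,
    cox_fit,
    km_curve,
    km_median,
    logrank,
    nested_lr_test,
    significance_band,
)
from tests.conftest import exponential_surv


# ---------------------------------------------------------------------------
# independent first-principles oracles
# ---------------------------------------------------------------------------


def logrank_oracle(ta, ea, tb, eb):
    """Two-group log-rank chi-square from the observed-minus-expected sums."""
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def naive_partial_likelihood(beta, x, times, events):
    """Brute-force Breslow log partial likelihood (tie-free usage)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] == 1:
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------


class TestKaplanMeier:
    def test_no_censoring_reduces_to_ecdf(self, rng):
        times = rng.uniform(1, 10, 40)
        curve = km_curve(times, np.ones(40, dtype=int))
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_all_censored_is_flat_with_median_not_reached(self):
        curve = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.allclose(curve.survival, 1.0)
        med = km_median(curve)
        assert med.median == NOT_REACHED

    def test_exponential_curve_matches_closed_form(self, rng):
        lam = math.log(2) / 10.0
        times, events = exponential_surv(rng, 2000, lam, 0.02)
        curve = km_curve(times, events)
        for t in (5.0, 10.0, 20.0):
            idx = np.searchsorted(curve.event_times, t, side="right") - 1
            assert abs(curve.survival[idx] - math.exp(-lam * t)) < 0.03

    def test_exponential_median_near_ln2_over_lambda(self, rng):
        times, events = exponential_surv(rng, 2000, math.log(2) / 10.0, 0.02)
        med = km_median(km_curve(times, events))
        assert 9.0 <= med.median <= 11.0
        assert med.ci[0] <= med.median <= med.ci[1]

    def test_survival_exactly_half_defines_median(self):
        # S(2) = 0.5 exactly with four uncensored deaths
        med = km_median(km_curve([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
        assert med.median == 2.0

    def test_monotone_and_starts_at_one(self, cohort_163):
        curve = km_curve(cohort_163["os_time"], cohort_163["os_event"])
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert curve.survival[0] <= 1.0
        assert np.all(curve.ci_lower <= curve.survival + 1e-9)
        assert np.all(curve.survival <= curve.ci_upper + 1e-9)

    def test_tied_record_order_irrelevant(self):
        t = np.array([2.0, 2.0, 5.0, 5.0, 7.0])
        e = np.array([1, 0, 1, 1, 0])
        a = km_curve(t, e)
        order = [1, 0, 3, 2, 4]
        b = km_curve(t[order], e[order])
        assert np.allclose(a.survival, b.survival)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        res = logrank(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_worked_example_matches_oracle(self):
        ta, ea = np.array([1.0, 3.0, 5.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 4.0, 6.0]), np.array([1, 0, 1])
        res = logrank(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-9)

    def test_symmetric_under_group_swap(self, rng):
        ta, ea = exponential_surv(rng, 30, 0.2, 0.05)
        tb, eb = exponential_surv(rng, 25, 0.1, 0.05)
        r1 = logrank(ta, ea, tb, eb)
        r2 = logrank(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([1.0, 2.0], [0, 0], [3.0], [0])

    def test_matches_cox_score_test_on_tie_free_binary_fixture(self, rng):
        # the log-rank statistic equals the Cox partial-likelihood score test
        n = 60
        x = np.array([0, 1] * (n // 2), dtype=float)
        times = rng.exponential(1.0 / (0.1 * np.exp(0.7 * x)))
        assert len(set(times)) == n  # tie-free
        events = np.ones(n, dtype=int)
        u = 0.0
        info = 0.0
        for i in range(n):
            risk = times >= times[i]
            m = x[risk].mean()
            u += x[i] - m
            info += np.mean(x[risk] ** 2) - m**2
        score_stat = u**2 / info
        lr = logrank(times[x == 1], events[x == 1], times[x == 0], events[x == 0])
        assert abs(lr.statistic - score_stat) / score_stat < 1e-6


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


class TestCox:
    def test_recovers_binary_log_hazard_ratio(self, rng):
        x = rng.integers(0, 2, 2000).astype(float)
        t_lat = rng.exponential(1.0 / (0.1 * np.exp(math.log(2) * x)))
        c = rng.exponential(20.0, 2000)
        fit = cox_fit(x, np.minimum(t_lat, c), (t_lat <= c).astype(int))
        assert fit.converged
        assert abs(fit.coefficients[0] - math.log(2)) <= 0.15

    def test_null_covariate_coefficient_near_zero(self, rng):
        x = rng.normal(size=2000)
        times, events = exponential_surv(rng, 2000, 0.1, 0.03)
        fit = cox_fit(x, times, events)
        assert abs(fit.coefficients[0]) < 0.1

    def test_single_covariate_matches_grid_search_oracle(self, rng):
        n = 60
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
        events = np.ones(n, dtype=int)
        fit = cox_fit(x, times, events)
        grid = np.arange(-2.0, 2.0, 1e-3)
        lls = [naive_partial_likelihood(b, x, times, events) for b in grid]
        best = grid[int(np.argmax(lls))]
        assert abs(fit.coefficients[0] - best) <= 1.5e-3

    def test_matches_lifelines_on_multivariate_fit(self, rng):
        n, p = 400, 4
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"c{i}" for i in range(p)])
        beta = np.array([0.5, -0.4, 0.0, 0.2])
        t_lat = rng.exponential(1.0 / (0.1 * np.exp(X.to_numpy() @ beta)))
        c = rng.exponential(15.0, n)
        times, events = np.minimum(t_lat, c), (t_lat <= c).astype(int)
        mine = cox_fit(X, times, events)
        df = X.copy()
        df["t"], df["e"] = times, events
        ref = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(mine.coefficients, ref.params_.to_numpy(), atol=1e-5)
        assert np.allclose(mine.standard_errors, ref.standard_errors_.to_numpy(), atol=1e-5)
        assert mine.log_partial_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-5)

    def test_efron_matches_lifelines_on_tied_data(self, rng):
        x = rng.integers(0, 2, 300).astype(float)
        t_lat = rng.exponential(1.0 / (0.2 * np.exp(0.6 * x)))
        times = np.ceil(t_lat)  # heavy ties
        events = np.ones(300, dtype=int)
        mine = cox_fit(x, times, events, tie_method="efron")
        ref = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": times, "e": events}), "t", "e"
        )
        assert mine.coefficients[0] == pytest.approx(float(ref.params_.iloc[0]), abs=1e-6)

    def test_breslow_and_efron_agree_without_ties(self, rng):
        x = rng.normal(size=100)
        times = rng.exponential(1.0 / (0.1 * np.exp(0.4 * x)))
        events = np.ones(100, dtype=int)
        fe = cox_fit(x, times, events, tie_method="efron")
        fb = cox_fit(x, times, events, tie_method="breslow")
        assert fe.coefficients[0] == pytest.approx(fb.coefficients[0], abs=1e-9)

    def test_centering_equivariance(self, rng):
        x = rng.normal(5.0, 2.0, size=300)
        times, events = exponential_surv(rng, 300, 0.1, 0.02)
        f1 = cox_fit(x, times, events)
        f2 = cox_fit(x - x.mean(), times, events)
        assert f1.coefficients[0] == pytest.approx(f2.coefficients[0], abs=1e-8)

    def test_perfect_separation_flagged_not_raised(self):
        # covariate orders survival perfectly -> monotone likelihood
        times = np.arange(1.0, 21.0)
        events = np.ones(20, dtype=int)
        x = (times > 10).astype(float)
        fit = cox_fit(x, times, events)
        assert not fit.converged

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            cox_fit(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=int))


# ---------------------------------------------------------------------------
# Nested comparison and banding
# ---------------------------------------------------------------------------


class TestNested:
    def test_identical_models_give_p_one(self, rng):
        x = rng.normal(size=100)
        times, events = exponential_surv(rng, 100, 0.1, 0.02)
        fit = cox_fit(pd.DataFrame({"a": x}), times, events)
        comp = nested_lr_test(fit, fit)
        assert comp.lr_statistic == 0.0
        assert comp.p_value == 1.0

    def test_non_nested_rejected(self, rng):
        times, events = exponential_surv(rng, 100, 0.1, 0.02)
        fa = cox_fit(pd.DataFrame({"a": rng.normal(size=100)}), times, events)
        fb = cox_fit(pd.DataFrame({"b": rng.normal(size=100)}), times, events)
        with pytest.raises(ValueError):
            nested_lr_test(fa, fb)

    def test_power_against_generating_indicator(self):
        # adding the true HR-2 indicator at n=300 should be detected >= 80%
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            sig = rng.integers(0, 2, 300).astype(float)
            noise = rng.normal(size=300)
            t_lat = rng.exponential(1.0 / (0.08 * np.exp(math.log(2) * sig)))
            c = rng.exponential(25.0, 300)
            times, events = np.minimum(t_lat, c), (t_lat <= c).astype(int)
            reduced = cox_fit(pd.DataFrame({"noise": noise}), times, events)
            full = cox_fit(pd.DataFrame({"noise": noise, "sig": sig}), times, events)
            if nested_lr_test(reduced, full).p_value <= 0.05:
                hits += 1
        assert hits / n_rep >= 0.80


class TestSignificanceBand:
    @pytest.mark.parametrize(
        "p,symbol",
        [
            (0.3, "-"),
            (0.051, "-"),
            (0.05, "+"),
            (0.025, "+"),
            (0.005, "++"),
            (0.0006, "++"),
            (0.0005, "+++"),
            (0.0001, "+++"),
            (1.0, "-"),
        ],
    )
    def test_banding_table(self, p, symbol):
        assert significance_band(p) == symbol

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            significance_band(bad)
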