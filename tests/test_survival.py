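"""Survival statistics: dichotomization, KM, log-rank, BH, Cox, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from texhist import (
    DegenerateSplitError,
    MedianSplitScreen,
    ForwardWaldCoxSelector,
    bh_adjust,
    dichotomize_at_median,
    fit_cox,
    forward_wald_select,
    km_estimate,
    logrank_test,
    run_univariate_screen,
)


class TestDichotomize:
    def test_even_n_median(self):
        threshold, above, _ = dichotomize_at_median([1, 2, 3, 4])
        assert threshold == 2.5
        np.testing.assert_array_equal(above, [False, False, True, True])

    def test_ties_go_below(self):
        threshold, above, _ = dichotomize_at_median([1, 2, 2, 5])
        assert threshold == 2.0
        np.testing.assert_array_equal(above, [False, False, False, True])

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            dichotomize_at_median([3.0, 3.0, 3.0])

    def test_missing_values_counted(self):
        _, above, n_missing = dichotomize_at_median([1.0, np.nan, 2.0, 3.0])
        assert n_missing == 1
        assert above.size == 3


class TestKaplanMeier:
    def test_uncensored_median(self):
        km = km_estimate([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert km.median == 3

    def test_all_censored_median_not_reached(self):
        km = km_estimate([5, 8, 11], [0, 0, 0])
        assert np.isinf(km.median)
        assert km.median_label == "Not reached"

    def test_hand_computed_censored_fixture(self):
        """times {1, 2+, 3, 4+, 5}: S(1)=4/5, S(3)=4/5*2/3, S(5)=0."""
        km = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 0, 1])
        s = dict(zip(km.timeline, km.survival))
        assert s[1.0] == pytest.approx(0.8)
        assert s[3.0] == pytest.approx(0.8 * 2 / 3)
        assert s[5.0] == pytest.approx(0.0)
        assert km.median == 5.0  # smallest t with S(t) <= 0.5

    def test_no_censoring_reproduces_empirical_survival(self, rng):
        t = rng.exponential(10, 40)
        km = km_estimate(t, np.ones(40, bool))
        for ti, si in zip(km.timeline, km.survival):
            assert si == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1.0, 2.0], [1, 1])


def naive_logrank(ta, ea, tb, eb):
    """O/E contingency computation at each distinct event time, from
    scratch (the textbook 1-df log-rank statistic)."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(ta.size, bool), np.ones(tb.size, bool)])
    O_minus_E = 0.0
    V = 0.0
    for t in np.unique(t_all[e_all]):
        at_risk = t_all >= t
        n = at_risk.sum()
        n1 = (at_risk & grp).sum()
        d = (e_all & (t_all == t)).sum()
        d1 = (e_all & (t_all == t) & grp).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_oe_table_on_small_fixture(self):
        ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
        tb, eb = [2.0, 4.0, 6.0], [1, 0, 1]
        stat, _ = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(naive_logrank(ta, ea, tb, eb), rel=1e-10)

    def test_invariant_under_time_rescaling(self, rng):
        ta, tb = rng.exponential(1, 30), rng.exponential(1.5, 30)
        e = np.ones(30, bool)
        s1, _ = logrank_test(ta, e, tb, e)
        s2, _ = logrank_test(10 * ta, e, 10 * tb, e)
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0], [0], [2.0], [0])


class TestBenjaminiHochberg:
    def test_worked_example(self):
        adjusted, reject = bh_adjust([0.01, 0.02, 0.04], q=0.3)
        np.testing.assert_allclose(adjusted, [0.03, 0.03, 0.04])
        assert reject.all()

    def test_single_p_is_identity(self):
        adjusted, _ = bh_adjust([0.2])
        assert adjusted[0] == pytest.approx(0.2)

    def test_equal_ps_stay_equal(self):
        adjusted, _ = bh_adjust([0.1, 0.1, 0.1])
        np.testing.assert_allclose(adjusted, [0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_adjusted_monotone_in_rank_and_at_least_raw(self, ps):
        adjusted, _ = bh_adjust(ps, q=0.3)
        order = np.argsort(ps)
        assert (np.diff(adjusted[order]) >= -1e-12).all()
        assert (adjusted >= np.asarray(ps) - 1e-12).all()

    def test_q_one_flags_everything(self):
        _, reject = bh_adjust([0.2, 0.8, 0.99], q=1.0)
        assert reject.all()


def breslow_neg_loglik(beta, x, times, events):
    """Breslow partial log-likelihood of a single covariate, from scratch."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    ll = 0.0
    for t in np.unique(times[events]):
        dead = events & (times == t)
        risk = times >= t
        ll += beta * x[dead].sum()
        ll -= dead.sum() * np.log(np.exp(beta * x[risk]).sum())
    return -ll


COX_FIXTURE = dict(
    x=np.array([0, 0, 0, 0, 1, 1, 1, 1], float),
    times=np.array([5.0, 8.0, 12.0, 20.0, 1.0, 2.0, 6.0, 10.0]),
    events=np.array([1, 1, 0, 1, 1, 1, 1, 0], bool),
)


class TestCox:
    def test_null_effect_gives_unit_hazard_ratio(self):
        t = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        e = np.ones(8, bool)
        x = pd.DataFrame({"g": [0, 1, 0, 1, 0, 1, 0, 1]})
        # identical survival in both arms by pairing times across groups
        t_paired = np.array([1.0, 1, 3, 3, 5, 5, 7, 7])
        fit = fit_cox(x, t_paired, e)
        assert fit.loc["g", "HR"] == pytest.approx(1.0, abs=0.05)

    def test_matches_partial_likelihood_scan_oracle(self):
        """Newton fit agrees with a 1-D minimization of the from-scratch
        Breslow partial likelihood to 1e-4 (untied event times, so the tie
        convention is immaterial)."""
        fx = COX_FIXTURE
        fit = fit_cox(pd.DataFrame({"x": fx["x"]}), fx["times"], fx["events"])
        res = minimize_scalar(
            breslow_neg_loglik,
            bounds=(-5, 5),
            method="bounded",
            args=(fx["x"], fx["times"], fx["events"]),
            options={"xatol": 1e-10},
        )
        assert fit.loc["x", "coef"] == pytest.approx(res.x, abs=1e-4)

    def test_ci_brackets_hr(self):
        fx = COX_FIXTURE
        fit = fit_cox(pd.DataFrame({"x": fx["x"]}), fx["times"], fx["events"])
        row = fit.loc["x"]
        assert row["CI95_low"] < row["HR"] < row["CI95_high"]
        assert row["HR"] > 0

    def test_agrees_with_lifelines_on_random_data(self, rng):
        """Independent cross-check against lifelines' Cox implementation
        (Efron ties; untied data so conventions coincide)."""
        from lifelines import CoxPHFitter

        n = 80
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        t += rng.uniform(0, 1e-9, n)  # break accidental ties
        e = np.ones(n, bool)
        fit = fit_cox(pd.DataFrame({"x": x}), t, e)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"x": x, "t": t, "e": e.astype(int)}), "t", "e"
        )
        assert fit.loc["x", "coef"] == pytest.approx(
            cph.params_["x"], abs=1e-5
        )

    def test_sign_consistent_with_logrank_direction(self, rng):
        x = np.repeat([0.0, 1.0], 40)
        t = rng.exponential(1.0 / np.exp(1.0 * x))
        e = np.ones(80, bool)
        fit = fit_cox(pd.DataFrame({"x": x}), t, e)
        km0 = km_estimate(t[x == 0], e[x == 0])
        km1 = km_estimate(t[x == 1], e[x == 1])
        assert (fit.loc["x", "coef"] > 0) == (km1.median < km0.median)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(
                pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}),
                [1, 2, 3, 4], [1, 1, 1, 1],
            )


class TestForwardWald:
    def _simulated(self, rng, n=200, hr=3.0):
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0 / np.exp(np.log(hr) * x))
        e = np.ones(n, bool)
        return x, t, e

    def test_single_strong_candidate_selected(self, rng):
        x, t, e = self._simulated(rng)
        res = forward_wald_select(pd.DataFrame({"m": x}), t, e)
        assert res.covariates == ["m"]
        assert res.hr[0] > 1

    def test_duplicated_marker_enters_once(self, rng):
        x, t, e = self._simulated(rng)
        res = forward_wald_select(pd.DataFrame({"m1": x, "m2": x}), t, e)
        assert len(res.covariates) == 1

    def test_empty_candidate_set_is_valid_empty_model(self, rng):
        res = forward_wald_select(
            pd.DataFrame(index=range(10)), rng.exponential(1, 10),
            np.ones(10, bool),
        )
        assert res.covariates == []

    def test_null_candidates_rarely_selected(self):
        """With 5 null markers and entry alpha=0.05, the chance of selecting
        at least one is ~1-(1-alpha)^5 ~ 0.23 (correlated steps make this
        approximate); 200 simulations must fall well inside [0.1, 0.4]."""
        rng = np.random.default_rng(3)
        n, reps, hits = 60, 200, 0
        for _ in range(reps):
            X = pd.DataFrame(
                rng.binomial(1, 0.5, (n, 5)).astype(float),
                columns=[f"m{i}" for i in range(5)],
            )
            t = rng.exponential(1.0, n)
            res = forward_wald_select(X, t, np.ones(n, bool))
            hits += len(res.covariates) > 0
        assert 0.1 < hits / reps < 0.4


class TestScreen:
    def _table(self, rng, n=120, effect=True):
        marker = rng.normal(0, 1, n)
        lam = 0.05 * np.exp(1.0 * marker if effect else 0.0)
        t = rng.exponential(1.0 / lam)
        c = rng.uniform(0, 60, n)
        return pd.DataFrame(
            {
                "marker": marker,
                "noise": rng.normal(0, 1, n),
                "os_months": np.minimum(t, c),
                "os_event": (t <= c).astype(int),
            }
        )

    def test_constructed_marker_flagged_with_correct_direction(self, rng):
        table = self._table(rng)
        results, _ = run_univariate_screen(
            table, "os", ["marker", "noise"], q=0.3
        )
        by_name = {r.marker: r for r in results}
        assert by_name["marker"].significant
        assert by_name["marker"].poor_prognosis == "above"
        assert by_name["marker"].p_adjusted >= by_name["marker"].p_raw

    def test_group_sizes_partition_cohort(self, rng):
        table = self._table(rng)
        results, _ = run_univariate_screen(table, "os", ["marker"], q=0.3)
        assert results[0].n_below + results[0].n_above == len(table)

    def test_degenerate_marker_skipped_with_log_entry(self, rng):
        table = self._table(rng)
        table["flat"] = 1.0
        results, skips = run_univariate_screen(
            table, "os", ["marker", "flat"], q=0.3
        )
        assert [r.marker for r in results] == ["marker"]
        assert skips[0]["marker"] == "flat"

    def test_estimator_facades(self, rng):
        table = self._table(rng)
        X = table[["marker", "noise"]]
        y = (table["os_months"], table["os_event"].astype(bool))
        screen = MedianSplitScreen(q=0.3, endpoint="os").fit(X, y)
        assert "marker" in screen.significant_
        sel = ForwardWaldCoxSelector().fit(
            (X > X.median()).astype(float), y
        )
        assert "marker" in sel.selected_
        assert sel.summary_.loc["marker", "HR"] > 1
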