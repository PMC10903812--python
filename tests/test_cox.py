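"""The survival core against closed forms, hand arithmetic and lifelines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from cmrsurv.cox import (
    BaselineHazard,
    SurvivalDataError,
    breslow_baseline,
    grid_search_cox_coefficient,
    kaplan_meier,
    log_rank_test,
    neg_log_partial_likelihood,
    neg_log_partial_likelihood_grad,
    stratify_by_median,
    survival_curve,
)


def _random_instance(rng, n, tie_times=True):
    time = (rng.integers(1, 12, n).astype(float) if tie_times
            else rng.uniform(1, 60, n))
    event = rng.integers(0, 2, n)
    if event.sum() == 0:
        event[rng.integers(0, n)] = 1
    scores = rng.normal(0, 1, n)
    return scores, time, event


class TestPartialLikelihood:
    def test_three_subject_zero_score_closed_form(self):
        loss = neg_log_partial_likelihood([0, 0, 0], [1, 2, 3], [1, 1, 1],
                                          reduction="sum")
        assert loss == pytest.approx(np.log(6), abs=1e-12)

    @given(st.integers(0, 1000), st.floats(-50, 50))
    def test_location_invariance(self, seed, shift):
        scores, time, event = _random_instance(np.random.default_rng(seed), 12)
        a = neg_log_partial_likelihood(scores, time, event)
        b = neg_log_partial_likelihood(scores + shift, time, event)
        assert a == pytest.approx(b, abs=1e-8)

    def test_breslow_tie_formula_by_hand(self):
        """4 subjects, events tied at t=2 plus censoring: each tied event
        contributes log of the full risk-set sum at t=2."""
        x = np.array([0.5, -0.2, 0.1, 0.3])
        time = np.array([2.0, 2.0, 2.0, 5.0])
        event = np.array([1, 1, 0, 1])
        s_all = np.exp(x).sum()
        expected = -((x[0] - np.log(s_all)) + (x[1] - np.log(s_all))
                     + (x[3] - np.log(np.exp(x[3]))))
        loss = neg_log_partial_likelihood(x, time, event, reduction="sum")
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_zero_events_is_an_error(self):
        with pytest.raises(SurvivalDataError, match="zero events"):
            neg_log_partial_likelihood([1.0, 2.0], [1, 2], [0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        scores, time, event = _random_instance(rng, 10)
        _, grad = neg_log_partial_likelihood_grad(scores, time, event)
        eps = 1e-6
        for i in range(len(scores)):
            up, dn = scores.copy(), scores.copy()
            up[i] += eps
            dn[i] -= eps
            num = (neg_log_partial_likelihood(up, time, event)
                   - neg_log_partial_likelihood(dn, time, event)) / (2 * eps)
            assert grad[i] == pytest.approx(num, abs=1e-6)


class TestBreslowBaseline:
    def test_two_subject_hand_arithmetic(self):
        bh = breslow_baseline([0.0, 0.0], [1.0, 2.0], [1, 1])
        np.testing.assert_allclose(bh.cumulative, [0.5, 1.5])

    @pytest.mark.parametrize("seed", range(10))
    def test_zero_scores_equal_nelson_aalen(self, seed):
        rng = np.random.default_rng(seed)
        _, time, event = _random_instance(rng, 15)
        bh = breslow_baseline(np.zeros(15), time, event)
        # Nelson-Aalen by direct counting
        for tk, inc in zip(bh.event_times, bh.increments):
            d = ((time == tk) & (event == 1)).sum()
            n_at_risk = (time >= tk).sum()
            assert inc == pytest.approx(d / n_at_risk, abs=1e-14)

    def test_random_instance_matches_one_pass_reference(self, rng):
        """Independent reference: direct evaluation of d_i / sum exp(x_j)
        by explicit risk-set loops."""
        scores, time, event = _random_instance(rng, 8)
        bh = breslow_baseline(scores, time, event)
        for tk, inc in zip(bh.event_times, bh.increments):
            d = ((time == tk) & (event == 1)).sum()
            denom = np.exp(scores[time >= tk]).sum()
            assert inc == pytest.approx(d / denom, rel=1e-12)


class TestSurvivalCurve:
    def test_closed_form_spot_value(self):
        bh = BaselineHazard(event_times=np.array([10.0]), increments=np.array([0.5]))
        c = survival_curve(bh, 0.0)
        assert c.at([10.0])[0] == pytest.approx(np.exp(-0.5))
        assert c.at([5.0])[0] == 1.0  # before the first event time

    def test_low_risk_limit_is_unity(self):
        bh = BaselineHazard(event_times=np.array([1.0, 2.0]),
                            increments=np.array([0.3, 0.4]))
        c = survival_curve(bh, -50.0)
        assert np.all(c.survival > 0.999999)

    def test_monotone_in_risk_score(self, rng):
        _, time, event = _random_instance(rng, 20)
        bh = breslow_baseline(rng.normal(0, 1, 20), time, event)
        s1 = survival_curve(bh, -0.7).survival
        s2 = survival_curve(bh, 0.9).survival
        assert np.all(s1 >= s2)

    def test_breslow_curve_tracks_kaplan_meier_at_null_scores(self):
        """exp(-H0) with zero scores stays within the usual product-limit
        vs exponential gap of the KM curve on a sizeable cohort."""
        from cmrsurv.simulate import SimParams, generate_cohort
        _, _, fu, _ = generate_cohort(SimParams(n=200, seed=13))
        t, e = fu.time_months.to_numpy(), fu.event.to_numpy()
        bh = breslow_baseline(np.zeros(200), t, e)
        km = kaplan_meier(t, e)
        gap = np.abs(np.exp(-bh.at(km.times)) - km.survival)
        assert gap.max() < 0.05


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = kaplan_meier([3.0, 5.0], [0, 0])
        assert np.all(km.survival == 1.0)

    def test_two_subject_hand_arithmetic(self):
        km = kaplan_meier([1.0, 2.0], [1, 1])
        np.testing.assert_allclose(km.survival, [0.5, 0.0])

    def test_matches_lifelines_value_by_value(self, rng):
        time = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        km = kaplan_meier(time, event)
        ref = KaplanMeierFitter().fit(time, event)
        np.testing.assert_allclose(
            km.at(km.times), ref.survival_function_at_times(km.times), atol=1e-12)
        np.testing.assert_array_equal(km.censor_times, [2.0, 4.0])


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        chi2, df, p = log_rank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_lifelines_reference(self, k, rng):
        time = rng.uniform(1, 40, 30)
        event = rng.integers(0, 2, 30)
        event[0] = 1
        groups = rng.integers(0, k, 30)
        chi2, df, p = log_rank_test(time, event, groups)
        ref = multivariate_logrank_test(time, groups, event)
        assert df == k - 1
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-10)
        assert p == pytest.approx(ref.p_value, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(SurvivalDataError):
            log_rank_test([1.0, 2.0], [1, 1], ["a", "a"])


class TestStratification:
    def test_even_split_on_distinct_scores(self):
        labels = stratify_by_median([1.0, 2.0, 3.0, 4.0])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_all_tied_scores_warn_and_go_high(self):
        with pytest.warns(UserWarning, match="degenerate"):
            labels = stratify_by_median([5.0, 5.0, 5.0])
        assert list(labels) == ["high"] * 3

    @pytest.mark.parametrize("seed", range(10))
    def test_balanced_within_one_for_distinct_scores(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.permutation(rng.uniform(0, 1, 11))
        labels = stratify_by_median(scores)
        assert abs((labels == "high").sum() - (labels == "low").sum()) <= 1


class TestAgainstStandardCoxFitter:
    def test_grid_search_recovers_standard_estimate(self):
        """One-covariate linear model: dense grid search over our partial
        likelihood agrees with lifelines' Newton fit to 1e-3 (continuous
        times, so all tie conventions coincide)."""
        rng = np.random.default_rng(21)
        n = 20
        z = rng.normal(0, 1, n)
        time = rng.exponential(20 * np.exp(-0.8 * z))
        event = (rng.uniform(size=n) > 0.25).astype(int)
        beta_grid = grid_search_cox_coefficient(z, time, event)
        ref = CoxPHFitter().fit(
            pd.DataFrame({"z": z, "t": time, "e": event}), "t", "e")
        assert beta_grid == pytest.approx(ref.params_.iloc[0], abs=1e-3)
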