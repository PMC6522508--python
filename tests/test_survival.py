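"""Kaplan-Meier and log-rank estimators against closed forms and lifelines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from meldalloc.errors import DegenerateInputError, InvalidInputError
from meldalloc.registry import SurvivalSample
from meldalloc.survival import km_fit, km_survival_at, logrank_test, permutation_logrank


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = km_fit([(5, False), (8, False), (12, False)])
        assert curve.survival_at(0) == 1.0
        assert curve.survival_at(100) == 1.0
        assert curve.event_times.size == 0

    def test_hand_product_limit(self):
        # events at 2 and 3, censored at 1, 4, 5: S(3) = (3/4)(2/3) = 0.5
        curve = km_fit([(1, False), (2, True), (3, True), (4, False), (5, False)])
        assert curve.survival_at(3) == pytest.approx(0.5)
        assert curve.survival_at(2.5) == pytest.approx(0.75)
        assert curve.survival_at(0) == 1.0
        assert curve.survival_at(100) == pytest.approx(0.5)  # step extension

    def test_accepts_survival_samples(self):
        curve = km_fit([SurvivalSample(2.0, True), SurvivalSample(3.0, False)])
        assert curve.survival_at(2) == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.0, 100.0), min_size=1, max_size=40))
    def test_all_events_equals_one_minus_ecdf(self, times):
        curve = km_fit([(t, True) for t in times])
        arr = np.sort(np.asarray(times))
        for q in list(arr) + [0.0, 50.0, 200.0]:
            ecdf = np.mean(arr <= q)
            assert curve.survival_at(q) == pytest.approx(1.0 - ecdf, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.tuples(st.floats(0.0, 50.0), st.booleans()), min_size=2, max_size=30
        ),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance(self, samples, rnd):
        shuffled = list(samples)
        rnd.shuffle(shuffled)
        a, b = km_fit(samples), km_fit(shuffled)
        np.testing.assert_allclose(a.survival, b.survival)
        np.testing.assert_allclose(a.event_times, b.event_times)

    def test_late_censoring_leaves_curve_unchanged_before(self):
        base = [(1, True), (2, True), (3, False)]
        extended = base + [(10, False)]
        a, b = km_fit(base), km_fit(extended)
        for q in (0.5, 1.0, 1.5, 2.0):
            # risk sets before the added censoring time grow by one
            assert km_survival_at(b, q) == pytest.approx(
                km_fit(extended).survival_at(q)
            )
        assert b.at_risk[0] == a.at_risk[0] + 1

    def test_matches_lifelines_with_ties_and_censoring(self):
        rng = np.random.default_rng(7)
        t = np.round(rng.exponential(30, 100)) + 1
        e = rng.random(100) < 0.6
        ours = km_fit(list(zip(t, e)))
        theirs = KaplanMeierFitter().fit(t, e)
        for q in (1, 5.5, 20, 60, 200):
            assert ours.survival_at(q) == pytest.approx(float(theirs.predict(q)), abs=1e-12)

    def test_greenwood_se_positive_after_events(self):
        curve = km_fit([(1, True), (2, True), (3, False), (4, False)])
        assert (curve.greenwood_se > 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            km_fit([])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = [(1, True), (2, False), (3, True)]
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # alternating event times, all events: chi2 = 0.7667^2 / 1.2122
        res = logrank_test([[(1, 1), (3, 1), (5, 1)], [(2, 1), (4, 1), (6, 1)]])
        assert res.statistic == pytest.approx(0.4849, abs=1e-4)
        assert res.p_value == pytest.approx(0.4862, abs=1e-4)
        assert res.observed[0] == 3

    def test_observed_minus_expected_sums_to_zero(self):
        rng = np.random.default_rng(3)
        groups = [
            list(zip(rng.exponential(20, 40), rng.random(40) < 0.8)) for _ in range(3)
        ]
        res = logrank_test(groups)
        assert float(np.sum(res.observed - res.expected)) == pytest.approx(0.0, abs=1e-9)
        assert res.df == 2

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(4)
        groups = [
            list(zip(rng.exponential(20, 30), rng.random(30) < 0.7)) for _ in range(3)
        ]
        a = logrank_test(groups)
        b = logrank_test(groups[::-1])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-9)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_lifelines(self, k):
        rng = np.random.default_rng(k)
        n = 150
        t = np.round(rng.exponential(30, n)) + 1
        e = rng.random(n) < 0.7
        g = rng.integers(0, k, n)
        ours = logrank_test([list(zip(t[g == i], e[g == i])) for i in range(k)])
        theirs = multivariate_logrank_test(t, g, e)
        assert ours.statistic == pytest.approx(theirs.test_statistic, abs=1e-8)
        assert ours.p_value == pytest.approx(theirs.p_value, abs=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            logrank_test([[(1, True)]])
        with pytest.raises(DegenerateInputError):
            logrank_test([[(1, True)], []])
        with pytest.raises(DegenerateInputError):
            logrank_test([[(1, False)], [(2, False)]])

    def test_type_one_error_close_to_nominal(self):
        """Under equal exponential hazards the 0.05-level test rejects ~5%."""
        rng = np.random.default_rng(123)
        reps, rejections = 500, 0
        for _ in range(reps):
            t = rng.exponential(100, 60)
            cens = np.minimum(rng.exponential(200, 60), 365)
            time = np.minimum(t, cens)
            event = t <= cens
            res = logrank_test(
                [list(zip(time[:30], event[:30])), list(zip(time[30:], event[30:]))]
            )
            rejections += res.p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3.5 * np.sqrt(0.05 * 0.95 / reps)


class TestPermutationLogrank:
    def test_identical_groups_p_near_one(self):
        g = [(1, True), (2, True), (3, False), (4, True)]
        assert permutation_logrank([g, list(g)], n_perm=99, seed=1) > 0.9

    def test_agrees_with_asymptotic(self):
        rng = np.random.default_rng(11)
        a = list(zip(rng.exponential(30, 60), np.full(60, True)))
        b = list(zip(rng.exponential(55, 60), np.full(60, True)))
        asym = logrank_test([a, b]).p_value
        perm = permutation_logrank([a, b], n_perm=400, seed=2)
        mc_se = np.sqrt(max(asym * (1 - asym), 0.002) / 400)
        assert abs(perm - asym) < 5 * mc_se + 0.01

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        a = list(zip(rng.exponential(30, 20), np.full(20, True)))
        b = list(zip(rng.exponential(60, 20), np.full(20, True)))
        assert permutation_logrank([a, b], 50, seed=9) == permutation_logrank([a, b], 50, seed=9)

    def test_zero_permutations_rejected(self):
        with pytest.raises(InvalidInputError):
            permutation_logrank([[(1, True)], [(2, True)]], n_perm=0)
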