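"""Censoring KM, IPCW weights and the concordance estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cindexboost as cb
from cindexboost import SurvivalSample

from conftest import (
    brute_censoring_km,
    brute_smooth,
    brute_truncated,
    brute_uno,
    brute_weights,
    random_censored_sample,
)


class TestSurvivalSample:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SurvivalSample([1.0], [1])  # single subject
        with pytest.raises(ValueError):
            SurvivalSample([0.0, 1.0], [1, 1])  # non-positive time
        with pytest.raises(ValueError):
            SurvivalSample([1.0, 2.0], [1, 2])  # bad status code
        with pytest.raises(ValueError):
            SurvivalSample([1.0, 2.0], [1, 1], [[1.0], [np.nan]])

    def test_covariate_shape_and_names(self):
        s = SurvivalSample([1, 2, 3], [1, 1, 0], np.eye(3))
        assert s.p == 3 and s.var_names == ("x1", "x2", "x3")


class TestCensoringKM:
    def test_no_censoring_is_identity(self):
        s = SurvivalSample([1.0, 2.0, 3.0], [1, 1, 1])
        G = cb.km_censoring(s)
        assert np.all(G.evaluate([0.5, 2.0, 10.0]) == 1.0)

    def test_hand_computed_fixture(self, toy_sample):
        # single censoring at t=2 with risk set {2,3,4}: G = 2/3 beyond
        G = cb.km_censoring(toy_sample)
        assert G.evaluate(1.9) == 1.0
        assert G.evaluate(2.0) == pytest.approx(2.0 / 3.0)
        assert G.evaluate_left(2.0) == 1.0
        assert G.evaluate(5.0) == pytest.approx(2.0 / 3.0)

    def test_matches_loop_oracle_and_lifelines(self):
        rng = np.random.default_rng(5)
        s = random_censored_sample(rng, 80)
        G = cb.km_censoring(s)
        G_left, G_right = brute_censoring_km(s.times, s.status)
        pts = np.quantile(s.times, [0.0, 0.2, 0.5, 0.8, 1.0])
        for t in pts:
            assert G.evaluate(t) == pytest.approx(G_right(t), abs=1e-12)
            assert G.evaluate_left(t) == pytest.approx(G_left(t), abs=1e-12)
        lifelines = pytest.importorskip("lifelines")
        km = lifelines.KaplanMeierFitter().fit(s.times, 1 - s.status)
        ref = km.survival_function_at_times(pts).to_numpy()
        np.testing.assert_allclose(G.evaluate(pts), ref, atol=1e-12)

    def test_query_before_first_jump_is_one(self, toy_sample):
        G = cb.km_censoring(toy_sample)
        assert G.evaluate(1e-9) == 1.0

    def test_evaluation_convention_flag(self):
        # an event tied with a censoring jump: the left-limit convention
        # keeps weight 1, the right-continuous variant deflates it
        s = SurvivalSample([1.0, 2.0, 2.0, 3.0], [1, 0, 1, 1])
        w_left = cb.ipcw_weights(s, cb.km_censoring(s, left_limit=True))
        w_right = cb.ipcw_weights(s, cb.km_censoring(s, left_limit=False))
        assert w_left[2] == pytest.approx(1.0)
        assert w_right[2] == pytest.approx(1.0 / (2.0 / 3.0) ** 2)


class TestIPCW:
    def test_no_censoring_unit_weights(self):
        s = SurvivalSample([1.0, 2.0, 3.0], [1, 1, 1])
        w = cb.ipcw_weights(s, cb.km_censoring(s))
        np.testing.assert_array_equal(w, [1.0, 1.0, 1.0])

    def test_fixture_weight_and_censored_zero(self, toy_sample):
        w = cb.ipcw_weights(toy_sample, cb.km_censoring(toy_sample))
        assert w[1] == 0.0            # censored subject
        assert w[2] == pytest.approx(2.25)  # 1 / (2/3)^2
        np.testing.assert_allclose(
            w, brute_weights(toy_sample.times, toy_sample.status))

    def test_zero_G_gives_zero_weight_with_warning(self, caplog):
        # an event beyond the point where the censoring KM has dropped
        # to zero must be zero-weighted, not infinite
        s = SurvivalSample([1.0, 2.0], [1, 1])
        G = cb.CensoringKM([1.5], [0.0])
        with caplog.at_level("WARNING"):
            w = cb.ipcw_weights(s, G)
        np.testing.assert_array_equal(w, [1.0, 0.0])
        assert "zero censoring-survival" in caplog.text


class TestEstimators:
    def test_perfect_discrimination(self):
        s = SurvivalSample(np.arange(1.0, 5.0), np.ones(4, int))
        assert cb.concordance_uno(s, [4.0, 3.0, 2.0, 1.0]) == 1.0

    def test_uncensored_partial_concordance(self):
        # 5 of 6 pairs concordant
        s = SurvivalSample(np.arange(1.0, 5.0), np.ones(4, int))
        assert cb.concordance_uno(s, [4.0, 3.0, 1.0, 2.0]) == pytest.approx(5 / 6)

    def test_censored_fixture_value(self, toy_sample, toy_eta):
        # weights (1, 0, 2.25, 2.25) under the left-limit convention
        assert cb.concordance_uno(toy_sample, toy_eta) == pytest.approx(3 / 5.25)

    def test_truncated_fixture_and_coincidence(self, toy_sample, toy_eta):
        assert cb.concordance_truncated(toy_sample, toy_eta, tau=2.5) == 1.0
        s = SurvivalSample(np.arange(1.0, 5.0), np.ones(4, int))
        eta = [4.0, 3.0, 1.0, 2.0]
        assert cb.concordance_truncated(s, eta, tau=10.0) == \
            cb.concordance_uno(s, eta)

    def test_truncated_empty_pair_set_errors(self, toy_sample, toy_eta):
        with pytest.raises(ValueError, match="tau"):
            cb.concordance_truncated(toy_sample, toy_eta, tau=0.5)

    def test_no_usable_pair_errors(self):
        s = SurvivalSample([2.0, 2.0], [1, 1])  # tied times: no pair
        with pytest.raises(ValueError, match="usable pair"):
            cb.concordance_uno(s, [1.0, 0.0])

    def test_tied_scores_half_smooth_zero_hard(self):
        s = SurvivalSample([1.0, 2.0], [1, 1])
        assert cb.concordance_uno(s, [1.0, 1.0]) == 0.0
        assert cb.concordance_smooth(s, [1.0, 1.0], 0.3) == 0.5

    @pytest.mark.parametrize("seed", range(6))
    def test_all_estimators_match_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        s = random_censored_sample(rng, n)
        eta = rng.standard_normal(n)
        assert cb.concordance_uno(s, eta) == pytest.approx(
            brute_uno(s.times, s.status, eta), abs=1e-12)
        assert cb.concordance_smooth(s, eta, 0.17) == pytest.approx(
            brute_smooth(s.times, s.status, eta, 0.17), abs=1e-12)
        tau = float(np.median(s.times))
        try:
            expected = brute_truncated(s.times, s.status, eta, tau)
        except ZeroDivisionError:
            return
        assert cb.concordance_truncated(s, eta, tau) == pytest.approx(
            expected, abs=1e-12)

    def test_agrees_with_scikit_survival(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(11)
        s = random_censored_sample(rng, 200)
        eta = rng.standard_normal(200)
        y = np.empty(200, dtype=[("event", bool), ("time", float)])
        y["event"], y["time"] = s.status.astype(bool), s.times
        ref = sksurv_metrics.concordance_index_ipcw(y, y, eta)[0]
        assert cb.concordance_uno(s, eta) == pytest.approx(ref, abs=1e-10)

    def test_smooth_converges_to_uno(self, toy_sample, toy_eta):
        u = cb.concordance_uno(toy_sample, toy_eta)
        assert cb.concordance_smooth(toy_sample, toy_eta, 1e-4) == \
            pytest.approx(u, abs=1e-3)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(shift=st.floats(-50, 50), seed=st.integers(0, 10 ** 6))
    def test_shift_invariance_and_symmetry(self, shift, seed):
        rng = np.random.default_rng(seed)
        s = random_censored_sample(rng, 12)
        eta = rng.standard_normal(12)
        u = cb.concordance_uno(s, eta)
        assert cb.concordance_uno(s, eta + shift) == pytest.approx(u, abs=1e-12)
        assert cb.concordance_uno(s, np.exp(eta)) == pytest.approx(u, abs=1e-12)
        assert cb.concordance_uno(s, -eta) == pytest.approx(1 - u, abs=1e-12)
        sm = cb.concordance_smooth(s, eta, 0.2)
        assert cb.concordance_smooth(s, -eta, 0.2) == pytest.approx(
            1 - sm, abs=1e-12)


class TestGradient:
    def test_two_subject_hand_value(self):
        # single pair, K'(0) = 1/(4 sigma) = 2.5, D = 1
        s = SurvivalSample([1.0, 2.0], [1, 1])
        g = cb.smooth_gradient(s, [0.0, 0.0], sigma=0.1)
        np.testing.assert_allclose(g, [2.5, -2.5])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 30))
        s = random_censored_sample(rng, n)
        eta = rng.standard_normal(n)
        sigma = float(rng.uniform(0.05, 0.5))
        g = cb.smooth_gradient(s, eta, sigma)
        assert abs(g.sum()) < 1e-10
        h = 1e-6
        for k in rng.choice(n, size=min(5, n), replace=False):
            ep, em = eta.copy(), eta.copy()
            ep[k] += h
            em[k] -= h
            fd = (cb.concordance_smooth(s, ep, sigma)
                  - cb.concordance_smooth(s, em, sigma)) / (2 * h)
            assert g[k] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def test_query_validation():
    with pytest.raises(ValueError):
        cb.ConcordanceQuery(eta=[1.0, 2.0], tau=-1.0)
    with pytest.raises(ValueError):
        cb.ConcordanceQuery(eta=[1.0, 2.0], sigma=0.0)
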