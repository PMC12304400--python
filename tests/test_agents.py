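"""Hand-computed oracles and invariants for the learning and choice rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from banditx.agents import (
    HORIZON_VALUE_SCALE,
    HorizonParams,
    KalmanBelief,
    LearnerConfig,
    RestlessParams,
    TwoArmedParams,
    diffusion_prior_step,
    horizon_features,
    kalman_update,
    logistic_choice_prob,
    restless_learner_config,
    twoarmed_predictors,
    ucb_choice_probs,
)

CFG = LearnerConfig(innov_var=7.84, noise_var=16.0, decay_rate=0.9836)


class TestKalmanUpdate:
    def test_hand_example(self):
        # V=16, innov=7.84, noise=16: K = 23.84/39.84, E = 50 + K*10
        belief = KalmanBelief(np.array([50.0, 50.0]), np.array([16.0, 16.0]))
        out = kalman_update(belief, 0, 60.0, CFG)
        gain = 23.84 / 39.84
        assert out.means[0] == pytest.approx(50 + gain * 10, abs=1e-9)
        assert out.variances[0] == pytest.approx((1 - gain) * 23.84, abs=1e-9)

    def test_noiseless_limit_gain_is_one(self):
        cfg = LearnerConfig(innov_var=7.84, noise_var=0.0)
        belief = KalmanBelief(np.array([50.0, 50.0]), np.array([16.0, 16.0]))
        out = kalman_update(belief, 0, 61.5, cfg)
        assert out.means[0] == pytest.approx(61.5, abs=1e-12)
        assert out.variances[0] == pytest.approx(0.0, abs=1e-12)

    def test_unchosen_arm_diffuses_only(self):
        belief = KalmanBelief(np.array([50.0, 42.0]), np.array([16.0, 9.0]))
        out = kalman_update(belief, 0, 60.0, CFG)
        assert out.means[1] == 42.0
        assert out.variances[1] == pytest.approx(9.0 + 7.84, abs=1e-12)

    def test_invalid_arm_raises(self):
        belief = KalmanBelief(np.array([50.0, 50.0]), np.array([16.0, 16.0]))
        with pytest.raises(IndexError):
            kalman_update(belief, 2, 60.0, CFG)

    def test_negative_variance_config_raises(self):
        belief = KalmanBelief(np.array([50.0]), np.array([16.0]))
        with pytest.raises(ValueError):
            kalman_update(belief, 0, 60.0, LearnerConfig(innov_var=-1.0, noise_var=16.0))

    @settings(max_examples=50, derandomize=True)
    @given(
        prior=st.floats(0.0, 100.0),
        reward=st.floats(0.0, 100.0),
        var=st.floats(0.1, 500.0),
    )
    def test_posterior_mean_between_prior_and_reward(self, prior, reward, var):
        belief = KalmanBelief(np.array([prior, 50.0]), np.array([var, var]))
        out = kalman_update(belief, 0, reward, CFG)
        lo, hi = min(prior, reward), max(prior, reward)
        assert lo - 1e-9 <= out.means[0] <= hi + 1e-9
        assert np.all(out.variances >= 0)

    def test_variance_nonincreasing_without_innovation(self):
        cfg = LearnerConfig(innov_var=0.0, noise_var=16.0)
        belief = KalmanBelief(np.array([50.0]), np.array([100.0]))
        for _ in range(10):
            new = kalman_update(belief, 0, 55.0, cfg)
            assert new.variances[0] <= belief.variances[0] + 1e-12
            belief = new


class TestDiffusionStep:
    def test_center_is_fixed_point(self):
        belief = KalmanBelief(np.array([50.0, 50.0]), np.array([5.0, 9.0]))
        cfg = restless_learner_config()
        out = diffusion_prior_step(belief, cfg)
        assert np.allclose(out.means, 50.0)

    def test_hand_example(self):
        # 0.9836 * 70 + 0.0164 * 50 = 69.672
        belief = KalmanBelief(np.array([70.0]), np.array([5.0]))
        cfg = restless_learner_config()
        out = diffusion_prior_step(belief, cfg)
        assert out.means[0] == pytest.approx(69.672, abs=1e-9)

    def test_repeated_application_contracts_to_center(self):
        belief = KalmanBelief(np.array([90.0]), np.array([5.0]))
        cfg = restless_learner_config()
        prev_gap = 40.0
        for _ in range(50):
            belief = diffusion_prior_step(belief, cfg)
            gap = abs(belief.means[0] - 50.0)
            assert gap < prev_gap
            prev_gap = gap

    def test_variance_decays_to_walk_stationary_value(self):
        # lam^2 V + innov (applied at the next update) converges to the
        # stationary variance of the mean-reverting walk
        cfg = restless_learner_config()
        belief = KalmanBelief(np.array([50.0]), np.array([1000.0]))
        for _ in range(2000):
            belief = KalmanBelief(belief.means, belief.variances + cfg.innov_var)
            belief = diffusion_prior_step(belief, cfg)
        stationary = 7.84 / (1 - 0.9836**2)
        assert belief.variances[0] + cfg.innov_var == pytest.approx(stationary, rel=1e-3)

    def test_requires_diffusion_flag(self):
        belief = KalmanBelief(np.array([50.0]), np.array([5.0]))
        cfg = LearnerConfig(innov_var=4.0, noise_var=16.0, apply_diffusion_to_means=False)
        with pytest.raises(ValueError):
            diffusion_prior_step(belief, cfg)


class TestHorizonFeatures:
    def test_hand_example(self):
        f = horizon_features([1, 2, 2, 2], [40.0, 50.0, 60.0, 70.0])
        assert f.value_diff == pytest.approx(40.0 - 60.0, abs=1e-12)
        assert f.info_diff == pytest.approx(-0.5, abs=1e-12)

    def test_equal_information(self):
        f = horizon_features([1, 1, 2, 2], [40.0, 44.0, 60.0, 70.0])
        assert f.info_diff == 0.0
        assert f.value_diff == pytest.approx(42.0 - 65.0, abs=1e-12)

    def test_order_invariance(self):
        a = horizon_features([1, 2, 2, 2], [40.0, 50.0, 60.0, 70.0])
        b = horizon_features([2, 2, 1, 2], [60.0, 50.0, 40.0, 70.0])
        assert a.value_diff == pytest.approx(b.value_diff)
        assert a.info_diff == pytest.approx(b.info_diff)

    def test_unsampled_arm_raises(self):
        with pytest.raises(ValueError):
            horizon_features([1, 1, 1, 1], [40.0, 50.0, 60.0, 70.0])

    def test_scaled_predictors(self):
        f = horizon_features([1, 2, 2, 2], [40.0, 50.0, 60.0, 70.0])
        v, i = f.predictors()
        assert v == pytest.approx(-20.0 / HORIZON_VALUE_SCALE)
        assert i == -0.5


class TestUcbChoice:
    def test_flat_utilities_uniform(self):
        belief = KalmanBelief(np.full(4, 50.0), np.full(4, 20.0))
        p = ucb_choice_probs(belief, RestlessParams(0.0, 0.0), CFG)
        assert np.allclose(p, 0.25, atol=1e-12)

    def test_two_arm_hand_example(self):
        # tau=0.15, dE=10 -> p = 1/(1+exp(-1.5))
        belief = KalmanBelief(np.array([60.0, 50.0]), np.array([20.0, 20.0]))
        p = ucb_choice_probs(belief, RestlessParams(0.15, 0.0), CFG)
        assert p[0] == pytest.approx(1 / (1 + np.exp(-1.5)), abs=1e-9)

    def test_shift_invariance(self):
        belief = KalmanBelief(np.array([60.0, 50.0, 40.0, 55.0]), np.full(4, 12.0))
        p1 = ucb_choice_probs(belief, RestlessParams(0.15, -0.41), CFG)
        shifted = KalmanBelief(belief.means + 100.0, belief.variances)
        p2 = ucb_choice_probs(shifted, RestlessParams(0.15, -0.41), CFG)
        assert np.allclose(p1, p2, atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        tau=st.floats(0.0, 5.0),
        beta=st.floats(-20.0, 20.0),
        means=st.lists(st.floats(0.0, 100.0), min_size=4, max_size=4),
    )
    def test_probabilities_sum_to_one(self, tau, beta, means):
        belief = KalmanBelief(np.array(means), np.full(4, 25.0))
        p = ucb_choice_probs(belief, RestlessParams(tau, beta), CFG)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)


class TestTwoArmedPredictors:
    def test_symmetric_beliefs_give_zero(self):
        belief = KalmanBelief(np.array([50.0, 50.0]), np.array([16.0, 16.0]))
        assert twoarmed_predictors(belief, "original") == (0.0, 0.0, 0.0)

    def test_hand_example(self):
        belief = KalmanBelief(np.array([55.0, 45.0]), np.array([16.0, 25.0]))
        v, d, r = twoarmed_predictors(belief, "original")
        assert v == pytest.approx(10.0)
        assert d == pytest.approx(-1.0)
        assert r == pytest.approx(10.0 / np.sqrt(41.0), abs=1e-9)

    def test_swap_antisymmetry(self):
        belief = KalmanBelief(np.array([55.0, 45.0]), np.array([16.0, 25.0]))
        swapped = KalmanBelief(belief.means[::-1].copy(), belief.variances[::-1].copy())
        a = twoarmed_predictors(belief, "original")
        b = twoarmed_predictors(swapped, "original")
        assert np.allclose(np.asarray(a), -np.asarray(b))

    def test_improved_drops_random_predictor(self):
        belief = KalmanBelief(np.array([55.0, 45.0]), np.array([16.0, 25.0]))
        assert len(twoarmed_predictors(belief, "improved")) == 2

    def test_zero_total_variance_signals(self):
        belief = KalmanBelief(np.array([55.0, 45.0]), np.array([0.0, 0.0]))
        with pytest.raises(ZeroDivisionError):
            twoarmed_predictors(belief, "original")


class TestLogisticChoice:
    def test_null_model(self):
        assert logistic_choice_prob((0.0, 0.0), (0.0, 0.0, 0.0)) == 0.5

    def test_hand_example(self):
        p = logistic_choice_prob((8.0, 0.0), (0.0, 0.1, 0.0))
        assert p == pytest.approx(1 / (1 + np.exp(-0.8)), abs=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.floats(-30.0, 30.0), min_size=2, max_size=2),
        w=st.lists(st.floats(-5.0, 5.0), min_size=2, max_size=2),
    )
    def test_symmetry_without_intercept(self, x, w):
        p_pos = logistic_choice_prob(x, (0.0, *w))
        p_neg = logistic_choice_prob([-v for v in x], (0.0, *w))
        assert p_pos + p_neg == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            logistic_choice_prob((1.0, 2.0, 3.0), (0.0, 0.1))

    def test_params_objects_accepted(self):
        p = logistic_choice_prob(
            (10.0, -1.0), TwoArmedParams(beta0=0.0, w_value=0.1, w_directed=0.2)
        )
        assert p == pytest.approx(1 / (1 + np.exp(-(1.0 - 0.2))), abs=1e-9)
        q = logistic_choice_prob(
            (0.5, -0.5), HorizonParams(beta0_long=0.1, w_value_long=1.0, w_info_long=0.4)
        )
        assert q == pytest.approx(1 / (1 + np.exp(-(0.1 + 0.5 - 0.2))), abs=1e-9)


def test_horizon_params_difference_scores():
    p = HorizonParams(
        beta0_long=0.0, w_value_long=4.0, w_info_long=0.5,
        beta0_short=0.1, w_value_short=3.0, w_info_short=-0.2,
    )
    assert p.variant == "original"
    assert p.delta_w_value == pytest.approx(1.0)
    assert p.delta_w_info == pytest.approx(0.7)
    improved = HorizonParams(beta0_long=0.0, w_value_long=4.0, w_info_long=0.5)
    with pytest.raises(ValueError):
        _ = improved.delta_w_value
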