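import math

import numpy as np
import pytest

import socialhgf as sh
from socialhgf.response import (
    MODEL_SPACE,
    ModelSpec,
    decision_trajectory,
    follow_probabilities,
    run_perceptual,
    wsls_follow_prob,
)
from socialhgf.task import responses_from_follow
from .oracles import response_prob_oracle


class TestModelSpec:
    def test_space_has_eight_models(self):
        assert len(MODEL_SPACE) == 8
        assert len({m.label for m in MODEL_SPACE}) == 8

    @pytest.mark.parametrize(
        "perceptual,response",
        [("rw", 1), ("k1", 2), ("none", 4), ("hgf", "wsls"), ("rw", "random")],
    )
    def test_invalid_combinations_rejected(self, perceptual, response):
        with pytest.raises(ValueError):
            ModelSpec(perceptual, response)


class TestGazeFrame:
    def test_prediction_follows_gaze_target(self):
        assert sh.gaze_frame_card_prediction(0.7, "blue") == 0.7
        assert math.isclose(sh.gaze_frame_card_prediction(0.7, "green"), 0.3)
        assert sh.gaze_frame_card_prediction(0.5, "green") == 0.5


class TestCombinedBelief:
    def test_symmetric_case(self):
        b, wg, wc = sh.combined_belief(0.5, 0.5, 1.0)
        assert b == 0.5 and wg == 0.5 and wc == 0.5

    def test_hand_computed_case(self):
        # pi_gaze = 6.25, pi_card = 4.1667 -> w_gaze = 0.6, b = 0.72
        b, wg, wc = sh.combined_belief(0.8, 0.6, 1.0)
        assert math.isclose(wg, 0.6, abs_tol=1e-12)
        assert math.isclose(b, 0.72, abs_tol=1e-12)

    def test_zeta_limits(self):
        b_hi, _, _ = sh.combined_belief(0.8, 0.6, 1e12)
        b_lo, _, _ = sh.combined_belief(0.8, 0.6, 1e-12)
        assert math.isclose(b_hi, 0.8, abs_tol=1e-9)
        assert math.isclose(b_lo, 0.6, abs_tol=1e-9)

    def test_weights_sum_to_one_and_belief_in_bounds(self):
        rng = np.random.default_rng(2)
        mg = rng.uniform(0.001, 0.999, 500)
        mc = rng.uniform(0.001, 0.999, 500)
        for zeta in (0.01, 1.0, 50.0):
            b, wg, wc = sh.combined_belief(mg, mc, zeta)
            np.testing.assert_allclose(wg + wc, 1.0, rtol=1e-12)
            assert np.all((b > 0) & (b < 1))

    def test_boundary_predictions_guarded(self):
        b, _, _ = sh.combined_belief(1.0, 0.0, 1.0)
        assert np.isfinite(b)

    def test_nonpositive_zeta_rejected(self):
        with pytest.raises(ValueError):
            sh.combined_belief(0.5, 0.5, 0.0)


class TestDecisionTemperature:
    def test_variant1_at_zero_volatility(self):
        assert sh.decision_temperature(1, 0.0, 0.0, 2.0) == 2.0

    def test_variant1_attenuation(self):
        got = sh.decision_temperature(1, 1.0, 1.0, 1.0)
        assert math.isclose(got, math.exp(-2), rel_tol=1e-12)

    def test_single_stream_variants(self):
        assert math.isclose(sh.decision_temperature(2, 5.0, 1.0, 1.0), math.exp(-1))
        assert math.isclose(sh.decision_temperature(3, 1.0, 5.0, 1.0), math.exp(-1))

    def test_variant4_constant(self):
        out = sh.decision_temperature(4, np.zeros(120), np.zeros(120), 3.0)
        assert np.all(out == 3.0)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            sh.decision_temperature(5, 0.0, 0.0, 1.0)


class TestProbFollowGaze:
    def test_indifference_point(self):
        for gamma in (0.1, 1.0, 100.0):
            for eta in (0.0, 0.5, 1.0):
                assert sh.prob_follow_gaze(0.5, 4, 4, gamma, eta) == 0.5

    def test_hand_computed_linear_case(self):
        # gamma (r_g b - r_ng (1-b)) = 5*0.72 - 3*0.28 = 2.76
        got = sh.prob_follow_gaze(0.72, 5, 3, 1.0, 1.0)
        assert math.isclose(got, 1 / (1 + math.exp(-2.76)), rel_tol=1e-12)

    def test_zero_temperature_limit(self):
        assert math.isclose(sh.prob_follow_gaze(0.9, 9, 1, 1e-12, 0.3), 0.5, abs_tol=1e-9)

    def test_monotone_in_belief(self):
        b = np.linspace(0.01, 0.99, 50)
        p = sh.prob_follow_gaze(b, 5, 3, 2.0, 0.5)
        assert np.all(np.diff(p) > 0)

    def test_reward_below_one_rejected(self):
        with pytest.raises(ValueError):
            sh.prob_follow_gaze(0.5, 0.5, 3, 1.0, 1.0)


class TestLikelihood:
    def test_random_model_constant_bias(self, experiment):
        spec = ModelSpec("none", "random")
        responses = responses_from_follow(
            experiment, np.random.default_rng(3).integers(0, 2, 120)
        )
        _, loglik, _, _ = sh.likelihood_series(
            spec, experiment, responses, {"bias": 0.5}
        )
        assert math.isclose(loglik, 120 * math.log(0.5), rel_tol=1e-12)

    def test_wsls_deterministic_policy_is_certain_after_trial_one(self, experiment):
        spec = ModelSpec("none", "wsls")
        responses, _ = sh.simulate_agent(experiment, {"epsilon": 0.0}, spec, seed=4)
        p, loglik, _, _ = sh.likelihood_series(
            spec, experiment, responses, {"epsilon": 0.0}
        )
        assert p[0] == 0.5
        np.testing.assert_allclose(p[1:], 1.0, atol=1e-7)
        assert loglik > math.log(0.5) - 1e-4

    def test_total_equals_sum_of_bernoulli_terms(self, experiment, hgf_agent, hgf_native_params):
        spec, responses, _ = hgf_agent
        p, loglik, _, _ = sh.likelihood_series(
            spec, experiment, responses, hgf_native_params
        )
        prob_follow, _ = follow_probabilities(
            spec, experiment, hgf_native_params, responses
        )
        manual = sum(
            math.log(q if y == 1 else 1 - q)
            for q, y in zip(prob_follow, responses.y)
        )
        assert math.isclose(loglik, manual, rel_tol=1e-9)

    def test_missing_trials_excluded(self, experiment, hgf_agent, hgf_native_params):
        spec, responses, _ = hgf_agent
        missing = np.zeros(120, dtype=bool)
        missing[:10] = True
        partial = responses_from_follow(experiment, responses.y, missing=missing)
        p_full, ll_full, _, _ = sh.likelihood_series(
            spec, experiment, responses, hgf_native_params
        )
        _, ll_part, _, _ = sh.likelihood_series(
            spec, experiment, partial, hgf_native_params
        )
        assert math.isclose(ll_full - ll_part, np.sum(np.log(p_full[:10])), rel_tol=1e-9)

    def test_wsls_maps_card_policy_into_gaze_frame(self, experiment):
        responses = responses_from_follow(experiment, np.ones(120, dtype=int))
        p = wsls_follow_prob(experiment, responses, epsilon=0.1)
        # after a win the intended card is the previous (gazed-at) one
        for t in range(1, 20):
            prev_win = responses.rewarded[t - 1] == 1
            prev_card = responses.chosen_card[t - 1]
            intended = prev_card if prev_win else (
                "green" if prev_card == "blue" else "blue"
            )
            expected = 0.9 if intended == experiment.gaze_target[t] else 0.1
            assert p[t] == expected


class TestSimulation:
    def test_pure_function_of_seed(self, experiment, hgf_native_params):
        spec = ModelSpec("hgf", 1)
        a, _ = sh.simulate_agent(experiment, hgf_native_params, spec, seed=11)
        b, _ = sh.simulate_agent(experiment, hgf_native_params, spec, seed=11)
        np.testing.assert_array_equal(a.y, b.y)
        c, _ = sh.simulate_agent(experiment, hgf_native_params, spec, seed=12)
        assert not np.array_equal(a.y, c.y)

    def test_deterministic_limit_is_reward_belief_argmax(self, experiment):
        params = {"alpha_card": 0.3, "alpha_gaze": 0.3, "zeta": 1.0,
                  "beta": 1e6, "eta": 1.0}
        spec = ModelSpec("rw", 4)
        responses, info = sh.simulate_agent(experiment, params, spec, seed=13)
        d = info["decision"]
        arg = experiment.r_gaze * d.b - experiment.r_notgaze * (1 - d.b)
        np.testing.assert_array_equal(responses.y, (arg > 0).astype(int))

    def test_follow_frequency_matches_probability(self, experiment):
        # binomial oracle: across reseeded simulations the follow rate matches p
        spec = ModelSpec("none", "random")
        n_sim = 200
        total = sum(
            sh.simulate_agent(experiment, {"bias": 0.7}, spec, seed=s)[0].y.sum()
            for s in range(n_sim)
        )
        n = n_sim * 120
        se = math.sqrt(0.7 * 0.3 / n)
        assert abs(total / n - 0.7) < 3 * se

    def test_wsls_agent_follows_its_own_policy(self, experiment):
        spec = ModelSpec("none", "wsls")
        responses, _ = sh.simulate_agent(experiment, {"epsilon": 0.0}, spec, seed=14)
        for t in range(1, 120):
            prev = responses.chosen_card[t - 1]
            intended = prev if responses.rewarded[t - 1] else (
                "green" if prev == "blue" else "blue"
            )
            assert responses.chosen_card[t] == intended


@pytest.mark.parametrize("variant", [1, 2, 3, 4])
def test_full_response_path_matches_oracle(experiment, hgf_native_params, variant):
    """The composed belief->temperature->softmax path equals the per-trial oracle."""
    spec = ModelSpec("hgf", variant)
    state = run_perceptual(spec, experiment, hgf_native_params)
    d = decision_trajectory(spec, state, experiment, hgf_native_params)
    mc_gf = np.where(
        experiment.gaze_is_blue, state.muhat1_card, 1 - state.muhat1_card
    )
    for t in range(0, 120, 7):
        want = response_prob_oracle(
            state.muhat1_gaze[t], mc_gf[t],
            hgf_native_params["zeta"], hgf_native_params["beta"],
            hgf_native_params["eta"],
            state.muhat3_card[t], state.muhat3_gaze[t],
            experiment.r_gaze[t], experiment.r_notgaze[t], variant,
        )
        assert math.isclose(d.prob_gaze[t], want, abs_tol=1e-8)
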