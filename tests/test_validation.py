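import numpy as np
import pandas as pd
import pytest

import socialhgf as sh
from socialhgf.response import ModelSpec
from socialhgf.task import (
    CohortSpec,
    GroupSpec,

    ScheduleConfig,
    responses_from_follow,
)
from socialhgf.validation import (
    behavioral_summaries,
    choice_sequence_glm,
    parameter_recovery,
    posterior_predictive,
    precision_weight_summary,
    slope_phase_contrast,
)


def follow_best_gaze_policy(experiment, schedule):
    """y = follow exactly when the gaze is currently reliable."""
    return responses_from_follow(
        experiment, (schedule.p_gaze >= 0.5).astype(int)
    )


class TestBehavioralSummaries:
    def test_always_follow_agent(self, experiment, schedule):
        responses = responses_from_follow(experiment, np.ones(120, dtype=int))
        cells = behavioral_summaries(responses, experiment, schedule)
        for phase in ("stable", "volatile"):
            assert cells[f"advice_high_{phase}"] == 1.0
            assert cells[f"advice_low_{phase}"] == 1.0

    def test_omniscient_card_chooser(self, experiment, schedule):
        # always chooses the card with the higher ground-truth probability
        better = np.where(schedule.p_card >= 0.5, "blue", "green")
        y = (experiment.gaze_target == better).astype(int)
        responses = responses_from_follow(experiment, y)
        assert np.all(responses.chosen_card == better)
        cells = behavioral_summaries(responses, experiment, schedule)
        assert cells["hp_card_stable"] == 1.0
        assert cells["hp_card_volatile"] == 1.0

    def test_gaze_policy_agent(self, experiment, schedule):
        cells = behavioral_summaries(
            follow_best_gaze_policy(experiment, schedule), experiment, schedule
        )
        assert cells["hp_gaze_stable"] == 1.0
        assert cells["hp_gaze_volatile"] == 1.0

    def test_coin_flip_agent_near_half_everywhere(self):
        # high and low gaze accuracy each occur in both phases
        cfg = ScheduleConfig(
            n_trials=10_000,
            card_blocks=[(1, 10_000, 0.73)],
            gaze_blocks=[(1, 2_500, 0.73), (2_501, 5_000, 0.27),
                         (5_001, 7_500, 0.73), (7_501, 10_000, 0.27)],
            card_phases=[(1, 5_000, "stable"), (5_001, 10_000, "volatile")],
            gaze_phases=[(1, 5_000, "stable"), (5_001, 10_000, "volatile")],
        )
        schedule = sh.build_schedule(cfg)
        experiment = sh.generate_experiment(schedule, 17)
        y = np.random.default_rng(18).integers(0, 2, 10_000)
        cells = behavioral_summaries(
            responses_from_follow(experiment, y), experiment, schedule
        )
        se = np.sqrt(0.25 / 2_500)
        for name, value in cells.items():
            assert abs(value - 0.5) < 3 * se, name

    def test_all_missing_cell_is_absent(self, experiment, schedule):
        missing = np.ones(120, dtype=bool)
        missing[60:] = False   # only volatile card trials observed
        responses = responses_from_follow(
            experiment, np.ones(120, dtype=int), missing=missing
        )
        cells = behavioral_summaries(responses, experiment, schedule)
        assert np.isnan(cells["hp_card_stable"])
        assert not np.isnan(cells["hp_card_volatile"])


class TestPrecisionWeightSummary:
    def test_constant_trajectory_has_equal_phase_means(self, schedule):
        from socialhgf.perceptual import HGFTrajectory

        n = schedule.n_trials
        const = HGFTrajectory(
            *(np.ones(n) for _ in range(12)),
            psi2=np.ones(n), qpsi2=np.full(n, 0.2), psi3=np.full(n, 0.7),
        )
        cells = precision_weight_summary({"card": const, "gaze": const}, schedule)
        assert cells["qpsi2_card_stable"] == pytest.approx(0.2)
        assert cells["qpsi2_card_volatile"] == pytest.approx(0.2)
        assert cells["psi3_gaze_stable"] == pytest.approx(0.7)
        assert cells["psi3_gaze_volatile"] == pytest.approx(0.7)

    def test_psi3_positive_for_simulated_agent(self, hgf_agent, schedule):
        _, _, info = hgf_agent
        cells = precision_weight_summary(
            info["perceptual"].trajectories, schedule
        )
        assert all(v > 0 for v in cells.to_numpy())


class TestPosteriorPredictive:
    def _mini_cohort(self, n):
        spec = ModelSpec("hgf", 1)
        params = {
            "omega2_card": (-3, 0.2), "omega2_gaze": (-3, 0.2),
            "omega3_card": (-6, 0.2), "omega3_gaze": (-6, 0.2),
            "zeta": (0, 0.2), "beta": (2, 0.2), "eta": (0, 0.2),
        }
        return sh.generate_cohort(
            CohortSpec(groups=[GroupSpec("g", n, params, spec)]), seed=23
        )

    def test_simulation_count_is_subjects_times_replicates(self):
        subjects = self._mini_cohort(5)
        ppc = posterior_predictive(
            subjects,
            [s.experiment for s in subjects],
            [s.schedule for s in subjects],
            n_rep=1, seed=3,
        )
        assert ppc.n_simulations == 5
        assert len(ppc.per_subject) == 5

    def test_simulated_proportions_in_unit_interval(self):
        subjects = self._mini_cohort(3)
        ppc = posterior_predictive(
            subjects,
            [s.experiment for s in subjects],
            [s.schedule for s in subjects],
            n_rep=4, seed=4,
        )
        assert ppc.n_simulations == 12
        values = ppc.simulations.drop(columns=["subject", "rep"]).to_numpy()
        assert np.nanmin(values) >= 0 and np.nanmax(values) <= 1

    def test_reproducible_in_seed(self):
        subjects = self._mini_cohort(2)
        args = ([s.experiment for s in subjects], [s.schedule for s in subjects])
        a = posterior_predictive(subjects, *args, n_rep=2, seed=9)
        b = posterior_predictive(subjects, *args, n_rep=2, seed=9)
        pd.testing.assert_frame_equal(a.simulations, b.simulations)


class TestParameterRecoveryMechanics:
    def test_degenerate_generating_values_flagged(self):
        spec = ModelSpec("none", "random")
        params = {"bias": (0.0, 0.0)}
        subjects = sh.generate_cohort(
            CohortSpec(groups=[GroupSpec("g", 3, params, spec)]), seed=31
        )
        rec = parameter_recovery(subjects, n_rep=1, seed=32)
        assert rec.correlations["bias"] is None
        assert "zero variance" in rec.reasons["bias"]

    def test_bias_recovery_tracks_truth(self):
        spec = ModelSpec("none", "random")
        params = {"bias": (0.0, 1.5)}
        subjects = sh.generate_cohort(
            CohortSpec(groups=[GroupSpec("g", 12, params, spec)]), seed=33
        )
        rec = parameter_recovery(subjects, n_rep=2, seed=34)
        assert rec.correlations["bias"] > 0.9

    def test_invalid_replicate_count(self):
        with pytest.raises(ValueError):
            parameter_recovery([], n_rep=0, seed=1)


class TestChoiceSequenceGLM:
    def _imitator(self, experiment, flip_seed=41, eps=0.01):
        """Follows the gaze iff the gaze was correct on the previous trial."""
        rng = np.random.default_rng(flip_seed)
        y = np.empty(120, dtype=int)
        y[0] = 1
        y[1:] = experiment.u_gaze[:-1]
        flips = rng.random(120) < eps
        y = np.where(flips, 1 - y, y)
        return responses_from_follow(experiment, y)

    def test_lag_one_dominates_for_outcome_imitator(self, experiment, schedule):
        responses = self._imitator(experiment)
        res = choice_sequence_glm(responses, experiment, schedule, "gaze", "all")
        assert np.argmax(np.abs(res.lag_coefs)) == 0
        assert res.lag_coefs[0] > 0
        assert np.all(np.abs(res.lag_coefs[1:]) < 0.5 * res.lag_coefs[0])
        assert res.slope < 0

    def test_history_blind_agent_has_null_coefficients(self, experiment, schedule):
        y = np.random.default_rng(43).integers(0, 2, 120)
        responses = responses_from_follow(experiment, y)
        res = choice_sequence_glm(responses, experiment, schedule, "gaze", "all")
        assert not res.ridge
        # coefficients statistically indistinguishable from zero
        assert np.all(np.abs(res.lag_coefs) < 4 * res.lag_ses)

    def test_deterministic_fit(self, experiment, schedule):
        responses = self._imitator(experiment)
        a = choice_sequence_glm(responses, experiment, schedule, "card", "stable")
        b = choice_sequence_glm(responses, experiment, schedule, "card", "stable")
        np.testing.assert_array_equal(a.lag_coefs, b.lag_coefs)

    def test_phase_windows_do_not_cross_boundaries(self, experiment, schedule):
        responses = self._imitator(experiment)
        res = choice_sequence_glm(responses, experiment, schedule, "card", "volatile")
        # card volatile phase is trials 61-120; with 5 lags the first usable
        # trial is 66, leaving 55 rows
        assert res.n_rows == 55

    def test_rank_deficient_design_names_columns(self, schedule):
        cfg = ScheduleConfig(reward_range=(5, 5))
        sched = sh.build_schedule(cfg)
        experiment = sh.generate_experiment(sched, 44)
        responses = self._imitator(experiment)
        with pytest.raises(ValueError, match="reward"):
            choice_sequence_glm(responses, experiment, sched, "gaze", "all")

    def test_separable_data_falls_back_to_ridge(self, experiment, schedule):
        responses = self._imitator(experiment, eps=0.0)
        res = choice_sequence_glm(responses, experiment, schedule, "gaze", "all")
        assert res.ridge
        assert np.isfinite(res.lag_coefs).all()

    def test_linear_family_available(self, experiment, schedule):
        responses = self._imitator(experiment)
        res = choice_sequence_glm(
            responses, experiment, schedule, "gaze", "all", family="linear"
        )
        assert res.lag_coefs[0] > 0.5
        assert np.isfinite(res.lag_ses).all()


class TestSlopePhaseContrast:
    def test_identical_slopes_give_zero_statistic(self):
        t, p = slope_phase_contrast([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(51)
        a, b = rng.normal(size=10), rng.normal(size=10)
        t1, _ = slope_phase_contrast(a, b)
        t2, _ = slope_phase_contrast(b, a)
        assert np.isclose(t1, -t2)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            slope_phase_contrast([0.1, 0.2], [0.1])
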