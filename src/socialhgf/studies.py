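"""The package's headline synthetic studies.

Each function runs one self-contained analysis at a configurable size and
returns plain results; the numbered scripts under ``analysis/`` and the
reproduction script drive these, and the test suite asserts their scientific
properties at reduced sizes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import cohorts
from .inversion import FitConfig, fit_subject
from .response import MODEL_SPACE, ModelSpec, run_perceptual
from .selection import BMSResult, rfx_bms
from .task import CohortSpec, build_schedule, generate_cohort
from .validation import (
    RecoveryResult,
    choice_sequence_glm,
    parameter_recovery,
    posterior_predictive,
    precision_weight_summary,
    slope_phase_contrast,
    zeta_alignment,
)

WINNING_MODEL = ModelSpec("hgf", 1)


def fit_cohort(subjects, specs, fit_config: FitConfig, seed: int) -> np.ndarray:
    """Fit every model in ``specs`` to every subject; returns the LME matrix."""
    lme = np.empty((len(subjects), len(specs)))
    rng = np.random.default_rng(seed)
    for i, s in enumerate(subjects):
        for j, spec in enumerate(specs):
            fit = fit_subject(s.experiment, s.responses, spec,
                              config=fit_config, seed=int(rng.integers(2**31)))
            lme[i, j] = fit.lme
    return lme


def parameter_recovery_study(n_subjects: int, n_rep: int, seed: int,
                             fit_config: FitConfig = FitConfig()) -> RecoveryResult:
    """Simulate a priors-dispersion cohort, estimate it once, then check that
    re-simulating from the estimates and refitting recovers them.

    Mirrors the standard recovery protocol: the first-pass estimates play the
    role of the parameters "estimated from the real data", and recovery
    correlates refitted values with them across subjects.
    """
    group = cohorts.priors_dispersion_group(WINNING_MODEL, n_subjects)
    subjects = generate_cohort(CohortSpec(groups=[group]), seed=seed)
    rng = np.random.default_rng(seed + 1)
    fitted = []
    for s in subjects:
        fit = fit_subject(s.experiment, s.responses, WINNING_MODEL,
                          config=fit_config, seed=int(rng.integers(2**31)))
        fitted.append(replace(s, params_est=fit.params_est,
                              params_native=fit.params_native))
    return parameter_recovery(fitted, n_rep=n_rep, seed=seed + 2,
                              fit_config=fit_config)


def model_recovery_study(generating: ModelSpec, n_subjects: int, seed: int,
                         fit_config: FitConfig = FitConfig(),
                         mc_samples: int = 200_000) -> BMSResult:
    """Generate a cohort from one model, fit the whole model space, run BMS."""
    group = cohorts.model_recovery_group(generating, n_subjects)
    subjects = generate_cohort(CohortSpec(groups=[group]), seed=seed)
    lme = fit_cohort(subjects, MODEL_SPACE, fit_config, seed + 1)
    return rfx_bms(lme, mc_samples=mc_samples, seed=seed + 2,
                   model_labels=[m.label for m in MODEL_SPACE])


def phase_effect_study(n_subjects: int, seed: int) -> pd.DataFrame:
    """Cohort-mean precision weights by stream and phase, default parameters."""
    schedule = build_schedule()
    perceptual = {k: v for k, v in cohorts.MODEL_RECOVERY_MEANS.items()
                  if k.startswith("omega")}
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_subjects):
        from .task import generate_experiment

        experiment = generate_experiment(schedule, int(rng.integers(2**31)))
        state = run_perceptual(WINNING_MODEL, experiment, perceptual)
        rows.append(precision_weight_summary(state.trajectories, schedule))
    return pd.DataFrame(rows)


def zeta_alignment_study(seed: int, n_experiments: int = 10) -> pd.DataFrame:
    """Alignment of the combined belief with each input stream over log zeta."""
    return zeta_alignment(range(-5, 6), build_schedule(), seed=seed,
                          n_experiments=n_experiments)


def glm_phase_study(n_subjects: int, seed: int, frame: str = "card") -> dict:
    """Per-subject lagged-regression slopes in stable vs volatile phases."""
    subjects = generate_cohort(cohorts.reference_cohort(n_subjects), seed=seed)
    stable, volatile = [], []
    for s in subjects:
        rs = choice_sequence_glm(s.responses, s.experiment, s.schedule, frame, "stable")
        rv = choice_sequence_glm(s.responses, s.experiment, s.schedule, frame, "volatile")
        stable.append(rs.slope)
        volatile.append(rv.slope)
    stable, volatile = np.asarray(stable), np.asarray(volatile)
    t, p = slope_phase_contrast(stable, volatile)
    return {
        "slopes_stable": stable,
        "slopes_volatile": volatile,
        "mean_diff": float(np.mean(volatile - stable)),
        "t": t,
        "p": p,
    }


def ppc_count_study(n_subjects: int, n_rep: int, seed: int):
    """Posterior-predictive bookkeeping on a synthetic cohort.

    Simulated subjects stand in for fitted ones (their generating parameters
    are the 'estimates'), so the count n_subjects x n_rep is exercised without
    the expense of inverting the full cohort.
    """
    group = cohorts.model_recovery_group(WINNING_MODEL, n_subjects)
    subjects = generate_cohort(CohortSpec(groups=[group]), seed=seed)
    return posterior_predictive(
        subjects,
        [s.experiment for s in subjects],
        [s.schedule for s in subjects],
        n_rep=n_rep,
        seed=seed + 1,
    )
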