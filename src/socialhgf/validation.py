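"""Validation analyses: behavioral summaries, posterior predictive checks,
parameter recovery, precision-weight phase summaries and the lagged-regression
choice-sequence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .inversion import FitConfig, default_priors, fit_subject
from .response import ModelSpec, decision_trajectory, run_perceptual, simulate_agent
from .task import (
    ExperimentInput,
    ResponseRecord,
    STABLE,
    TaskSchedule,
    VOLATILE,
    generate_experiment,
)

SUMMARY_CELLS = [
    "hp_card_stable", "hp_card_volatile",
    "hp_gaze_stable", "hp_gaze_volatile",
    "advice_high_stable", "advice_high_volatile",
    "advice_low_stable", "advice_low_volatile",
]


def _cell_mean(values: np.ndarray, mask: np.ndarray) -> float:
    # all-missing cells are absent (NaN), never zero
    return float(np.mean(values[mask])) if mask.any() else float("nan")


def behavioral_summaries(responses: ResponseRecord, experiment: ExperimentInput,
                         schedule: TaskSchedule) -> pd.Series:
    """Per-subject summary cells.

    A high-probability choice for the card cue means the chosen card's
    ground-truth winning probability was >= 0.5 that trial; for the gaze cue it
    means following when the gaze accuracy was >= 0.5 and not following
    otherwise.  Advice taking is the follow rate split by social accuracy
    (high: p_gaze >= 0.5) and the gaze stream's schedule stability.
    """
    obs = responses.observed
    chosen_p = np.where(responses.chosen_card == "blue",
                        schedule.p_card, 1.0 - schedule.p_card)
    hp_card = (chosen_p >= 0.5).astype(float)
    gaze_high = schedule.p_gaze >= 0.5
    hp_gaze = ((responses.y == 1) == gaze_high).astype(float)
    y = responses.y.astype(float)
    cells = {}
    for phase in (STABLE, VOLATILE):
        m_card = obs & (schedule.phase_card == phase)
        m_gaze = obs & (schedule.phase_gaze == phase)
        cells[f"hp_card_{phase}"] = _cell_mean(hp_card, m_card)
        cells[f"hp_gaze_{phase}"] = _cell_mean(hp_gaze, m_gaze)
        cells[f"advice_high_{phase}"] = _cell_mean(y, m_gaze & gaze_high)
        cells[f"advice_low_{phase}"] = _cell_mean(y, m_gaze & ~gaze_high)
    return pd.Series(cells)


def precision_weight_summary(trajectories: dict, schedule: TaskSchedule) -> pd.Series:
    """Mean q(psi2) and psi3 per stream within that stream's own phases."""
    cells = {}
    for stream, traj in trajectories.items():
        phases = schedule.phase_card if stream == "card" else schedule.phase_gaze
        for phase in (STABLE, VOLATILE):
            mask = phases == phase
            cells[f"qpsi2_{stream}_{phase}"] = _cell_mean(traj.qpsi2, mask)
            cells[f"psi3_{stream}_{phase}"] = _cell_mean(traj.psi3, mask)
    return pd.Series(cells)


@dataclass(frozen=True)
class PPCResult:
    simulations: pd.DataFrame   # one row per subject x replicate
    per_subject: pd.DataFrame   # replicate-averaged cells per subject
    n_simulations: int


def posterior_predictive(fits, experiments, schedules, n_rep: int, seed: int) -> PPCResult:
    """Simulate each subject's fitted model on their own experiment n_rep times.

    ``fits`` may be :class:`~socialhgf.inversion.SubjectFit` objects or any
    objects exposing ``spec`` and ``params_native``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, (fit, experiment, schedule) in enumerate(zip(fits, experiments, schedules)):
        spec = fit.spec if hasattr(fit, "spec") else fit.model
        for rep in range(n_rep):
            sim, _ = simulate_agent(
                experiment, fit.params_native, spec, seed=int(rng.integers(2**31))
            )
            cells = behavioral_summaries(sim, experiment, schedule)
            rows.append(pd.concat([pd.Series({"subject": i, "rep": rep}), cells]))
    simulations = pd.DataFrame(rows).reset_index(drop=True)
    per_subject = simulations.groupby("subject")[SUMMARY_CELLS].mean().reset_index()
    return PPCResult(simulations=simulations, per_subject=per_subject,
                     n_simulations=len(simulations))


@dataclass(frozen=True)
class RecoveryResult:
    table: pd.DataFrame          # subject x parameter true/recovered (estimation space)
    correlations: dict           # name -> Pearson r, or None when degenerate
    reasons: dict                # name -> reason when correlation is absent
    n_subjects: int
    n_rep: int


def parameter_recovery(subjects, n_rep: int, seed: int,
                       priors: dict | None = None,
                       fit_config: FitConfig = FitConfig()) -> RecoveryResult:
    """Simulate-and-refit recovery of generating parameters.

    Per subject, ``n_rep`` fresh response simulations from the true parameters
    are each refit with the generating model; the replicate-mean recovered
    value (estimation space) is correlated with the generating value across
    subjects.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i, subject in enumerate(subjects):
        spec = subject.model
        p = priors if priors is not None else default_priors(spec)
        recovered = []
        for _ in range(n_rep):
            sim, _ = simulate_agent(
                subject.experiment, subject.params_native, spec,
                seed=int(rng.integers(2**31)),
            )
            fit = fit_subject(subject.experiment, sim, spec, priors=p,
                              config=fit_config, seed=int(rng.integers(2**31)))
            recovered.append(fit.params_est)
        row = {"subject": i}
        for name in spec.free_params:
            row[f"{name}_true"] = subject.params_est[name]
            row[f"{name}_recovered"] = float(np.mean([r[name] for r in recovered]))
        rows.append(row)
    table = pd.DataFrame(rows)
    correlations, reasons = {}, {}
    param_names = subjects[0].model.free_params
    for name in param_names:
        true = table[f"{name}_true"].to_numpy()
        rec = table[f"{name}_recovered"].to_numpy()
        if np.std(true) == 0 or np.std(rec) == 0:
            correlations[name] = None
            reasons[name] = "zero variance in generating or recovered values"
        else:
            correlations[name] = float(stats.pearsonr(true, rec)[0])
    return RecoveryResult(table=table, correlations=correlations, reasons=reasons,
                          n_subjects=len(subjects), n_rep=n_rep)


# ---------------------------------------------------------------------------
# Lagged-regression choice sequence analysis


@dataclass(frozen=True)
class GLMResult:
    frame: str
    phase: str
    lag_coefs: np.ndarray
    lag_ses: np.ndarray
    reward_coefs: np.ndarray
    intercept: float
    slope: float
    n_rows: int
    ridge: bool


def _glm_design(responses: ResponseRecord, experiment: ExperimentInput,
                schedule: TaskSchedule, frame: str, phase: str, lags: int):
    if frame == "card":
        y_all = (responses.chosen_card == "blue").astype(float)
        outcome = experiment.u_card.astype(float)
        rewards = np.column_stack([experiment.reward_blue, experiment.reward_green])
        reward_names = ["reward_blue", "reward_green"]
        phases = schedule.phase_card
    elif frame == "gaze":
        y_all = responses.y.astype(float)
        outcome = experiment.u_gaze.astype(float)
        rewards = np.column_stack([experiment.r_gaze, experiment.r_notgaze])
        reward_names = ["reward_gaze", "reward_notgaze"]
        phases = schedule.phase_gaze
    else:
        raise ValueError(f"unknown frame {frame!r}")
    if phase not in ("all", STABLE, VOLATILE):
        raise ValueError(f"unknown phase {phase!r}")
    obs = responses.observed
    n = experiment.n_trials
    keep, y_rows, x_rows = [], [], []
    for t in range(lags, n):
        window = np.arange(t - lags, t + 1)
        if not obs[window].all():
            continue
        # lag windows never cross a phase boundary
        if phase != "all" and not (phases[window] == phase).all():
            continue
        keep.append(t)
        y_rows.append(y_all[t])
        x_rows.append(np.concatenate((outcome[t - 1 :: -1][:lags], rewards[t])))
    if len(keep) < lags + 1:
        raise ValueError(
            f"need at least {lags + 1} usable trials in phase {phase!r}, got {len(keep)}"
        )
    names = [f"outcome_lag{j}" for j in range(1, lags + 1)] + reward_names
    X = np.asarray(x_rows)
    y = np.asarray(y_rows)
    return y, X, names


def choice_sequence_glm(responses: ResponseRecord, experiment: ExperimentInput,
                        schedule: TaskSchedule, frame: str, phase: str = "all",
                        lags: int = 5, family: str = "logistic") -> GLMResult:
    """Lagged regression of choices on the past ``lags`` outcomes plus rewards.

    Binary outcomes are fit with a logistic link (a linear-probability fit is
    available via ``family='linear'`` for sensitivity checks).  Perfect
    separation falls back to a small ridge penalty, flagged in the result.
    The lag slope is the least-squares slope of the lag coefficients against
    the lag index; a negative slope means recent outcomes dominate.
    """
    import statsmodels.api as sm

    y, X, names = _glm_design(responses, experiment, schedule, frame, phase, lags)
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        degenerate = [names[j] for j in range(X.shape[1]) if np.std(X[:, j]) == 0]
        raise ValueError(
            "rank-deficient design matrix; collinear or constant columns: "
            + (", ".join(degenerate) if degenerate else "(linear combination)")
        )
    ridge = False
    if family == "linear":
        res = sm.OLS(y, Xc).fit()
        coefs, ses = res.params, res.bse
    else:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        model = sm.GLM(y, Xc, family=sm.families.Binomial())
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = model.fit(maxiter=200)
            coefs, ses = res.params, res.bse
            # exploding coefficients on 0/1 predictors signal quasi-separation
            if not np.isfinite(coefs).all() or np.abs(coefs).max() > 20.0:
                raise ValueError("separation")
        except Exception:
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
            coefs = np.asarray(res.params)
            ses = np.full_like(coefs, np.nan)
            ridge = True
    lag_coefs = np.asarray(coefs[1 : lags + 1])
    slope = float(np.polyfit(np.arange(1, lags + 1), lag_coefs, 1)[0])
    return GLMResult(
        frame=frame,
        phase=phase,
        lag_coefs=lag_coefs,
        lag_ses=np.asarray(ses[1 : lags + 1]),
        reward_coefs=np.asarray(coefs[lags + 1 :]),
        intercept=float(coefs[0]),
        slope=slope,
        n_rows=len(y),
        ridge=ridge,
    )


def slope_phase_contrast(slopes_stable, slopes_volatile):
    """Paired t test on per-subject stable-minus-volatile lag slopes."""
    slopes_stable = np.asarray(slopes_stable, dtype=float)
    slopes_volatile = np.asarray(slopes_volatile, dtype=float)
    if slopes_stable.shape != slopes_volatile.shape:
        raise ValueError("stable and volatile slope vectors must pair up")
    if len(slopes_stable) < 2:
        raise ValueError("need at least two paired subjects")
    if np.all(slopes_stable == slopes_volatile):
        return 0.0, 1.0
    res = stats.ttest_rel(slopes_stable, slopes_volatile)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Social-weighting alignment curves


def zeta_alignment(log_zetas, schedule: TaskSchedule, n_experiments: int = 10,
                   seed: int = 0, perceptual_params: dict | None = None,
                   beta: float = 48.0, eta: float = 1.0) -> pd.DataFrame:
    """Alignment of the combined belief with each stream's ground truth
    across the social weighting factor.

    Agents share perceptual parameters (defaults: the prior means) and differ
    only in zeta.  ``alignment_gaze``/``alignment_card`` are the partial
    regression coefficients of the per-trial combined belief on the two
    ground-truth probability schedules jointly (gaze accuracy, and the
    gaze-frame probability that the gazed-at card wins).  The joint regression
    matters: the two streams' predictions are mutually informative, so any
    marginal agreement measure peaks at an interior zeta, whereas the partial
    coefficients track which structure the belief actually follows.  Marginal
    Pearson correlations are included as ``corr_gaze``/``corr_card``.
    """
    if perceptual_params is None:
        perceptual_params = {
            "omega2_card": -3.0, "omega2_gaze": -3.0,
            "omega3_card": -6.0, "omega3_gaze": -6.0,
        }
    spec = ModelSpec("hgf", 1)
    rng = np.random.default_rng(seed)
    acc = {lz: {"gaze": [], "card": [], "cg": [], "cc": []} for lz in log_zetas}
    for _ in range(n_experiments):
        experiment = generate_experiment(schedule, int(rng.integers(2**31)))
        state = run_perceptual(spec, experiment, perceptual_params)
        p_card_gf = np.where(
            experiment.gaze_is_blue, schedule.p_card, 1.0 - schedule.p_card
        )
        X = np.column_stack(
            [schedule.p_gaze, p_card_gf, np.ones(schedule.n_trials)]
        )
        for lz in log_zetas:
            params = dict(perceptual_params, zeta=float(np.exp(lz)), beta=beta, eta=eta)
            decision = decision_trajectory(spec, state, experiment, params)
            b = decision.b
            b_card = np.where(experiment.gaze_is_blue, b, 1.0 - b)
            coef, *_ = np.linalg.lstsq(X, b, rcond=None)
            acc[lz]["gaze"].append(coef[0])
            acc[lz]["card"].append(coef[1])
            acc[lz]["cg"].append(stats.pearsonr(b, schedule.p_gaze)[0])
            acc[lz]["cc"].append(stats.pearsonr(b_card, schedule.p_card)[0])
    rows = [
        {
            "log_zeta": lz,
            "alignment_gaze": float(np.mean(acc[lz]["gaze"])),
            "alignment_card": float(np.mean(acc[lz]["card"])),
            "corr_gaze": float(np.mean(acc[lz]["cg"])),
            "corr_card": float(np.mean(acc[lz]["cc"])),
        }
        for lz in log_zetas
    ]
    return pd.DataFrame(rows)
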