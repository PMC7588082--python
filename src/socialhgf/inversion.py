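"""Subject-level MAP estimation with Laplace-approximated log model evidence.

Each free parameter is estimated in a transformed space (native, log or logit)
under an independent Gaussian prior.  The posterior mode is found with a
quasi-Newton optimizer (numerical gradients) restarted from seeded
perturbations of the prior mean, and the log model evidence (LME) is the
Laplace approximation

    LME = log p(y, theta*) + d/2 * ln(2*pi) - 1/2 * ln det(-H),

with H the numerically differentiated Hessian of the log-joint at the mode
theta* and d the number of free parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

from .perceptual import FilterRejection
from .response import ModelSpec, likelihood_series
from .task import ExperimentInput, ResponseRecord

REJECTION_PENALTY = -1e10

SPACES = ("native", "log", "logit")


def to_native_value(value: float, space: str) -> float:
    if space == "native":
        return value
    if space == "log":
        # saturate far outside any plausible range so optimizer excursions
        # see a flat region instead of an overflow
        return math.exp(min(value, 700.0))
    if space == "logit":
        return float(expit(value))
    raise ValueError(f"unknown estimation space {space!r}")


def to_estimation_value(value: float, space: str) -> float:
    if space == "native":
        return value
    if space == "log":
        if value <= 0:
            raise ValueError("log-space parameters must be positive in native space")
        return math.log(value)
    if space == "logit":
        if not 0.0 < value < 1.0:
            raise ValueError("logit-space parameters must lie in (0, 1) in native space")
        return float(logit(value))
    raise ValueError(f"unknown estimation space {space!r}")


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on one parameter in its estimation space."""

    space: str
    mean: float
    var: float
    fixed: bool = False

    def __post_init__(self):
        if self.space not in SPACES:
            raise ValueError(f"unknown estimation space {self.space!r}")
        if not self.fixed and self.var <= 0:
            raise ValueError("free parameters need positive prior variance")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)


#: Default weakly-informative priors, given in each parameter's estimation
#: space.  Evolution rates omega are native; zeta/beta are log; eta and the
#: baseline parameters are logit.
DEFAULT_PRIORS = {
    "omega2_card": Prior("native", -3.0, 16.0),
    "omega2_gaze": Prior("native", -3.0, 16.0),
    "omega3_card": Prior("native", -6.0, 16.0),
    "omega3_gaze": Prior("native", -6.0, 16.0),
    "zeta": Prior("log", 0.0, 4.0),
    # decision-noise scale: the customary softmax prior centred at beta = 48
    # (with the volatility attenuation exp(-muhat3_card - muhat3_gaze) ~ e^-2
    # this yields moderate effective temperatures)
    "beta": Prior("log", math.log(48.0), 1.0),
    "eta": Prior("logit", 0.0, 4.0),
    "alpha_card": Prior("logit", 0.0, 1.0),
    "alpha_gaze": Prior("logit", 0.0, 1.0),
    "meta_card": Prior("log", 0.0, 4.0),
    "meta_gaze": Prior("log", 0.0, 4.0),
    "epsilon": Prior("logit", 0.0, 1.0),
    "bias": Prior("logit", 0.0, 1.0),
}


def default_priors(spec: ModelSpec) -> dict:
    """Priors for every free parameter of ``spec``."""
    return {name: DEFAULT_PRIORS[name] for name in spec.free_params}


def estimation_space(name: str) -> str:
    return DEFAULT_PRIORS[name].space


def to_native(params_est: dict, spec: ModelSpec | None = None) -> dict:
    """Map a dict of estimation-space values to native space."""
    return {
        name: to_native_value(value, estimation_space(name))
        for name, value in params_est.items()
    }


def to_estimation(params_native: dict) -> dict:
    return {
        name: to_estimation_value(value, estimation_space(name))
        for name, value in params_native.items()
    }


def log_joint(theta: np.ndarray, experiment: ExperimentInput,
              responses: ResponseRecord, spec: ModelSpec, priors: dict) -> float:
    """Log-likelihood plus Gaussian log-prior at estimation-space ``theta``.

    Filter rejections (invalid belief trajectories) map to a large negative
    penalty so line searches remain finite.
    """
    names = [n for n in spec.free_params if not priors[n].fixed]
    logprior = 0.0
    params_est = {}
    for value, name in zip(theta, names):
        p = priors[name]
        logprior += -0.5 * math.log(2 * math.pi * p.var) - 0.5 * (value - p.mean) ** 2 / p.var
        params_est[name] = value
    for name in spec.free_params:
        if priors[name].fixed:
            params_est[name] = priors[name].mean
    params_native = to_native(params_est, spec)
    if responses.n_trials == 0 or not responses.observed.any():
        return logprior
    try:
        _, loglik, _, _ = likelihood_series(spec, experiment, responses, params_native)
    except (FilterRejection, FloatingPointError, OverflowError):
        return REJECTION_PENALTY
    if not math.isfinite(loglik):
        return REJECTION_PENALTY
    return loglik + logprior


@dataclass(frozen=True)
class FitConfig:
    n_restarts: int = 4
    perturb_scale: float = 0.25   # restart SD as a fraction of the prior SD
    tol: float = 1e-6
    maxiter: int = 1000
    hessian_step: float = 1e-4


@dataclass(frozen=True)
class SubjectFit:
    """MAP fit of one model to one subject."""

    spec: ModelSpec
    params_est: dict
    params_native: dict
    lme: float
    log_joint: float
    neg_hessian: np.ndarray
    converged: bool
    n_restarts: int
    best_restart: int
    hessian_regularized: bool
    seed: int


def numerical_hessian(fn, x: np.ndarray, step: float) -> np.ndarray:
    """Central-finite-difference Hessian of ``fn`` at ``x``."""
    d = len(x)
    H = np.empty((d, d))
    f0 = fn(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (fn(x + ei) - 2.0 * f0 + fn(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                fn(x + ei + ej) - fn(x + ei - ej) - fn(x - ei + ej) + fn(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def map_laplace(objective, x0_list, config: FitConfig = FitConfig()):
    """Maximize ``objective`` from several starts; Laplace-correct the best mode.

    Returns ``(x_mode, lj_mode, lme, negH, converged, best_start, regularized)``.
    """
    best = None
    converged = False
    best_idx = -1
    for idx, x0 in enumerate(x0_list):
        res = optimize.minimize(
            lambda x: -objective(x),
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            # L-BFGS-B's ftol is relative to max(|f|, 1); divide by a typical
            # objective scale so config.tol acts as an absolute tolerance
            options={"ftol": config.tol / 100.0, "gtol": 1e-7,
                     "maxiter": config.maxiter},
        )
        if best is None or -res.fun > best[1]:
            best = (res.x, -res.fun)
            converged = bool(res.success)
            best_idx = idx
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError("all optimizer restarts failed")
    x_mode, lj_mode = best
    d = len(x_mode)
    H = numerical_hessian(objective, x_mode, config.hessian_step)
    negH = -H
    regularized = False
    eigvals = np.linalg.eigvalsh(negH)
    if eigvals.min() <= 0:
        negH = negH + (abs(eigvals.min()) + 1e-6) * np.eye(d)
        regularized = True
    sign, logdet = np.linalg.slogdet(negH)
    lme = lj_mode + 0.5 * d * math.log(2 * math.pi) - 0.5 * logdet
    return x_mode, lj_mode, lme, negH, converged, best_idx, regularized


def fit_subject(experiment: ExperimentInput, responses: ResponseRecord,
                spec: ModelSpec, priors: dict | None = None,
                config: FitConfig = FitConfig(), seed: int = 0) -> SubjectFit:
    """MAP-fit one model to one subject's data.

    Starts at the prior mean plus ``n_restarts - 1`` seeded Gaussian
    perturbations (SD = prior SD * ``perturb_scale``) and keeps the best mode.
    Deterministic given identical data, config and seed.
    """
    if responses.n_trials < 1 or not responses.observed.any():
        raise ValueError("fit_subject needs at least one observed trial")
    if priors is None:
        priors = default_priors(spec)
    free = [n for n in spec.free_params if not priors[n].fixed]
    means = np.array([priors[n].mean for n in free])
    sds = np.array([priors[n].sd for n in free])
    rng = np.random.default_rng(seed)
    starts = [means] + [
        means + config.perturb_scale * sds * rng.standard_normal(len(free))
        for _ in range(config.n_restarts - 1)
    ]

    def objective(theta):
        return log_joint(theta, experiment, responses, spec, priors)

    x, lj, lme, negH, converged, best_idx, regularized = map_laplace(
        objective, starts, config
    )
    params_est = dict(zip(free, (float(v) for v in x)))
    for name in spec.free_params:
        if priors[name].fixed:
            params_est[name] = priors[name].mean
    return SubjectFit(
        spec=spec,
        params_est=params_est,
        params_native=to_native(params_est, spec),
        lme=float(lme),
        log_joint=float(lj),
        neg_hessian=negH,
        converged=converged,
        n_restarts=config.n_restarts,
        best_restart=best_idx,
        hessian_regularized=regularized,
        seed=seed,
    )


def fit_table(fits: list) -> "object":
    """Tidy per-subject x model table of estimates and diagnostics."""
    import pandas as pd

    rows = []
    for i, fit in enumerate(fits):
        row = {"subject": i, "model": fit.spec.label, "lme": fit.lme,
               "converged": fit.converged,
               "hessian_regularized": fit.hessian_regularized}
        for name, value in fit.params_est.items():
            row[f"{name}_est"] = value
        for name, value in fit.params_native.items():
            row[f"{name}_native"] = value
        rows.append(row)
    return pd.DataFrame(rows)
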