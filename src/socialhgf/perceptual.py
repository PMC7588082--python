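"""Trial-by-trial perceptual filters: three-level binary HGF, Rescorla-Wagner
and Sutton K1.

The hierarchical Gaussian filter (HGF) tracks, per input stream, a binary
outcome tendency (level 2, in logit space) and its log-volatility (level 3).
Beliefs mu_i with precisions pi_i are updated by precision-weighted prediction
errors from the level below; the tonic log-volatility parameters omega_2 and
omega_3 set how fast the tendency and the volatility can move.  Levels 2 and 3
support an AR(1) drift toward an attractor, fixed by default to the pure
random-walk limit (phi = 0).

Both task streams (card tendency, gaze accuracy) are filtered independently
with their own parameters; responses never feed back into the filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "sigmoid",
    "HGFParams",
    "HGFTrajectory",
    "FilterRejection",
    "hgf_filter",
    "derived_precision_weights",
    "rw_filter",
    "sutton_k1_filter",
]

MUHAT1_CLIP = 1e-8     # keeps the Bernoulli precision 1/(m(1-m)) finite
MIN_PRECISION = 1e-12  # posterior precisions below this reject the parameters


def sigmoid(x):
    """Logistic sigmoid 1/(1+exp(-x)), saturating without overflow."""
    return expit(x)


class FilterRejection(ValueError):
    """A parameter set produced a non-finite or non-positive-precision state.

    Carries the 1-based ``trial`` at which filtering failed so that a fitter
    can penalize the parameter set instead of crashing.
    """

    def __init__(self, trial: int, message: str = "filter rejected parameters"):
        super().__init__(f"{message} at trial {trial}")
        self.trial = int(trial)


@dataclass(frozen=True)
class HGFParams:
    """Parameters of one stream's three-level binary HGF.

    omega2/omega3 are the tonic log-volatilities ("evolution rates") of levels
    2 and 3; kappa couples level 3 into the level-2 step size.  phi/m are the
    AR(1) coefficients and attractors, zero by default (random walk).
    """

    omega2: float = -3.0
    omega3: float = -6.0
    kappa: float = 1.0
    mu2_0: float = 0.0
    sigma2_0: float = 1.0
    mu3_0: float = 1.0
    # level-3 prior variance defaults to the filter's approximate stationary
    # posterior variance under the default evolution rates, so that phase
    # contrasts of psi3 are not confounded by a start-up transient
    sigma3_0: float = 0.5
    phi2: float = 0.0
    m2: float = 0.0
    phi3: float = 0.0
    m3: float = 0.0

    def validate(self) -> None:
        if self.sigma2_0 <= 0 or self.sigma3_0 <= 0:
            raise ValueError("initial variances must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class HGFTrajectory:
    """Per-trial HGF quantities for one stream (arrays of length n_trials).

    ``muhat*``/``pihat*`` are the pre-outcome predictions on each trial; the
    unhatted quantities are the post-outcome posteriors.  ``psi2 = 1/pi2``,
    ``qpsi2 = psi2 * s(mu2)(1 - s(mu2))`` and ``psi3 = pihat2/pi3`` are the
    dynamic learning rates (precision weights).
    """

    muhat1: np.ndarray
    pihat1: np.ndarray
    da1: np.ndarray
    muhat2: np.ndarray
    pihat2: np.ndarray
    mu2: np.ndarray
    pi2: np.ndarray
    da2: np.ndarray
    muhat3: np.ndarray
    pihat3: np.ndarray
    mu3: np.ndarray
    pi3: np.ndarray
    psi2: np.ndarray = field(default=None)
    qpsi2: np.ndarray = field(default=None)
    psi3: np.ndarray = field(default=None)


def _hgf_core(u, omega2, omega3, kappa, mu2_0, sigma2_0, mu3_0, sigma3_0,
              phi2, m2, phi3, m3, out):
    """Sequential prediction/update recursion; returns 0 or the 1-based
    rejection trial.  ``out`` is an (n, 12) array filled in place with columns
    muhat1, pihat1, da1, muhat2, pihat2, mu2, pi2, da2, muhat3, pihat3, mu3, pi3.
    """
    n = u.shape[0]
    mu2 = mu2_0
    pi2 = 1.0 / sigma2_0
    mu3 = mu3_0
    pi3 = 1.0 / sigma3_0
    for k in range(n):
        # prediction step
        muhat2 = mu2 + phi2 * (m2 - mu2)
        muhat1 = 1.0 / (1.0 + math.exp(-muhat2))
        if muhat1 < MUHAT1_CLIP:
            muhat1 = MUHAT1_CLIP
        elif muhat1 > 1.0 - MUHAT1_CLIP:
            muhat1 = 1.0 - MUHAT1_CLIP
        pihat1 = 1.0 / (muhat1 * (1.0 - muhat1))
        v2 = math.exp(kappa * mu3 + omega2)
        pihat2 = 1.0 / (1.0 / pi2 + v2)
        muhat3 = mu3 + phi3 * (m3 - mu3)
        v3 = math.exp(omega3)
        pihat3 = 1.0 / (1.0 / pi3 + v3)

        # update step
        da1 = u[k] - muhat1
        pi2_new = pihat2 + 1.0 / pihat1
        mu2_new = muhat2 + da1 / pi2_new
        da2 = (1.0 / pi2_new + (mu2_new - muhat2) ** 2) * pihat2 - 1.0
        w2 = v2 * pihat2
        pi3_new = pihat3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
        if pi3_new <= MIN_PRECISION or not math.isfinite(pi3_new):
            return k + 1
        mu3_new = muhat3 + 0.5 * kappa * w2 * da2 / pi3_new
        if not (math.isfinite(mu2_new) and math.isfinite(mu3_new)):
            return k + 1

        mu2, pi2, mu3, pi3 = mu2_new, pi2_new, mu3_new, pi3_new
        out[k, 0] = muhat1
        out[k, 1] = pihat1
        out[k, 2] = da1
        out[k, 3] = muhat2
        out[k, 4] = pihat2
        out[k, 5] = mu2
        out[k, 6] = pi2
        out[k, 7] = da2
        out[k, 8] = muhat3
        out[k, 9] = pihat3
        out[k, 10] = mu3
        out[k, 11] = pi3
    return 0


try:  # JIT-compile the recursion when numba is present
    from numba import njit

    _hgf_core = njit(cache=False)(_hgf_core)
except Exception:  # pragma: no cover - plain Python is a drop-in fallback
    pass


def hgf_filter(inputs, params: HGFParams) -> HGFTrajectory:
    """Filter one binary input series through the three-level binary HGF.

    Raises :class:`FilterRejection` (with the trial index) when the level-3
    posterior precision becomes non-positive or a state diverges.
    """
    params.validate()
    u = np.asarray(inputs, dtype=np.float64)
    if not np.isin(u, (0.0, 1.0)).all():
        raise ValueError("HGF inputs must be binary (0/1)")
    out = np.empty((len(u), 12), dtype=np.float64)
    status = _hgf_core(
        u, params.omega2, params.omega3, params.kappa,
        params.mu2_0, params.sigma2_0, params.mu3_0, params.sigma3_0,
        params.phi2, params.m2, params.phi3, params.m3, out,
    )
    if status:
        raise FilterRejection(status)
    traj = HGFTrajectory(*(out[:, j].copy() for j in range(12)))
    psi2, qpsi2, psi3 = derived_precision_weights(traj)
    return HGFTrajectory(
        **{f: getattr(traj, f) for f in (
            "muhat1", "pihat1", "da1", "muhat2", "pihat2", "mu2", "pi2",
            "da2", "muhat3", "pihat3", "mu3", "pi3")},
        psi2=psi2, qpsi2=qpsi2, psi3=psi3,
    )


def derived_precision_weights(trajectory: HGFTrajectory):
    """Precision-weight series psi2 = 1/pi2, q(psi2) and psi3 = pihat2/pi3."""
    if np.any(trajectory.pi2 <= 0) or np.any(trajectory.pi3 <= 0):
        raise ValueError("posterior precisions must be positive")
    psi2 = 1.0 / trajectory.pi2
    s = sigmoid(trajectory.mu2)
    qpsi2 = psi2 * s * (1.0 - s)
    psi3 = trajectory.pihat2 / trajectory.pi3
    return psi2, qpsi2, psi3


def rw_filter(inputs, alpha: float, v0: float = 0.5) -> np.ndarray:
    """Rescorla-Wagner delta rule v(k) = v(k-1) + alpha * (u(k) - v(k-1)).

    Returns the posterior value series; the trial-k prediction is ``v(k-1)``
    (``v0`` on trial 1).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    u = np.asarray(inputs, dtype=float)
    v = np.empty(len(u))
    prev = v0
    for k in range(len(u)):
        prev = prev + alpha * (u[k] - prev)
        v[k] = prev
    return v


def sutton_k1_filter(inputs, meta_rate: float, alpha0: float = 0.1):
    """Sutton K1: a delta rule whose gain adapts to recent prediction errors.

    The log-gain beta moves by ``meta_rate * delta(k) * h(k-1)``, where h is a
    decaying trace of past weighted prediction errors, so the gain rises
    multiplicatively when current and recent errors agree in sign; the gain is
    bounded to (0, 1].  Returns ``(values, gains)``.
    """
    if meta_rate < 0:
        raise ValueError("meta_rate must be >= 0")
    if not 0.0 < alpha0 <= 1.0:
        raise ValueError("alpha0 must lie in (0, 1]")
    u = np.asarray(inputs, dtype=float)
    n = len(u)
    v = np.empty(n)
    alphas = np.empty(n)
    prev_v = 0.5
    log_gain = math.log(alpha0)
    h = 0.0
    for k in range(n):
        da = u[k] - prev_v
        log_gain = log_gain + meta_rate * da * h
        alpha = min(1.0, math.exp(log_gain))
        if not math.isfinite(alpha):
            raise FilterRejection(k + 1, "non-finite K1 gain")
        prev_v = prev_v + alpha * da
        h = h * max(0.0, 1.0 - alpha) + alpha * da
        v[k] = prev_v
        alphas[k] = alpha
    return v, alphas
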