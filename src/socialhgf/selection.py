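"""Group-level random-effects Bayesian model selection.

Given a subjects x models matrix of log model evidences, model frequencies r
in the population get a Dirichlet posterior by variational Bayes: subject-wise
model assignment responsibilities and the Dirichlet concentrations are
iterated to convergence.  Reported are the expected posterior model
probabilities (EXP_R), exceedance probabilities (XP, Monte-Carlo over the
Dirichlet posterior), the Bayes omnibus risk (BOR, the posterior probability
that all models are equally frequent) and the protected exceedance
probabilities PXP = (1 - BOR) * XP + BOR / K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


@dataclass(frozen=True)
class BMSResult:
    alpha: np.ndarray
    exp_r: np.ndarray
    xp: np.ndarray
    pxp: np.ndarray
    bor: float
    model_labels: list
    mc_samples: int
    xp_mc_se: np.ndarray
    seed: int
    n_iterations: int


def _validate_lme(lme: np.ndarray) -> np.ndarray:
    lme = np.asarray(lme, dtype=float)
    if lme.ndim != 2 or lme.shape[0] < 1 or lme.shape[1] < 2:
        raise ValueError("LME matrix must be subjects x models with >= 2 models")
    if not np.isfinite(lme).all():
        raise ValueError("LME matrix contains non-finite entries")
    return lme


def _vb_dirichlet(lme: np.ndarray, alpha0: float, tol: float = 1e-6,
                  max_iter: int = 10000):
    """Variational updates for the Dirichlet model-frequency posterior."""
    n, k = lme.shape
    alpha = np.full(k, alpha0)
    for iteration in range(1, max_iter + 1):
        log_u = lme + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u, iteration


def _rfx_free_energy(lme: np.ndarray, alpha: np.ndarray, u: np.ndarray,
                     alpha0: float) -> float:
    """Variational free energy of the random-effects model at convergence."""
    n, k = lme.shape
    e_log_r = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy_u = -np.nansum(u * np.log(np.where(u > 0, u, 1.0)))
    f = float(np.sum(u * (lme + e_log_r)) + entropy_u)
    # Dirichlet prior/posterior terms
    f += gammaln(k * alpha0) - k * gammaln(alpha0) + float((alpha0 - 1) * e_log_r.sum())
    f -= float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + np.sum((alpha - 1) * e_log_r)
    )
    return f


def _null_free_energy(lme: np.ndarray) -> float:
    """Log evidence of the null hypothesis of equal model frequencies."""
    n, k = lme.shape
    return float(np.sum(logsumexp(lme, axis=1) - np.log(k)))


def exceedance_probabilities(alpha: np.ndarray, mc_samples: int, seed: int):
    """Monte-Carlo P(r_k > r_j for all j != k) under Dirichlet(alpha)."""
    rng = np.random.default_rng(seed)
    k = len(alpha)
    counts = np.zeros(k)
    remaining = int(mc_samples)
    batch = 200_000
    while remaining > 0:
        m = min(batch, remaining)
        draws = rng.standard_gamma(alpha, size=(m, k))
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    xp = counts / mc_samples
    se = np.sqrt(xp * (1.0 - xp) / mc_samples)
    return xp, se


def rfx_bms(lme, mc_samples: int = 1_000_000, seed: int = 0,
            alpha0: float = 1.0, model_labels: list | None = None) -> BMSResult:
    """Random-effects Bayesian model selection over an LME matrix."""
    lme = _validate_lme(lme)
    n, k = lme.shape
    if model_labels is None:
        model_labels = [f"model_{j + 1}" for j in range(k)]
    alpha, u, n_iter = _vb_dirichlet(lme, alpha0)
    exp_r = alpha / alpha.sum()
    xp, xp_se = exceedance_probabilities(alpha, mc_samples, seed)
    f1 = _rfx_free_energy(lme, alpha, u, alpha0)
    f0 = _null_free_energy(lme)
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * xp + bor / k
    return BMSResult(
        alpha=alpha,
        exp_r=exp_r,
        xp=xp,
        pxp=pxp,
        bor=bor,
        model_labels=list(model_labels),
        mc_samples=int(mc_samples),
        xp_mc_se=xp_se,
        seed=seed,
        n_iterations=n_iter,
    )


@dataclass(frozen=True)
class WithinSubjectBest:
    best_index: np.ndarray
    counts: np.ndarray
    tie: np.ndarray


def within_subject_best(lme) -> WithinSubjectBest:
    """Row-wise best model; ties go to the lowest index and are flagged."""
    lme = _validate_lme(lme)
    best = np.argmax(lme, axis=1)
    tie = np.array([np.sum(row == row.max()) > 1 for row in lme])
    counts = np.bincount(best, minlength=lme.shape[1])
    return WithinSubjectBest(best_index=best, counts=counts, tie=tie)
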