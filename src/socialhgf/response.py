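"""Response models: mapping dual-stream beliefs to follow/not-follow choices.

The decision variable is a combined belief b(t) -- a precision-weighted convex
combination of the social prediction (gaze will indicate the winner) and the
non-social prediction (the gazed-at card's color will win), with the social
weighting factor zeta scaling the social precision.  b(t) enters a
reward-weighted softmax whose inverse temperature gamma(t) is, depending on
the response variant, attenuated by the predicted log-volatility of one or
both streams.  Two non-learning baselines (win-stay-lose-shift and random
responding) complete the model space.

All probabilities live in the gaze frame: y = 1 means the advice was followed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .perceptual import (
    HGFParams,
    MUHAT1_CLIP,
    hgf_filter,
    rw_filter,
    sigmoid,
    sutton_k1_filter,
)
from .task import ExperimentInput, ResponseRecord, responses_from_follow

PROB_CLIP = 1e-8

HGF_PARAM_NAMES = ["omega2_card", "omega2_gaze", "omega3_card", "omega3_gaze"]
RESPONSE_PARAM_NAMES = ["zeta", "beta", "eta"]


@dataclass(frozen=True)
class ModelSpec:
    """A perceptual family paired with a response rule.

    ``perceptual`` is one of ``hgf``, ``rw``, ``k1`` or ``none``; ``response``
    is a softmax variant 1-4 or one of the baselines ``wsls`` / ``random``.
    Variants 1-3 use third-level volatility predictions and therefore require
    the HGF; the baselines use no perceptual model.
    """

    perceptual: str
    response: object

    def __post_init__(self):
        if self.perceptual not in ("hgf", "rw", "k1", "none"):
            raise ValueError(f"unknown perceptual family {self.perceptual!r}")
        if self.response not in (1, 2, 3, 4, "wsls", "random"):
            raise ValueError(f"unknown response variant {self.response!r}")
        if self.response in (1, 2, 3) and self.perceptual != "hgf":
            raise ValueError("response variants 1-3 require the HGF (they use muhat3)")
        if self.response in ("wsls", "random") and self.perceptual != "none":
            raise ValueError("baseline response models take no perceptual family")
        if self.response == 4 and self.perceptual == "none":
            raise ValueError("response variant 4 requires a perceptual family")

    @property
    def label(self) -> str:
        if self.response in ("wsls", "random"):
            return self.response
        return f"{self.perceptual}-{self.response}"

    @property
    def free_params(self) -> list:
        if self.response == "wsls":
            return ["epsilon"]
        if self.response == "random":
            return ["bias"]
        if self.perceptual == "hgf":
            return HGF_PARAM_NAMES + RESPONSE_PARAM_NAMES
        if self.perceptual == "rw":
            return ["alpha_card", "alpha_gaze"] + RESPONSE_PARAM_NAMES
        return ["meta_card", "meta_gaze"] + RESPONSE_PARAM_NAMES


#: The full model space compared in the group-level selection: the HGF with
#: all four softmax variants, the two non-hierarchical learners with the
#: volatility-free variant 4, and the two non-learning baselines.
MODEL_SPACE = [
    ModelSpec("hgf", 1),
    ModelSpec("hgf", 2),
    ModelSpec("hgf", 3),
    ModelSpec("hgf", 4),
    ModelSpec("k1", 4),
    ModelSpec("rw", 4),
    ModelSpec("none", "wsls"),
    ModelSpec("none", "random"),
]


@dataclass(frozen=True)
class PerceptualState:
    """Per-trial predictions feeding the response model.

    ``muhat1_card`` predicts "blue wins"; ``muhat1_gaze`` predicts "gaze is
    correct".  ``muhat3_*`` are third-level log-volatility predictions (zeros
    for non-hierarchical families).  ``trajectories`` keeps the full per-stream
    filter output for audit.
    """

    muhat1_card: np.ndarray
    muhat1_gaze: np.ndarray
    muhat3_card: np.ndarray
    muhat3_gaze: np.ndarray
    trajectories: dict


@dataclass(frozen=True)
class DecisionTrajectory:
    mu1hat_card_gf: np.ndarray  # gaze-frame card prediction
    mu1hat_gaze: np.ndarray
    w_gaze: np.ndarray
    w_card: np.ndarray
    b: np.ndarray
    gamma: np.ndarray
    prob_gaze: np.ndarray


def run_perceptual(spec: ModelSpec, experiment: ExperimentInput, params: dict) -> PerceptualState:
    """Run the model specification's perceptual filters on both input streams."""
    n = experiment.n_trials
    zeros = np.zeros(n)
    if spec.perceptual == "hgf":
        trajs = {}
        for stream in ("card", "gaze"):
            u = experiment.u_card if stream == "card" else experiment.u_gaze
            hp = HGFParams(
                omega2=params[f"omega2_{stream}"], omega3=params[f"omega3_{stream}"]
            )
            trajs[stream] = hgf_filter(u, hp)
        return PerceptualState(
            muhat1_card=trajs["card"].muhat1,
            muhat1_gaze=trajs["gaze"].muhat1,
            muhat3_card=trajs["card"].muhat3,
            muhat3_gaze=trajs["gaze"].muhat3,
            trajectories=trajs,
        )
    if spec.perceptual == "rw":
        vc = rw_filter(experiment.u_card, params["alpha_card"])
        vg = rw_filter(experiment.u_gaze, params["alpha_gaze"])
        pred = lambda v: np.concatenate(([0.5], v[:-1]))
        return PerceptualState(pred(vc), pred(vg), zeros, zeros,
                               {"card": vc, "gaze": vg})
    if spec.perceptual == "k1":
        vc, ac = sutton_k1_filter(experiment.u_card, params["meta_card"])
        vg, ag = sutton_k1_filter(experiment.u_gaze, params["meta_gaze"])
        pred = lambda v: np.concatenate(([0.5], v[:-1]))
        return PerceptualState(pred(vc), pred(vg), zeros, zeros,
                               {"card": (vc, ac), "gaze": (vg, ag)})
    raise ValueError(f"{spec.label} has no perceptual stage")


def gaze_frame_card_prediction(muhat1_blue, gaze_target):
    """Re-express the 'blue wins' prediction as 'the gazed-at card wins'."""
    is_blue = np.asarray(gaze_target) == "blue"
    m = np.asarray(muhat1_blue, dtype=float)
    return np.where(is_blue, m, 1.0 - m)


def combined_belief(muhat1_gaze, muhat1_card_gf, zeta):
    """Precision-weighted combination of social and non-social predictions.

    Precisions are the inverse Bernoulli variances 1/(m(1-m)); zeta scales the
    social precision.  Returns ``(b, w_gaze, w_card)``.
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    mg = np.clip(np.asarray(muhat1_gaze, dtype=float), MUHAT1_CLIP, 1 - MUHAT1_CLIP)
    mc = np.clip(np.asarray(muhat1_card_gf, dtype=float), MUHAT1_CLIP, 1 - MUHAT1_CLIP)
    pi_g = 1.0 / (mg * (1.0 - mg))
    pi_c = 1.0 / (mc * (1.0 - mc))
    w_gaze = zeta * pi_g / (zeta * pi_g + pi_c)
    w_card = 1.0 - w_gaze
    b = w_gaze * mg + w_card * mc
    return b, w_gaze, w_card


def decision_temperature(variant, muhat3_card, muhat3_gaze, beta):
    """Inverse softmax temperature gamma(t) per response variant.

    Variants 1-3 attenuate the participant-specific noise scale beta by the
    predicted log-volatility of both streams, the social stream, or the
    non-social stream; variant 4 is constant.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    mc = np.asarray(muhat3_card, dtype=float)
    mg = np.asarray(muhat3_gaze, dtype=float)
    # saturate the exponent: an astronomically large gamma already means a
    # deterministic choice, and overflow would poison the likelihood with NaNs
    sat = lambda x: np.exp(np.clip(x, -600.0, 600.0))
    if variant == 1:
        return beta * sat(-mc - mg)
    if variant == 2:
        return beta * sat(-mg)
    if variant == 3:
        return beta * sat(-mc)
    if variant == 4:
        if np.ndim(mc) == 0:
            return float(beta)
        return np.full(np.shape(mc), float(beta))
    raise ValueError(f"unknown response variant {variant!r}")


def prob_follow_gaze(b, r_gaze, r_notgaze, gamma, eta):
    """Reward-weighted softmax probability of following the advice.

    Mixes (weight eta) a linear and a logarithmic weighting of the displayed
    rewards into the belief-difference argument of a logistic sigmoid.
    """
    r_gaze = np.asarray(r_gaze, dtype=float)
    r_notgaze = np.asarray(r_notgaze, dtype=float)
    if np.any(r_gaze < 1) or np.any(r_notgaze < 1):
        raise ValueError("rewards must be >= 1 (log weighting)")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    b = np.asarray(b, dtype=float)
    lin = sigmoid(gamma * (r_gaze * b - r_notgaze * (1.0 - b)))
    log = sigmoid(gamma * (np.log(r_gaze) * b - np.log(r_notgaze) * (1.0 - b)))
    return eta * lin + (1.0 - eta) * log


def decision_trajectory(spec: ModelSpec, state: PerceptualState,
                        experiment: ExperimentInput, params: dict) -> DecisionTrajectory:
    """Combined belief, temperature and follow probability per trial."""
    mc_gf = gaze_frame_card_prediction(state.muhat1_card, experiment.gaze_target)
    b, w_gaze, w_card = combined_belief(state.muhat1_gaze, mc_gf, params["zeta"])
    if spec.response == 4:
        gamma = np.full(experiment.n_trials, float(params["beta"]))
    else:
        gamma = decision_temperature(
            spec.response, state.muhat3_card, state.muhat3_gaze, params["beta"]
        )
    prob = prob_follow_gaze(
        b, experiment.r_gaze, experiment.r_notgaze, gamma, params["eta"]
    )
    return DecisionTrajectory(
        mu1hat_card_gf=mc_gf,
        mu1hat_gaze=np.clip(state.muhat1_gaze, MUHAT1_CLIP, 1 - MUHAT1_CLIP),
        w_gaze=w_gaze,
        w_card=w_card,
        b=b,
        gamma=np.broadcast_to(np.asarray(gamma, dtype=float), b.shape).copy(),
        prob_gaze=prob,
    )


def wsls_follow_prob(experiment: ExperimentInput, responses: ResponseRecord,
                     epsilon: float) -> np.ndarray:
    """Win-stay-lose-shift follow probabilities conditioned on observed history.

    The intended card on trial t is the previously chosen card after a win and
    the other card after a loss, executed with error probability ``epsilon``;
    the result is mapped into the gaze frame.  Trial 1 (and any trial whose
    predecessor is missing) gets probability 0.5.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    n = experiment.n_trials
    p = np.full(n, 0.5)
    for t in range(1, n):
        if responses.missing[t - 1]:
            continue
        prev = responses.chosen_card[t - 1]
        if responses.rewarded[t - 1] == 1:
            intended = prev
        else:
            intended = "green" if prev == "blue" else "blue"
        p_stay = 1.0 - epsilon
        p[t] = p_stay if intended == experiment.gaze_target[t] else epsilon
    return p


def follow_probabilities(spec: ModelSpec, experiment: ExperimentInput,
                         params: dict, responses: ResponseRecord | None = None):
    """Per-trial p(y=1) for any model; returns ``(prob, info)``."""
    if spec.response == "random":
        bias = params["bias"]
        if not 0.0 < bias < 1.0:
            raise ValueError("bias must lie in (0, 1)")
        return np.full(experiment.n_trials, float(bias)), {}
    if spec.response == "wsls":
        if responses is None:
            raise ValueError("WSLS likelihood requires observed responses")
        return wsls_follow_prob(experiment, responses, params["epsilon"]), {}
    state = run_perceptual(spec, experiment, params)
    decision = decision_trajectory(spec, state, experiment, params)
    return decision.prob_gaze, {"perceptual": state, "decision": decision}


def likelihood_series(spec: ModelSpec, experiment: ExperimentInput,
                      responses: ResponseRecord, params: dict):
    """Per-trial probability of the observed response and the total log-likelihood.

    Probabilities are clipped to [1e-8, 1-1e-8]; the number of clipped observed
    trials is returned so callers can flag near-deterministic fits.  Missing
    trials are excluded from the sum.
    """
    prob, info = follow_probabilities(spec, experiment, params, responses)
    clipped = np.clip(prob, PROB_CLIP, 1.0 - PROB_CLIP)
    n_clipped = int(np.sum((prob != clipped) & responses.observed))
    y = responses.y.astype(float)
    per_trial = np.where(y == 1, clipped, 1.0 - clipped)
    loglik = float(np.sum(np.log(per_trial[responses.observed])))
    return per_trial, loglik, n_clipped, info


def simulate_agent(experiment: ExperimentInput, params: dict, spec: ModelSpec,
                   seed: int):
    """Simulate one agent's responses; a pure function of (inputs, params, seed).

    Returns ``(ResponseRecord, info)`` where ``info`` carries the perceptual
    state and decision trajectory for learning models.
    """
    rng = np.random.default_rng(seed)
    n = experiment.n_trials
    if spec.response == "wsls":
        # sequential: each choice conditions on the agent's own last outcome
        eps = params["epsilon"]
        if not 0.0 <= eps <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        y = np.zeros(n, dtype=np.int8)
        chosen_prev = None
        rewarded_prev = None
        draws = rng.random(n)
        for t in range(n):
            if chosen_prev is None:
                p = 0.5
            else:
                intended = (chosen_prev if rewarded_prev
                            else ("green" if chosen_prev == "blue" else "blue"))
                p = (1.0 - eps) if intended == experiment.gaze_target[t] else eps
            y[t] = 1 if draws[t] < p else 0
            chosen_prev = (experiment.gaze_target[t] if y[t] == 1
                           else ("green" if experiment.gaze_target[t] == "blue" else "blue"))
            rewarded_prev = chosen_prev == experiment.winning_card[t]
        return responses_from_follow(experiment, y), {}
    prob, info = follow_probabilities(spec, experiment, params)
    y = (rng.random(n) < prob).astype(np.int8)
    return responses_from_follow(experiment, y), info
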