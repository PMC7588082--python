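"""Straight-line reference transcriptions of the model equations.

These are deliberately naive scalar implementations, written directly from the
update equations, against which the package's filters and response rules are
checked to 1e-8.  They share no code with the package internals.
"""

import math


def sigmoid(x):
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def hgf_binary_oracle(u, omega2, omega3, kappa=1.0, mu2=0.0, sigma2=1.0,
                      mu3=1.0, sigma3=0.5, clip=1e-8):
    """Three-level binary HGF, variance (sigma) formulation, one dict per trial."""
    out = []
    for uk in u:
        # predictions
        muhat2 = mu2
        muhat1 = sigmoid(muhat2)
        muhat1 = min(max(muhat1, clip), 1.0 - clip)
        v2 = math.exp(kappa * mu3 + omega2)
        sigmahat2 = sigma2 + v2
        muhat3 = mu3
        sigmahat3 = sigma3 + math.exp(omega3)
        # level-1 update
        da1 = uk - muhat1
        # level-2 update
        pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
        sigma2_new = 1.0 / pi2
        mu2_new = muhat2 + sigma2_new * da1
        # volatility prediction error and level-3 update
        da2 = (sigma2_new + (mu2_new - muhat2) ** 2) / sigmahat2 - 1.0
        w2 = v2 / sigmahat2
        pi3 = 1.0 / sigmahat3 + 0.5 * kappa**2 * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
        sigma3_new = 1.0 / pi3
        mu3_new = muhat3 + 0.5 * sigma3_new * kappa * w2 * da2
        mu2, sigma2, mu3, sigma3 = mu2_new, sigma2_new, mu3_new, sigma3_new
        out.append(
            dict(
                muhat1=muhat1,
                da1=da1,
                muhat2=muhat2,
                pihat2=1.0 / sigmahat2,
                mu2=mu2,
                pi2=1.0 / sigma2,
                da2=da2,
                muhat3=muhat3,
                mu3=mu3,
                pi3=1.0 / sigma3,
                psi2=sigma2,
                qpsi2=sigma2 * sigmoid(mu2) * (1.0 - sigmoid(mu2)),
                psi3=(1.0 / sigmahat2) / (1.0 / sigma3),
            )
        )
    return out


def sutton_k1_oracle(u, meta_rate, alpha0=0.1):
    """Sutton K1 delta rule with multiplicative gain adaptation."""
    v, log_gain, h = 0.5, math.log(alpha0), 0.0
    out = []
    for uk in u:
        da = uk - v
        log_gain += meta_rate * da * h
        alpha = min(1.0, math.exp(log_gain))
        v = v + alpha * da
        h = h * max(0.0, 1.0 - alpha) + alpha * da
        out.append((v, alpha))
    return out


def rw_oracle(u, alpha, v0=0.5):
    v, out = v0, []
    for uk in u:
        v = v + alpha * (uk - v)
        out.append(v)
    return out


def response_prob_oracle(mu1hat_gaze, mu1hat_card_gf, zeta, beta, eta,
                         muhat3_card, muhat3_gaze, r_gaze, r_notgaze, variant):
    """Combined belief -> temperature -> reward-weighted softmax, per trial."""
    pg = 1.0 / (mu1hat_gaze * (1.0 - mu1hat_gaze))
    pc = 1.0 / (mu1hat_card_gf * (1.0 - mu1hat_card_gf))
    wg = zeta * pg / (zeta * pg + pc)
    b = wg * mu1hat_gaze + (1.0 - wg) * mu1hat_card_gf
    if variant == 1:
        gamma = beta * math.exp(-muhat3_card - muhat3_gaze)
    elif variant == 2:
        gamma = beta * math.exp(-muhat3_gaze)
    elif variant == 3:
        gamma = beta * math.exp(-muhat3_card)
    else:
        gamma = beta
    lin = sigmoid(gamma * (r_gaze * b - r_notgaze * (1.0 - b)))
    log = sigmoid(gamma * (math.log(r_gaze) * b - math.log(r_notgaze) * (1.0 - b)))
    return eta * lin + (1.0 - eta) * log
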