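"""Canonical synthetic cohorts used by the validation analyses.

Three kinds of study condition are bundled here so analyses, tests and
reproduction scripts all draw the same populations:

* ``priors_dispersion_group`` -- parameters drawn from the default estimation
  priors; used for parameter recovery.
* ``model_recovery_group`` -- moderately dispersed, behaviorally engaged
  agents around conventional parameter values (decision-noise scale centred
  at log beta = 2, a realistic engaged-agent magnitude); used to check that
  group-level model selection identifies the generating model.
* ``two_group_cohort`` -- a high-social-weighting ("BPD-like", elevated zeta
  and volatility sensitivity) versus a low-social-weighting ("HC-like")
  group; used for the group-by-cue behavioral contrast.
* ``REFERENCE_POSTERIOR`` -- a representative single-subject posterior
  (estimation space) used where a fixed, behaviorally plausible parameter set
  is needed, e.g. the lagged-regression cohort.
"""

from __future__ import annotations

from .inversion import DEFAULT_PRIORS
from .response import ModelSpec
from .task import CohortSpec, GroupSpec

#: Representative single-subject posterior, estimation space.
REFERENCE_POSTERIOR = {
    "omega2_card": -1.46,
    "omega2_gaze": -3.58,
    "omega3_card": -6.02,
    "omega3_gaze": -6.07,
    "zeta": -2.02,
    "beta": 2.21,
    "eta": 0.21,
}

#: Estimation-space means for the model-recovery cohorts.
MODEL_RECOVERY_MEANS = {
    "omega2_card": -3.0, "omega2_gaze": -3.0,
    "omega3_card": -6.0, "omega3_gaze": -6.0,
    "zeta": 0.0, "beta": 2.0, "eta": 0.0,
    "alpha_card": 0.0, "alpha_gaze": 0.0,
    "meta_card": 0.0, "meta_gaze": 0.0,
    "epsilon": -2.0, "bias": 0.0,
}
MODEL_RECOVERY_SD = 0.5


def priors_dispersion_group(spec: ModelSpec, n_subjects: int,
                            label: str = "cohort") -> GroupSpec:
    """Group whose generating distribution equals the estimation priors."""
    params = {
        name: (DEFAULT_PRIORS[name].mean, DEFAULT_PRIORS[name].sd)
        for name in spec.free_params
    }
    return GroupSpec(label, n_subjects, params, spec)


def model_recovery_group(spec: ModelSpec, n_subjects: int,
                         label: str | None = None) -> GroupSpec:
    params = {
        name: (MODEL_RECOVERY_MEANS[name], MODEL_RECOVERY_SD)
        for name in spec.free_params
    }
    return GroupSpec(label or spec.label, n_subjects, params, spec)


def two_group_cohort(n_per_group: int = 15, sd: float = 0.3) -> CohortSpec:
    """High- vs low-social-weighting groups sharing the perceptual profile."""
    spec = ModelSpec("hgf", 1)
    base = {
        "omega2_card": (-3.0, sd), "omega2_gaze": (-3.0, sd),
        "omega3_card": (-6.0, sd), "omega3_gaze": (-6.0, sd),
        "beta": (2.0, sd), "eta": (0.0, sd),
    }
    high = GroupSpec("high_zeta", n_per_group, dict(base, zeta=(2.0, sd)), spec)
    low = GroupSpec("low_zeta", n_per_group, dict(base, zeta=(-2.0, sd)), spec)
    return CohortSpec(groups=[high, low])


def reference_cohort(n_subjects: int, sd: float = 0.3) -> CohortSpec:
    """Agents dispersed around the representative posterior."""
    spec = ModelSpec("hgf", 1)
    params = {name: (mean, sd) for name, mean in REFERENCE_POSTERIOR.items()}
    return CohortSpec(groups=[GroupSpec("reference", n_subjects, params, spec)])
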