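"""Task schedules, synthetic experiments and trial tables.

The task is a 120-trial probabilistic reward learning game: on each trial the
participant chooses between a blue and a green card, one of which wins, while an
on-screen face gazes at one of the cards.  Two independent binary probability
schedules govern (i) the probability that the blue card wins and (ii) the
probability that the gaze points at the winning card.  Both schedules alternate
between stable and volatile phases.

Trial indexing is 1-based in files and documentation ("trials 1-60"); internal
arrays are 0-based numpy arrays of length ``n_trials``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONGRUENT_FIRST = "congruent_first"
INCONGRUENT_FIRST = "incongruent_first"

STABLE = "stable"
VOLATILE = "volatile"

#: Canonical probability blocks, 1-based inclusive trial ranges.
CANONICAL_CARD_BLOCKS = [
    (1, 60, 0.73),
    (61, 80, 0.27),
    (81, 100, 0.73),
    (101, 120, 0.27),
]
CANONICAL_GAZE_BLOCKS = [
    (1, 30, 0.73),
    (31, 40, 0.27),
    (41, 50, 0.73),
    (51, 60, 0.27),
    (61, 70, 0.73),
    (71, 120, 0.27),
]
CANONICAL_CARD_PHASES = [(1, 60, STABLE), (61, 120, VOLATILE)]
CANONICAL_GAZE_PHASES = [(1, 30, STABLE), (31, 70, VOLATILE), (71, 120, STABLE)]

TRIAL_TABLE_COLUMNS = [
    "trial",
    "winning_card",
    "u_card",
    "u_gaze",
    "gaze_target",
    "reward_blue",
    "reward_green",
    "y",
    "chosen_card",
    "rewarded",
    "missing",
]


class ScheduleConfigError(ValueError):
    """Raised for blocks that do not tile the trial range, or bad probabilities."""


def _check_blocks(blocks, n_trials, what, value_check):
    prev_end = 0
    for start, end, value in blocks:
        if start != prev_end + 1 or end < start:
            raise ScheduleConfigError(
                f"{what} blocks must tile 1..{n_trials} without gaps or overlaps; "
                f"offending range ({start}, {end}) after trial {prev_end}"
            )
        value_check(value, start, end)
        prev_end = end
    if prev_end != n_trials:
        raise ScheduleConfigError(
            f"{what} blocks end at trial {prev_end}, expected {n_trials}"
        )


@dataclass(frozen=True)
class ScheduleConfig:
    """Configuration of the two per-trial probability schedules.

    Blocks are ``(start, end, value)`` with 1-based inclusive trial ranges that
    must tile ``1..n_trials``.  ``variant`` flips the gaze schedule pointwise:
    under ``incongruent_first`` the gaze probabilities become ``1 - p``.
    """

    n_trials: int = 120
    card_blocks: list = field(default_factory=lambda: list(CANONICAL_CARD_BLOCKS))
    gaze_blocks: list = field(default_factory=lambda: list(CANONICAL_GAZE_BLOCKS))
    card_phases: list = field(default_factory=lambda: list(CANONICAL_CARD_PHASES))
    gaze_phases: list = field(default_factory=lambda: list(CANONICAL_GAZE_PHASES))
    variant: str = CONGRUENT_FIRST
    reward_range: tuple = (1, 9)

    def validate(self) -> None:
        if self.n_trials < 1:
            raise ScheduleConfigError("n_trials must be >= 1")
        if self.variant not in (CONGRUENT_FIRST, INCONGRUENT_FIRST):
            raise ScheduleConfigError(f"unknown variant {self.variant!r}")
        lo, hi = self.reward_range
        if not (1 <= lo <= hi):
            raise ScheduleConfigError("reward_range must satisfy 1 <= lo <= hi")

        def prob_check(p, start, end):
            if not 0.0 <= p <= 1.0:
                raise ScheduleConfigError(
                    f"probability {p} outside [0, 1] in block ({start}, {end})"
                )

        def phase_check(label, start, end):
            if label not in (STABLE, VOLATILE):
                raise ScheduleConfigError(
                    f"unknown phase label {label!r} in block ({start}, {end})"
                )

        _check_blocks(self.card_blocks, self.n_trials, "card", prob_check)
        _check_blocks(self.gaze_blocks, self.n_trials, "gaze", prob_check)
        _check_blocks(self.card_phases, self.n_trials, "card phase", phase_check)
        _check_blocks(self.gaze_phases, self.n_trials, "gaze phase", phase_check)


def _expand(blocks, n_trials, dtype=float):
    out = np.empty(n_trials, dtype=object if dtype is str else float)
    for start, end, value in blocks:
        out[start - 1 : end] = value
    return out if dtype is str else out.astype(float)


@dataclass(frozen=True)
class TaskSchedule:
    """Per-trial ground-truth probabilities and phase labels for both streams."""

    p_card: np.ndarray
    p_gaze: np.ndarray
    phase_card: np.ndarray
    phase_gaze: np.ndarray
    variant: str
    reward_range: tuple = (1, 9)

    @property
    def n_trials(self) -> int:
        return len(self.p_card)


def build_schedule(config: ScheduleConfig | None = None, *, variant: str | None = None) -> TaskSchedule:
    """Expand a :class:`ScheduleConfig` into per-trial series.

    With no config, builds the canonical 120-trial schedule; ``variant``
    selects the congruent-first (gaze 73% accurate on trials 1-30) or
    incongruent-first (27%) counterbalancing.
    """
    if config is None:
        config = ScheduleConfig(variant=variant or CONGRUENT_FIRST)
    elif variant is not None:
        config = replace(config, variant=variant)
    config.validate()
    p_card = _expand(config.card_blocks, config.n_trials)
    p_gaze = _expand(config.gaze_blocks, config.n_trials)
    if config.variant == INCONGRUENT_FIRST:
        p_gaze = 1.0 - p_gaze
    return TaskSchedule(
        p_card=p_card,
        p_gaze=p_gaze,
        phase_card=_expand(config.card_phases, config.n_trials, dtype=str),
        phase_gaze=_expand(config.gaze_phases, config.n_trials, dtype=str),
        variant=config.variant,
        reward_range=config.reward_range,
    )


def count_contingency_changes(schedule: TaskSchedule, stream: str) -> int:
    """Number of trials (from trial 2 on) where the stream's probability changes."""
    if stream == "card":
        p = schedule.p_card
    elif stream == "gaze":
        p = schedule.p_gaze
    else:
        raise ValueError(f"unknown stream {stream!r}; expected 'card' or 'gaze'")
    return int(np.sum(p[1:] != p[:-1]))


@dataclass(frozen=True)
class ExperimentInput:
    """Realized binary outcomes, gaze targets and reward values for one run.

    ``u_card`` is 1 when blue wins, ``u_gaze`` is 1 when the gaze points at the
    winning card.  Rewards are the points printed on each card (independent of
    the winning probabilities).
    """

    winning_card: np.ndarray   # "blue"/"green"
    u_card: np.ndarray         # {0,1}
    u_gaze: np.ndarray         # {0,1}
    gaze_target: np.ndarray    # "blue"/"green"
    reward_blue: np.ndarray
    reward_green: np.ndarray
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.u_card)

    @property
    def gaze_is_blue(self) -> np.ndarray:
        return self.gaze_target == "blue"

    @property
    def r_gaze(self) -> np.ndarray:
        """Reward on the card the gaze points at."""
        return np.where(self.gaze_is_blue, self.reward_blue, self.reward_green)

    @property
    def r_notgaze(self) -> np.ndarray:
        return np.where(self.gaze_is_blue, self.reward_green, self.reward_blue)


@dataclass(frozen=True)
class ResponseRecord:
    """One subject's responses in the gaze frame (y = 1 means advice followed)."""

    y: np.ndarray
    chosen_card: np.ndarray
    rewarded: np.ndarray
    missing: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.y)

    @property
    def observed(self) -> np.ndarray:
        return ~self.missing


def generate_experiment(schedule: TaskSchedule, seed: int) -> ExperimentInput:
    """Sample one experiment from a schedule; a pure function of (schedule, seed)."""
    rng = np.random.default_rng(seed)
    n = schedule.n_trials
    u_card = (rng.random(n) < schedule.p_card).astype(np.int8)
    u_gaze = (rng.random(n) < schedule.p_gaze).astype(np.int8)
    lo, hi = schedule.reward_range
    reward_blue = rng.integers(lo, hi + 1, size=n)
    reward_green = rng.integers(lo, hi + 1, size=n)
    winning_card = np.where(u_card == 1, "blue", "green")
    losing_card = np.where(u_card == 1, "green", "blue")
    gaze_target = np.where(u_gaze == 1, winning_card, losing_card)
    return ExperimentInput(
        winning_card=winning_card,
        u_card=u_card,
        u_gaze=u_gaze,
        gaze_target=gaze_target,
        reward_blue=reward_blue,
        reward_green=reward_green,
        seed=int(seed),
    )


def responses_from_follow(experiment: ExperimentInput, y: np.ndarray,
                          missing: np.ndarray | None = None) -> ResponseRecord:
    """Derive chosen-card and reward fields from follow/not-follow choices."""
    y = np.asarray(y, dtype=np.int8)
    other = np.where(experiment.gaze_is_blue, "green", "blue")
    chosen = np.where(y == 1, experiment.gaze_target, other)
    rewarded = (chosen == experiment.winning_card).astype(np.int8)
    if missing is None:
        missing = np.zeros(len(y), dtype=bool)
    return ResponseRecord(y=y, chosen_card=chosen, rewarded=rewarded,
                          missing=np.asarray(missing, dtype=bool))


# ---------------------------------------------------------------------------
# Cohorts


@dataclass(frozen=True)
class GroupSpec:
    """One synthetic group: parameter distribution in estimation space.

    ``params`` maps parameter names to ``(mean, sd)`` in the space the
    parameter is estimated in (native, log or logit -- see
    :mod:`socialhgf.inversion`).
    """

    label: str
    n_subjects: int
    params: dict
    model: "object"  # ModelSpec; kept loose to avoid an import cycle

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ScheduleConfigError(f"group {self.label!r}: n_subjects must be >= 1")
        for name, (mean, sd) in self.params.items():
            if sd < 0:
                raise ScheduleConfigError(
                    f"group {self.label!r}: negative SD for parameter {name!r}"
                )


@dataclass(frozen=True)
class CohortSpec:
    groups: list
    frac_congruent_first: float = 0.5
    config: ScheduleConfig | None = None

    def validate(self) -> None:
        for g in self.groups:
            g.validate()
        if not 0.0 <= self.frac_congruent_first <= 1.0:
            raise ScheduleConfigError("frac_congruent_first must lie in [0, 1]")


@dataclass(frozen=True)
class SimulatedSubject:
    """One synthetic subject: experiment, generating parameters and behavior."""

    group: str
    schedule: TaskSchedule
    experiment: ExperimentInput
    model: "object"
    params_est: dict     # generating values in estimation space
    params_native: dict  # same values mapped to native space
    responses: ResponseRecord


def generate_cohort(spec: CohortSpec, seed: int) -> list:
    """Simulate a group-structured cohort of agents.

    Per subject, parameters are drawn from the group's Gaussian distribution in
    estimation space, transformed to native space, and an agent is simulated on
    a freshly sampled experiment.  Fully deterministic given ``seed``.
    """
    from .inversion import to_native
    from .perceptual import FilterRejection
    from .response import simulate_agent

    spec.validate()
    rng = np.random.default_rng(seed)
    subjects = []
    for group in spec.groups:
        for _ in range(group.n_subjects):
            variant = (
                CONGRUENT_FIRST
                if rng.random() < spec.frac_congruent_first
                else INCONGRUENT_FIRST
            )
            schedule = build_schedule(spec.config, variant=variant)
            experiment = generate_experiment(schedule, int(rng.integers(2**31)))
            # redraw parameter sets whose belief trajectories are invalid
            # (truncates the generating distribution to the filter's domain)
            for _attempt in range(100):
                params_est = {
                    name: mean + sd * rng.standard_normal()
                    for name, (mean, sd) in group.params.items()
                }
                params_native = to_native(params_est, group.model)
                try:
                    responses, _ = simulate_agent(
                        experiment, params_native, group.model,
                        seed=int(rng.integers(2**31)),
                    )
                    break
                except FilterRejection:
                    continue
            else:
                raise RuntimeError(
                    f"group {group.label!r}: no valid parameter draw in 100 attempts"
                )
            subjects.append(
                SimulatedSubject(
                    group=group.label,
                    schedule=schedule,
                    experiment=experiment,
                    model=group.model,
                    params_est=params_est,
                    params_native=params_native,
                    responses=responses,
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# Trial tables


class TrialTableError(ValueError):
    pass


def trial_table(experiment: ExperimentInput, responses: ResponseRecord) -> pd.DataFrame:
    n = experiment.n_trials
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "winning_card": experiment.winning_card,
            "u_card": experiment.u_card.astype(int),
            "u_gaze": experiment.u_gaze.astype(int),
            "gaze_target": experiment.gaze_target,
            "reward_blue": experiment.reward_blue.astype(int),
            "reward_green": experiment.reward_green.astype(int),
            "y": responses.y.astype(int),
            "chosen_card": responses.chosen_card,
            "rewarded": responses.rewarded.astype(int),
            "missing": responses.missing.astype(int),
        }
    )


def write_trial_table(path, experiment: ExperimentInput, responses: ResponseRecord) -> None:
    trial_table(experiment, responses).to_csv(path, index=False)


def read_trial_table(path):
    """Read a trial-table CSV back into (ExperimentInput, ResponseRecord).

    Raises :class:`TrialTableError` naming any absent mandatory column, and for
    non-binary entries in the binary columns.
    """
    df = pd.read_csv(path)
    for col in TRIAL_TABLE_COLUMNS:
        if col not in df.columns:
            raise TrialTableError(f"trial table missing mandatory column {col!r}")
    for col in ("u_card", "u_gaze", "y", "rewarded", "missing"):
        values = df[col].to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise TrialTableError(f"column {col!r} contains non-binary values")
    experiment = ExperimentInput(
        winning_card=df["winning_card"].to_numpy(dtype=object),
        u_card=df["u_card"].to_numpy(dtype=np.int8),
        u_gaze=df["u_gaze"].to_numpy(dtype=np.int8),
        gaze_target=df["gaze_target"].to_numpy(dtype=object),
        reward_blue=df["reward_blue"].to_numpy(dtype=np.int64),
        reward_green=df["reward_green"].to_numpy(dtype=np.int64),
        seed=-1,
    )
    responses = ResponseRecord(
        y=df["y"].to_numpy(dtype=np.int8),
        chosen_card=df["chosen_card"].to_numpy(dtype=object),
        rewarded=df["rewarded"].to_numpy(dtype=np.int8),
        missing=df["missing"].to_numpy(dtype=bool),
    )
    return experiment, responses
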