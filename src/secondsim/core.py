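"""Single-agent update rules of the SECONDS play model.

SECONDS (Socio-Emotional CONcern DynamicS) describes each member of a playing
dyad by five coupled variables updated in discrete time (one step = 4 s by
default):

* concerns -- a preference pair (autonomy ``c_self`` vs relatedness
  ``c_other``) that always sums to one,
* concern realization -- an appraisal of how well the session so far matches
  those concerns, which generates compensatory drives,
* play behavior -- self- or other-directed,
* emotional expression -- negative / neutral / positive,
* memory -- the accumulated count of joint-play steps.

Only play behavior and emotional expression are observable to the partner;
concerns, realization and memory are private.  The emergent joint outcome is
``z_t = AND(child other-directed, parent other-directed)``.

The qualitative mechanisms (continuity, symmetry, drives, appraisals, self-
and social reinforcement) are realized here with minimal additive forms; each
mechanism carries one weight ``a1``..``a9`` in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "Behavior",
    "DriveDirection",
    "ConcernPair",
    "Realization",
    "Memory",
    "AgentParams",
    "AgentState",
    "joint_outcome",
    "update_memory",
    "concern_realization",
    "update_concerns",
    "choose_behavior",
    "choose_emotion",
    "initial_state",
    "step_agent",
]

#: numeric emotion encoding: negative / neutral / positive
EMOTIONS = (-1, 0, 1)

_SUM_TOL = 1e-9


class Behavior(IntEnum):
    """Direction of play behavior; exactly one per agent per step."""

    SELF_DIRECTED = 0
    OTHER_DIRECTED = 1


class DriveDirection(IntEnum):
    """Direction of the compensatory drive produced by concern realization."""

    TOWARD_SELF = -1
    NONE = 0
    TOWARD_OTHER = 1


@dataclass(frozen=True, slots=True)
class ConcernPair:
    """Autonomy/relatedness preference pair; components sum to one."""

    c_self: float
    c_other: float

    def __post_init__(self) -> None:
        if not (-_SUM_TOL <= self.c_self <= 1 + _SUM_TOL):
            raise ValueError(f"c_self out of [0, 1]: {self.c_self}")
        if not (-_SUM_TOL <= self.c_other <= 1 + _SUM_TOL):
            raise ValueError(f"c_other out of [0, 1]: {self.c_other}")
        if abs(self.c_self + self.c_other - 1.0) > 1e-6:
            raise ValueError(
                f"concerns must sum to 1, got {self.c_self + self.c_other}"
            )

    @classmethod
    def from_other(cls, c_other: float) -> "ConcernPair":
        return cls(c_self=1.0 - c_other, c_other=float(c_other))

    def shifted(self, toward_other: float) -> "ConcernPair":
        """Move mass between the components, clip to [0, 1], renormalize."""
        c_other = min(1.0, max(0.0, self.c_other + toward_other))
        c_self = min(1.0, max(0.0, self.c_self - toward_other))
        total = c_other + c_self
        if total <= 0.0:  # cannot happen for a valid pair, but stay total
            return ConcernPair(0.5, 0.5)
        return ConcernPair(c_self=c_self / total, c_other=c_other / total)


@dataclass(frozen=True, slots=True)
class Realization:
    """Appraisal of concern fulfilment and the drive it generates.

    ``score`` is 0 (before noise) when concerns are exactly met and negative
    otherwise; ``drive_magnitude`` is zero iff ``drive_direction`` is NONE.
    """

    score: float
    drive_direction: DriveDirection
    drive_magnitude: float

    def __post_init__(self) -> None:
        if self.drive_magnitude < 0:
            raise ValueError("drive_magnitude must be >= 0")
        if (self.drive_magnitude == 0.0) != (
            self.drive_direction is DriveDirection.NONE
        ):
            raise ValueError("drive_magnitude == 0 iff drive_direction is NONE")


@dataclass(frozen=True, slots=True)
class Memory:
    """Within-session tally of joint-play outcomes."""

    joint_play_count: int = 0
    steps_elapsed: int = 0

    def __post_init__(self) -> None:
        if self.joint_play_count < 0 or self.steps_elapsed < 0:
            raise ValueError("memory counters must be non-negative")
        if self.joint_play_count > self.steps_elapsed:
            raise ValueError("joint_play_count cannot exceed steps_elapsed")


@dataclass(frozen=True, slots=True)
class AgentParams:
    """Weights and settings of one agent.

    All mechanism weights live in [0, 1]:

    a1  self-reinforcement of concerns by own emotional expressions
    a2  social reinforcement of concerns by the partner's expressions
    a3  realization sensitivity (satiation response of the concerns)
    a4  drive weight in behavior choice
    a5  play continuity (persist in own previous behavior)
    a6  play symmetry (imitate the partner's previous behavior)
    a7  appraisal-to-expression coupling
    a8  emotional continuity
    a9  emotional symmetry (contagion)

    ``baseline`` weights a concern-proportional propensity so that an agent
    with zero drive/continuity/symmetry still acts on its concerns.  ``omega``
    noise (sd ``noise_sd``) enters the realization score and the latent affect;
    the emotion thresholds split latent affect into negative/neutral/positive.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float
    a7: float
    a8: float
    a9: float
    baseline: float
    c_other_initial: float
    noise_sd: float = 0.05
    theta_neg: float = -0.3
    theta_pos: float = 0.3

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "a3", "a4", "a5", "a6", "a7", "a8", "a9", "baseline"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.c_other_initial <= 1.0):
            raise ValueError("c_other_initial must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.theta_neg < self.theta_pos:
            raise ValueError("emotion thresholds must satisfy theta_neg < theta_pos")


@dataclass(frozen=True, slots=True)
class AgentState:
    """One agent's full instantaneous state."""

    concerns: ConcernPair
    realization: Realization
    behavior: Behavior
    emotion: int
    memory: Memory

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"emotion must be one of {EMOTIONS}")


def joint_outcome(child_behavior: Behavior, parent_behavior: Behavior) -> int:
    """Joint play outcome: 1 iff both agents are other-directed."""
    return int(
        child_behavior is Behavior.OTHER_DIRECTED
        and parent_behavior is Behavior.OTHER_DIRECTED
    )


def update_memory(memory: Memory, z: int) -> Memory:
    """Accumulate one joint outcome: count += z, steps += 1."""
    if z not in (0, 1):
        raise ValueError(f"joint outcome must be 0 or 1, got {z!r}")
    return Memory(memory.joint_play_count + z, memory.steps_elapsed + 1)


def concern_realization(
    concerns: ConcernPair,
    memory: Memory,
    params: AgentParams,
    rng: np.random.Generator,
    *,
    a3_pair: tuple[float, float] | None = None,
) -> Realization:
    """Appraise the session so far and derive the compensatory drive.

    The realized relatedness proportion ``r`` is the fraction of steps spent
    in joint play; the discrepancy ``d = c_other - r`` yields a drive toward
    other-directed play when positive and toward self-directed play when
    negative, with magnitude ``a3 * |d|``.  The appraisal score is ``-a3*|d|``
    plus Gaussian noise: zero in expectation when concerns are fully met.

    ``a3_pair = (a3_relatedness, a3_autonomy)`` makes the satiation response
    concern-specific: the drive arising while *relatedness* is in surplus
    (d < 0, push back toward self) is scaled by ``a3_relatedness``, the drive
    while *autonomy* is in surplus (d > 0, push toward other) by
    ``a3_autonomy``.  A low ``a3_relatedness`` therefore means relatedness
    satiates slowly: joint play beyond the concern level is barely corrected.
    Defaults to ``(params.a3, params.a3)``.

    With ``steps_elapsed == 0`` (session start) there is no session history;
    ``r`` is defined as ``c_other`` so no spurious initial drive arises.
    """
    if memory.steps_elapsed == 0:
        r = concerns.c_other
    else:
        r = memory.joint_play_count / memory.steps_elapsed
    d = concerns.c_other - r
    if a3_pair is None:
        a3_rel = a3_aut = params.a3
    else:
        a3_rel, a3_aut = a3_pair
    if d > 0:
        direction = DriveDirection.TOWARD_OTHER
        magnitude = a3_aut * d
    elif d < 0:
        direction = DriveDirection.TOWARD_SELF
        magnitude = a3_rel * -d
    else:
        direction = DriveDirection.NONE
        magnitude = 0.0
    if magnitude == 0.0:
        direction = DriveDirection.NONE
    noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    return Realization(
        score=-magnitude + noise,
        drive_direction=direction,
        drive_magnitude=magnitude,
    )


def update_concerns(
    concerns: ConcernPair,
    own_behavior: Behavior,
    own_emotion: int,
    other_emotion: int,
    params: AgentParams,
) -> ConcernPair:
    """Reinforce the concern matching the current behavior.

    Positive expressions (own: self-reinforcement ``a1``; partner's: social
    reinforcement ``a2``) strengthen the concern associated with the behavior
    being performed; negative expressions weaken it.  The pair is clipped to
    [0, 1] and kept summing to one.
    """
    delta = params.a1 * own_emotion + params.a2 * other_emotion
    if own_behavior is Behavior.OTHER_DIRECTED:
        return concerns.shifted(delta)
    return concerns.shifted(-delta)


def _drive_to_other(realization: Realization) -> float:
    """Signed drive mapped to [0, 1]: 0.5 means no directional pull."""
    signed = realization.drive_magnitude * int(realization.drive_direction)
    return (1.0 + signed) / 2.0


def choose_behavior(
    realization: Realization,
    prev_own: Behavior,
    prev_other: Behavior,
    concerns: ConcernPair,
    params: AgentParams,
    rng: np.random.Generator,
    *,
    a6: float | None = None,
) -> Behavior:
    """Draw the next play behavior from the normalized other-directed propensity.

    The propensity combines drive (a4), continuity in own behavior (a5),
    symmetry with the partner's behavior (a6, overridable per step for
    conditional strategies) and a concern-proportional baseline, normalized by
    the sum of the active weights.  The draw is Bernoulli so that session-level
    outcomes vary continuously across runs.

    With all four weights zero there is no propensity to evaluate and the
    previous behavior persists (frozen dynamics).
    """
    a6_eff = params.a6 if a6 is None else a6
    if not (0.0 <= a6_eff <= 1.0):
        raise ValueError(f"effective a6 must lie in [0, 1], got {a6_eff}")
    denom = params.a4 + params.a5 + a6_eff + params.baseline
    u = rng.random()  # drawn unconditionally: fixed stream layout per step
    if denom == 0.0:
        return prev_own
    num = (
        params.a4 * _drive_to_other(realization)
        + params.a5 * (prev_own is Behavior.OTHER_DIRECTED)
        + a6_eff * (prev_other is Behavior.OTHER_DIRECTED)
        + params.baseline * concerns.c_other
    )
    pi = num / denom
    if not (-1e-12 <= pi <= 1.0 + 1e-12):
        raise ValueError(f"other-directed propensity out of [0, 1]: {pi}")
    return Behavior.OTHER_DIRECTED if u < pi else Behavior.SELF_DIRECTED


def choose_emotion(
    realization: Realization,
    prev_own: int,
    prev_other: int,
    params: AgentParams,
    rng: np.random.Generator,
    *,
    extra_affect: float = 0.0,
) -> int:
    """Draw the next emotional expression from thresholded latent affect.

    Latent affect ``u = a7*score + a8*prev_own + a9*prev_other + extra + noise``
    maps to positive above ``theta_pos``, negative below ``theta_neg`` and
    neutral in between.  ``extra_affect`` is a hook for strategy-level
    encouragement terms.
    """
    noise = rng.normal(0.0, params.noise_sd) if params.noise_sd > 0 else 0.0
    u = (
        params.a7 * realization.score
        + params.a8 * prev_own
        + params.a9 * prev_other
        + extra_affect
        + noise
    )
    if u > params.theta_pos:
        return 1
    if u < params.theta_neg:
        return -1
    return 0


def initial_state(params: AgentParams, rng: np.random.Generator) -> AgentState:
    """Session-start state: behavior drawn from initial concerns, neutral emotion."""
    concerns = ConcernPair.from_other(params.c_other_initial)
    memory = Memory(0, 0)
    realization = concern_realization(concerns, memory, params, rng)
    behavior = (
        Behavior.OTHER_DIRECTED
        if rng.random() < concerns.c_other
        else Behavior.SELF_DIRECTED
    )
    return AgentState(
        concerns=concerns,
        realization=realization,
        behavior=behavior,
        emotion=0,
        memory=memory,
    )


def step_agent(
    state: AgentState,
    other_prev: AgentState,
    z_prev: int,
    params: AgentParams,
    rng: np.random.Generator,
    *,
    a3_pair: tuple[float, float] | None = None,
    a6: float | None = None,
    extra_affect: float = 0.0,
) -> AgentState:
    """Advance one agent by one step.

    Cross-agent inputs are strictly the partner's *previous-step observables*
    (behavior and emotion) plus the previous joint outcome ``z_prev``; the
    partner's concerns, realization and memory never enter.  Order within the
    step: bank ``z_prev`` into memory, appraise (realization), choose behavior,
    choose emotion, update concerns.
    """
    memory = update_memory(state.memory, z_prev)
    realization = concern_realization(
        state.concerns, memory, params, rng, a3_pair=a3_pair
    )
    behavior = choose_behavior(
        realization,
        state.behavior,
        other_prev.behavior,
        state.concerns,
        params,
        rng,
        a6=a6,
    )
    emotion = choose_emotion(
        realization,
        state.emotion,
        other_prev.emotion,
        params,
        rng,
        extra_affect=extra_affect,
    )
    concerns = update_concerns(
        state.concerns, behavior, emotion, other_prev.emotion, params
    )
    return AgentState(
        concerns=concerns,
        realization=realization,
        behavior=behavior,
        emotion=emotion,
        memory=memory,
    )
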