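"""Session-level simulation of a coupled parent-child dyad.

Both agents are updated synchronously: every step uses only the partner's
previous-step observables, so the update order of the two agents within a
step carries no information.  The parent's strategy hooks (scaffolding,
selective symmetry, selective satiation, emotion policy) are applied inside
the loop each step.

A session is fully determined by its seed; batches derive one independent
integer seed per session from the master seed, so per-session results are
order-independent and any session can be re-run in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import (
    Behavior,
    ConcernPair,
    initial_state,
    joint_outcome,
    step_agent,
)
from .strategies import (
    DyadPreset,
    apply_emotion_policy,
    apply_scaffolding,
    effective_a6,
    encouragement_term,
)

__all__ = [
    "SessionConfig",
    "SessionRecord",
    "run_session",
    "run_batch",
    "derive_session_seeds",
    "records_to_frame",
]

#: default session length: 225 four-second steps = 15 minutes
DEFAULT_N_STEPS = 225
DEFAULT_STEP_SECONDS = 4.0


@dataclass(frozen=True, slots=True)
class SessionConfig:
    dyad: DyadPreset
    n_steps: int = DEFAULT_N_STEPS
    step_seconds: float = DEFAULT_STEP_SECONDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.step_seconds <= 0:
            raise ValueError("step_seconds must be > 0")


@dataclass(frozen=True, slots=True)
class SessionRecord:
    """Aligned per-step series of one simulated session."""

    child_behavior: np.ndarray  # uint8, 1 = other-directed
    parent_behavior: np.ndarray
    child_emotion: np.ndarray  # int8 in {-1, 0, 1}
    parent_emotion: np.ndarray
    child_c_other: np.ndarray  # float64
    parent_c_other: np.ndarray
    z: np.ndarray  # uint8 joint outcome
    step_seconds: float
    seed: int
    label: str

    @property
    def n_steps(self) -> int:
        return len(self.z)

    @property
    def final_child_c_other(self) -> float:
        """The child's relatedness concern at the final step (c_other,final)."""
        return float(self.child_c_other[-1])

    def to_frame(self, session: int = 0) -> pd.DataFrame:
        """Long-format view of the session (one row per step)."""
        return pd.DataFrame(
            {
                "session": session,
                "t": np.arange(self.n_steps),
                "child_behavior": np.where(self.child_behavior == 1, "other", "self"),
                "parent_behavior": np.where(self.parent_behavior == 1, "other", "self"),
                "child_emotion": self.child_emotion.astype(int),
                "parent_emotion": self.parent_emotion.astype(int),
                "z": self.z.astype(int),
                "child_c_other": self.child_c_other,
            }
        )


def run_session(config: SessionConfig) -> SessionRecord:
    """Simulate one session; deterministic given ``config.seed``.

    The child and parent draw from a single seeded generator in a fixed
    per-step order (child first), so records are bit-identical across runs.
    """
    rng = np.random.default_rng(config.seed)
    dyad = config.dyad
    strat = dyad.parent_strategy
    policy = strat.emotion_policy
    n = config.n_steps

    child = initial_state(dyad.child, rng)
    parent = initial_state(dyad.parent, rng)

    # Running estimate of the child's relatedness concern from its observable
    # behavior, initialized at the child's (known) initial concern.
    ref_num = dyad.child.c_other_initial
    ref_den = 1.0

    parent = replace(
        parent,
        concerns=_scaffolded(parent.concerns, ref_num / ref_den, strat),
    )

    child_behavior = np.empty(n, dtype=np.uint8)
    parent_behavior = np.empty(n, dtype=np.uint8)
    child_emotion = np.empty(n, dtype=np.int8)
    parent_emotion = np.empty(n, dtype=np.int8)
    child_c = np.empty(n, dtype=np.float64)
    parent_c = np.empty(n, dtype=np.float64)
    z_series = np.empty(n, dtype=np.uint8)

    z = joint_outcome(child.behavior, parent.behavior)
    _record(0, child, parent, z, child_behavior, parent_behavior,
            child_emotion, parent_emotion, child_c, parent_c, z_series)

    for t in range(1, n):
        child_prev, parent_prev = child, parent
        child = step_agent(child_prev, parent_prev, z, dyad.child, rng)
        parent = step_agent(
            parent_prev,
            child_prev,
            z,
            dyad.parent,
            rng,
            a3_pair=strat.satiation_bias,
            a6=effective_a6(strat, child_prev.behavior, dyad.parent.a6),
            extra_affect=encouragement_term(policy, child_prev.behavior),
        )
        expressed = apply_emotion_policy(
            parent.emotion, child_prev.behavior, policy
        )
        # the estimate uses behaviors observed up to the previous step
        ref_num += float(child_prev.behavior is Behavior.OTHER_DIRECTED)
        ref_den += 1.0
        reference = (
            child.concerns.c_other
            if strat.use_true_child_concern
            else ref_num / ref_den
        )
        parent = replace(
            parent,
            emotion=expressed,
            concerns=_scaffolded(parent.concerns, reference, strat),
        )
        z = joint_outcome(child.behavior, parent.behavior)
        _record(t, child, parent, z, child_behavior, parent_behavior,
                child_emotion, parent_emotion, child_c, parent_c, z_series)

    return SessionRecord(
        child_behavior=child_behavior,
        parent_behavior=parent_behavior,
        child_emotion=child_emotion,
        parent_emotion=parent_emotion,
        child_c_other=child_c,
        parent_c_other=parent_c,
        z=z_series,
        step_seconds=config.step_seconds,
        seed=config.seed,
        label=dyad.label,
    )


def _scaffolded(concerns: ConcernPair, reference: float, strat) -> ConcernPair:
    if strat.scaffold_floor is None and strat.scaffold_band is None:
        return concerns
    return apply_scaffolding(concerns, reference, strat)


def _record(t, child, parent, z, cb, pb, ce, pe, cc, pc, zs) -> None:
    cb[t] = int(child.behavior)
    pb[t] = int(parent.behavior)
    ce[t] = child.emotion
    pe[t] = parent.emotion
    cc[t] = child.concerns.c_other
    pc[t] = parent.concerns.c_other
    zs[t] = z


def derive_session_seeds(master_seed: int, n_sessions: int) -> np.ndarray:
    """Independent per-session integer seeds from a master seed (counter-based)."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    return np.random.SeedSequence(master_seed).generate_state(n_sessions)


def run_batch(config: SessionConfig, n_sessions: int) -> list[SessionRecord]:
    """Simulate ``n_sessions`` independent sessions.

    Session ``i`` is exactly ``run_session`` with the i-th derived seed, so
    batches are reproducible and order-independent.
    """
    seeds = derive_session_seeds(config.seed, n_sessions)
    return [
        run_session(replace(config, seed=int(s))) for s in seeds
    ]


def records_to_frame(records: list[SessionRecord]) -> pd.DataFrame:
    """Concatenate session records into one long-format DataFrame."""
    return pd.concat(
        [rec.to_frame(session=i) for i, rec in enumerate(records)],
        ignore_index=True,
    )
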