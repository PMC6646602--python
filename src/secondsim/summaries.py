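"""Observable state classification and per-session summary variables.

Each step of a session is classified into one of four mutually exclusive
observable states from the two play behaviors alone:

* ``together`` -- both other-directed (joint play, z = 1),
* ``alone`` -- both self-directed,
* ``attempt_child`` -- child solicits (other-directed) while the parent plays
  alone,
* ``attempt_parent`` -- the reverse.

Because observational coding registers only *verbalized* initiation attempts,
attempt runs lasting a single step (< 8 s) are assumed unverbalized and are
recoded as ``alone`` before any further analysis (the verbalization filter).

A ``together`` episode immediately preceded by an attempt episode counts, for
its full duration, as a successful initiation by whichever agent attempted
(``success_child`` / ``success_parent``).  The seven per-session summary
variables are the four state proportions, the two success proportions (all as
percentages of session time) and the child's final relatedness concern.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import SessionRecord

__all__ = [
    "State",
    "StateSeries",
    "Episode",
    "SummaryRow",
    "SUMMARY_COLUMNS",
    "classify_states",
    "verbalization_filter",
    "attribute_success",
    "summarize_session",
    "summarize_record",
    "summarize_records",
    "summarize_batch",
    "alone_attempt_regression",
    "RegressionResult",
]


class State(IntEnum):
    TOGETHER = 0
    ALONE = 1
    ATTEMPT_CHILD = 2
    ATTEMPT_PARENT = 3


STATE_NAMES = {
    State.TOGETHER: "together",
    State.ALONE: "alone",
    State.ATTEMPT_CHILD: "attempt_child",
    State.ATTEMPT_PARENT: "attempt_parent",
}

SUMMARY_COLUMNS = (
    "together",
    "alone",
    "attempt_child",
    "attempt_parent",
    "success_child",
    "success_parent",
    "c_final",
)


@dataclass(frozen=True, slots=True)
class StateSeries:
    """Per-step observable state sequence of one session."""

    states: np.ndarray  # int8 array of State values

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        if states.ndim != 1 or len(states) == 0:
            raise ValueError("states must be a non-empty 1-d array")
        if not np.isin(states, [int(s) for s in State]).all():
            raise ValueError("invalid state code in series")
        object.__setattr__(self, "states", states)

    @property
    def n_steps(self) -> int:
        return len(self.states)


@dataclass(frozen=True, slots=True)
class Episode:
    """A maximal run of one state; attribution set for together episodes."""

    state: State
    start_step: int
    duration_steps: int
    attributed_to: str | None = None  # 'child' | 'parent' | None

    def __post_init__(self) -> None:
        if self.duration_steps < 1:
            raise ValueError("episode duration must be >= 1")
        if self.attributed_to not in (None, "child", "parent"):
            raise ValueError("attributed_to must be 'child', 'parent' or None")


@dataclass(frozen=True, slots=True)
class SummaryRow:
    """Seven summary variables of one session (times in % of session)."""

    together: float
    alone: float
    attempt_child: float
    attempt_parent: float
    success_child: float
    success_parent: float
    c_final: float

    def __post_init__(self) -> None:
        pcts = (
            self.together,
            self.alone,
            self.attempt_child,
            self.attempt_parent,
            self.success_child,
            self.success_parent,
        )
        if any(not (0.0 <= v <= 100.0) for v in pcts):
            raise ValueError("summary percentages must lie in [0, 100]")
        if abs(
            self.together + self.alone + self.attempt_child + self.attempt_parent
            - 100.0
        ) > 1e-6:
            raise ValueError("state percentages must sum to 100")
        if self.success_child + self.success_parent > self.together + 1e-9:
            raise ValueError("success time cannot exceed together time")
        if not np.isnan(self.c_final) and not (0.0 <= self.c_final <= 1.0):
            raise ValueError("c_final must lie in [0, 1]")

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SUMMARY_COLUMNS}


def classify_states(record: SessionRecord) -> StateSeries:
    """Map the two behavior series to the four observable states."""
    child = record.child_behavior.astype(bool)
    parent = record.parent_behavior.astype(bool)
    states = np.full(len(child), int(State.ALONE), dtype=np.int8)
    states[child & parent] = int(State.TOGETHER)
    states[child & ~parent] = int(State.ATTEMPT_CHILD)
    states[~child & parent] = int(State.ATTEMPT_PARENT)
    return StateSeries(states)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs as (state, start, length)."""
    boundaries = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(states)]))
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def verbalization_filter(series: StateSeries) -> StateSeries:
    """Recode single-step attempt runs as ``alone``.

    An initiation attempt is assumed to be verbalized (hence observable) only
    when it persists for at least two steps; a lone attempt step leaves the
    observer seeing both members playing alone.
    """
    states = series.states.copy()
    for state, start, length in _runs(series.states):
        if length == 1 and state in (int(State.ATTEMPT_CHILD), int(State.ATTEMPT_PARENT)):
            states[start] = int(State.ALONE)
    return StateSeries(states)


def attribute_success(series: StateSeries) -> list[Episode]:
    """Segment a (filtered) series into episodes and attribute joint play.

    A ``together`` episode immediately preceded by an attempt episode is
    attributed in full to the attempting agent; a together episode preceded by
    ``alone`` (or starting the session) is attributed to neither.
    """
    episodes: list[Episode] = []
    prev_state: int | None = None
    for state, start, length in _runs(series.states):
        attributed = None
        if state == int(State.TOGETHER):
            if prev_state == int(State.ATTEMPT_CHILD):
                attributed = "child"
            elif prev_state == int(State.ATTEMPT_PARENT):
                attributed = "parent"
        episodes.append(
            Episode(
                state=State(state),
                start_step=start,
                duration_steps=length,
                attributed_to=attributed,
            )
        )
        prev_state = state
    return episodes


def summarize_session(series: StateSeries, c_final: float = np.nan) -> SummaryRow:
    """Compute the seven summary variables from a filtered state series."""
    n = series.n_steps
    counts = np.bincount(series.states, minlength=4)
    success = {"child": 0, "parent": 0}
    for ep in attribute_success(series):
        if ep.attributed_to is not None:
            success[ep.attributed_to] += ep.duration_steps
    scale = 100.0 / n
    return SummaryRow(
        together=counts[int(State.TOGETHER)] * scale,
        alone=counts[int(State.ALONE)] * scale,
        attempt_child=counts[int(State.ATTEMPT_CHILD)] * scale,
        attempt_parent=counts[int(State.ATTEMPT_PARENT)] * scale,
        success_child=success["child"] * scale,
        success_parent=success["parent"] * scale,
        c_final=c_final,
    )


def summarize_record(record: SessionRecord) -> SummaryRow:
    """Classify, filter and summarize one simulated session."""
    series = verbalization_filter(classify_states(record))
    return summarize_session(series, c_final=record.final_child_c_other)


def summarize_records(records: list[SessionRecord]) -> pd.DataFrame:
    """One summary row per simulated session."""
    return pd.DataFrame([summarize_record(r).to_dict() for r in records])


def summarize_batch(
    rows: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Medians with bootstrap percentile 95% CIs across sessions.

    Returns a frame indexed by variable with columns ``median``, ``ci_lo``,
    ``ci_hi`` (percentile interval of the bootstrapped median, B = ``n_boot``,
    seeded).
    """
    if len(rows) < 2:
        raise ValueError("batch summaries require at least 2 sessions")
    rng = np.random.default_rng(seed)
    out = {}
    n = len(rows)
    for col in rows.columns:
        values = rows[col].to_numpy(dtype=float)
        meds = np.empty(n_boot)
        chunk = max(1, int(2e6 // max(n, 1)))
        for lo in range(0, n_boot, chunk):
            k = min(chunk, n_boot - lo)
            idx = rng.integers(0, n, size=(k, n))
            meds[lo : lo + k] = np.median(values[idx], axis=1)
        lo_q, hi_q = np.percentile(meds, [2.5, 97.5])
        out[col] = {
            "median": float(np.median(values)),
            "ci_lo": float(lo_q),
            "ci_hi": float(hi_q),
        }
    return pd.DataFrame(out).T[["median", "ci_lo", "ci_hi"]]


@dataclass(frozen=True, slots=True)
class RegressionResult:
    intercept: float
    slope: float
    r_squared: float


def alone_attempt_regression(
    rows: pd.DataFrame, normalize_remaining: bool = False
) -> RegressionResult:
    """OLS of ``attempt_child`` on ``alone`` across sessions.

    More solitary play gives the child more openings to initiate, so the slope
    is expected to be positive.  With ``normalize_remaining=True`` the
    response is expressed as a percentage of the session time remaining after
    ``alone`` (a plotting normalization); by default both variables are
    percentages of total session time.
    """
    if len(rows) < 3:
        raise ValueError("regression requires at least 3 sessions")
    alone = rows["alone"].to_numpy(dtype=float)
    attempt = rows["attempt_child"].to_numpy(dtype=float)
    if normalize_remaining:
        attempt = 100.0 * attempt / (100.0 - alone)
    if np.ptp(alone) == 0.0:
        raise ValueError("zero variance in 'alone'; regression undefined")
    model = sm.OLS(attempt, sm.add_constant(alone)).fit()
    return RegressionResult(
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        r_squared=float(model.rsquared),
    )
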