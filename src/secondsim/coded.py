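"""Event-coded play sessions: CSV I/O, grid resampling, synthetic fixtures.

Observed sessions are coded exhaustively as non-overlapping events
``(onset_s, offset_s, code)`` with codes ``together | alone | attempt_child |
attempt_parent``.  For comparison with simulations they are resampled to the
simulation grid (4-s bins by default) with a majority-overlap rule.

Real coded data of this kind are not publicly deposited, so
:func:`generate_fixtures` provides a synthetic stand-in: a semi-Markov state
sequence generator with geometric episode durations whose long-run occupancy
matches requested target proportions.  Attempt episodes are generated with a
minimum of two steps so fixtures survive the verbalization filter.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .summaries import State, StateSeries

__all__ = [
    "CODES",
    "CodedSession",
    "read_coded_sessions",
    "write_coded_sessions",
    "resample_to_grid",
    "generate_fixtures",
    "summarize_coded",
]

CODES = ("together", "alone", "attempt_child", "attempt_parent")
_CODE_TO_STATE = {
    "together": State.TOGETHER,
    "alone": State.ALONE,
    "attempt_child": State.ATTEMPT_CHILD,
    "attempt_parent": State.ATTEMPT_PARENT,
}
_HEADER = ("session_id", "onset_s", "offset_s", "code")


@dataclass(frozen=True, slots=True)
class CodedSession:
    """One exhaustively coded session: contiguous events covering [0, end]."""

    session_id: str
    events: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError(f"session {self.session_id!r} has no events")
        prev_offset = 0.0
        for onset, offset, code in self.events:
            if code not in CODES:
                raise ValueError(
                    f"session {self.session_id!r}: unknown code {code!r}"
                )
            if offset <= onset:
                raise ValueError(
                    f"session {self.session_id!r}: event [{onset}, {offset}] "
                    "has non-positive duration"
                )
            if abs(onset - prev_offset) > 1e-9:
                raise ValueError(
                    f"session {self.session_id!r}: events must be contiguous; "
                    f"gap or overlap at t={onset}"
                )
            prev_offset = offset
        if abs(self.events[0][0]) > 1e-9:
            raise ValueError(f"session {self.session_id!r} must start at 0")

    @property
    def duration_s(self) -> float:
        return float(self.events[-1][1])


def read_coded_sessions(path: str | Path) -> list[CodedSession]:
    """Read and validate a coded-session CSV.

    Expects the header ``session_id,onset_s,offset_s,code``; events of each
    session must be contiguous (exhaustive, non-overlapping) in file order.
    Violations are reported with the offending line numbers.
    """
    path = Path(path)
    by_session: dict[str, list[tuple[float, float, str, int]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(row for row in fh if not row.startswith("#"))
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if tuple(h.strip() for h in header) != _HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(_HEADER)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            sid, onset_s, offset_s, code = row
            try:
                onset, offset = float(onset_s), float(offset_s)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric onset/offset"
                ) from None
            if code not in CODES:
                raise ValueError(
                    f"{path}:{lineno}: unknown code {code!r}; valid: {', '.join(CODES)}"
                )
            if offset <= onset:
                raise ValueError(f"{path}:{lineno}: offset must exceed onset")
            by_session.setdefault(sid, []).append((onset, offset, code, lineno))
    if not by_session:
        raise ValueError(f"{path}: no events found")

    sessions = []
    for sid, rows in by_session.items():
        prev_offset, prev_line = 0.0, None
        for onset, offset, code, lineno in rows:
            if onset < prev_offset - 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: event overlaps previous event "
                    f"(line {prev_line}) in session {sid!r}"
                )
            if onset > prev_offset + 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: gap before event in session {sid!r} "
                    f"(previous event at line {prev_line} ends at {prev_offset})"
                )
            prev_offset, prev_line = offset, lineno
        sessions.append(
            CodedSession(
                session_id=sid,
                events=tuple((on, off, code) for on, off, code, _ in rows),
            )
        )
    return sessions


def write_coded_sessions(sessions: Sequence[CodedSession], path: str | Path) -> None:
    """Write coded sessions to CSV (inverse of :func:`read_coded_sessions`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for session in sessions:
            for onset, offset, code in session.events:
                writer.writerow(
                    [session.session_id, f"{onset:g}", f"{offset:g}", code]
                )


def resample_to_grid(
    session: CodedSession, step_seconds: float = 4.0
) -> StateSeries:
    """Label each fixed-width bin with the majority-overlap state.

    ``n_steps = floor(duration / step_seconds)``; ties within a bin are broken
    toward the earlier-starting event.
    """
    if step_seconds <= 0:
        raise ValueError("step_seconds must be > 0")
    n_steps = int(session.duration_s // step_seconds)
    if n_steps < 1:
        raise ValueError(
            f"session {session.session_id!r} shorter than one step"
        )
    states = np.empty(n_steps, dtype=np.int8)
    events = session.events
    idx = 0
    for t in range(n_steps):
        lo, hi = t * step_seconds, (t + 1) * step_seconds
        while idx < len(events) - 1 and events[idx][1] <= lo + 1e-12:
            idx += 1
        best_code, best_overlap = None, 0.0
        j = idx
        while j < len(events) and events[j][0] < hi - 1e-12:
            onset, offset, code = events[j]
            overlap = min(offset, hi) - max(onset, lo)
            # strict inequality: ties go to the earlier-starting event
            if overlap > best_overlap + 1e-12:
                best_code, best_overlap = code, overlap
            j += 1
        states[t] = int(_CODE_TO_STATE[best_code])
    return StateSeries(states)


def summarize_coded(
    sessions: Sequence[CodedSession],
    step_seconds: float = 4.0,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Resample, optionally filter, and summarize coded sessions.

    Returns the standard per-session summary table; ``c_final`` is NaN since
    concerns are not observable.
    """
    from .summaries import summarize_session, verbalization_filter

    rows = []
    for session in sessions:
        series = resample_to_grid(session, step_seconds)
        if apply_filter:
            series = verbalization_filter(series)
        rows.append(summarize_session(series).to_dict())
    return pd.DataFrame(rows)


def _normalize_targets(target_proportions) -> np.ndarray:
    if isinstance(target_proportions, Mapping):
        targets = np.array([target_proportions[c] for c in CODES], dtype=float)
    else:
        targets = np.asarray(target_proportions, dtype=float)
    if targets.shape != (4,):
        raise ValueError("need one target proportion per state (4)")
    if (targets <= 0).any():
        raise ValueError(
            "all four target proportions must be positive; drop a state by "
            "making its target small, not zero"
        )
    if abs(targets.sum() - 1.0) > 1e-6:
        raise ValueError("target proportions must sum to 1")
    return targets / targets.sum()


def _normalize_means(mean_episode_steps) -> np.ndarray:
    if isinstance(mean_episode_steps, Mapping):
        means = np.array([mean_episode_steps[c] for c in CODES], dtype=float)
    else:
        means = np.broadcast_to(
            np.asarray(mean_episode_steps, dtype=float), (4,)
        ).copy()
    if (means < 1).any():
        raise ValueError("mean episode lengths must be >= 1 step")
    if (means[2:] < 2).any():
        raise ValueError(
            "attempt episodes must average >= 2 steps (the verbalization "
            "filter removes single-step attempts)"
        )
    return means


def _transition_weights(targets: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Visit weights whose embedded chain yields the target occupancy.

    The occupancy of a semi-Markov chain is the embedded chain's stationary
    visit distribution weighted by mean durations; a small fixed-point
    iteration corrects for the no-self-transition constraint.
    """
    w = targets / means
    for _ in range(200):
        P = np.tile(w, (4, 1))
        np.fill_diagonal(P, 0.0)
        P /= P.sum(axis=1, keepdims=True)
        # stationary distribution of the embedded chain
        A = np.vstack([P.T - np.eye(4), np.ones(4)])
        b = np.concatenate([np.zeros(4), [1.0]])
        nu = np.linalg.lstsq(A, b, rcond=None)[0]
        occ = nu * means
        occ /= occ.sum()
        if np.max(np.abs(occ - targets)) < 1e-10:
            break
        w *= targets / np.maximum(occ, 1e-12)
        w /= w.sum()
    return w


def generate_fixtures(
    n_sessions: int,
    target_proportions=(0.40, 0.30, 0.10, 0.20),
    mean_episode_steps=(5.0, 4.0, 2.5, 3.0),
    seed: int = 0,
    n_steps: int = 225,
    step_seconds: float = 4.0,
) -> list[CodedSession]:
    """Synthetic event-coded sessions emulating observed play corpora.

    Semi-Markov generation: episode durations are geometric with the given
    per-state means (attempt durations shifted to a minimum of two steps),
    and next-state transitions are weighted so the long-run occupancy of the
    four states matches ``target_proportions``.  Deterministic given ``seed``.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    targets = _normalize_targets(target_proportions)
    means = _normalize_means(mean_episode_steps)
    w = _transition_weights(targets, means)
    rng = np.random.default_rng(seed)

    sessions = []
    for i in range(n_sessions):
        events: list[tuple[float, float, str]] = []
        t = 0
        state = int(rng.choice(4, p=targets))
        while t < n_steps:
            mean = means[state]
            if state >= 2:  # attempts: minimum two steps
                extra_mean = mean - 2.0
                dur = 2 + (
                    rng.geometric(1.0 / (extra_mean + 1.0)) - 1
                    if extra_mean > 0
                    else 0
                )
            else:
                dur = int(rng.geometric(min(1.0, 1.0 / mean)))
            dur = min(dur, n_steps - t)
            events.append(
                (t * step_seconds, (t + dur) * step_seconds, CODES[state])
            )
            t += dur
            probs = w.copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(4, p=probs))
        sessions.append(
            CodedSession(session_id=f"fixture_{i:03d}", events=tuple(events))
        )
    return sessions
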