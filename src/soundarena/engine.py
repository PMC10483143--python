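"""Closed-loop soundscape controller.

Turns a timestamped centroid stream into the tone-command stream the speaker
would have played.  During the habituation phase no tone is delivered
regardless of position; afterwards the tone follows the role of the occupied
quadrant, with the silent role (Q1) mapping to silence.

A quadrant change only takes effect after DEBOUNCE_FRAMES consecutive frames
in the new quadrant (100 ms at 20 fps), suppressing artifactual tone flicker
from centroid noise at the virtual boundaries.  Tracking dropouts hold the
last confirmed quadrant: a real-time system cannot act on absent data.
Actuation latency is modeled as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .arena import (
    ArenaSpec,
    PhaseSchedule,
    SILENCE,
    SoundscapeAssignment,
    ToneSpec,
    assign_quadrant,
)
from .errors import SequencingError, TruncationError

#: consecutive frames required in a new quadrant before the tone switches
DEBOUNCE_FRAMES = 2


@dataclass(frozen=True)
class ToneCommand:
    """One speaker command: what plays from ``time_s`` on, and why.

    ``cause`` is the role label of the (debounce-confirmed) occupied quadrant;
    during habituation the tone is silence whatever the cause.
    """

    time_s: float
    tone: ToneSpec
    cause: str


class EngineState:
    """Mutable per-session controller state (confirmed quadrant + debounce)."""

    __slots__ = (
        "confirmed_role",
        "candidate_role",
        "candidate_count",
        "last_time",
        "last_tone",
        "last_cause",
        "started",
        "_inv",
    )

    def __init__(self) -> None:
        self.confirmed_role: Optional[str] = None
        self.candidate_role: Optional[str] = None
        self.candidate_count = 0
        self.last_time = -float("inf")
        self.last_tone: Optional[ToneSpec] = None
        self.last_cause: Optional[str] = None
        self.started = False
        self._inv: Optional[dict[str, str]] = None  # cached physical->role


def step(
    position: Optional[tuple[float, float]],
    time_s: float,
    schedule: PhaseSchedule,
    assignment: SoundscapeAssignment,
    state: EngineState,
    arena=None,
) -> tuple[Optional[ToneCommand], EngineState]:
    """Advance the controller by one frame.

    ``position`` is the centroid in cm, or ``None`` on a tracking dropout.
    Returns a :class:`ToneCommand` when the commanded output changes (always
    on the first frame), else ``None``.  Raises on time regression.
    """
    if time_s < state.last_time:
        raise SequencingError(
            f"time regression: {time_s} s after {state.last_time} s"
        )
    state.last_time = time_s

    if state._inv is None:
        state._inv = assignment.physical_to_role
    if position is not None:
        a = arena if arena is not None else ArenaSpec()
        physical = assign_quadrant(position[0], position[1], a)
        role = state._inv[physical]
        if state.confirmed_role is None:
            # first observed position is adopted immediately
            state.confirmed_role = role
            state.candidate_role = None
            state.candidate_count = 0
        elif role == state.confirmed_role:
            state.candidate_role = None
            state.candidate_count = 0
        else:
            if role == state.candidate_role:
                state.candidate_count += 1
            else:
                state.candidate_role = role
                state.candidate_count = 1
            if state.candidate_count >= DEBOUNCE_FRAMES:
                state.confirmed_role = role
                state.candidate_role = None
                state.candidate_count = 0
    # dropout: hold last confirmed quadrant

    cause = state.confirmed_role if state.confirmed_role is not None else "Q1"
    if time_s < schedule.habituation_s:
        tone = SILENCE
    else:
        tone = assignment.role_to_tone[cause]

    command = None
    if not state.started or tone != state.last_tone or cause != state.last_cause:
        command = ToneCommand(time_s=time_s, tone=tone, cause=cause)
        state.last_tone = tone
        state.last_cause = cause
        state.started = True
    return command, state


@dataclass
class ToneEventLog:
    """Ordered tone transitions of one session (only changes recorded)."""

    session_id: str
    assignment: SoundscapeAssignment
    commands: list[ToneCommand] = field(default_factory=list)

    def tone_on_time_s(self, frame_period_s: float, end_time_s: float) -> float:
        """Total commanded tone-on time, treating each command as holding
        until the next (last command holds until ``end_time_s``)."""
        total = 0.0
        for cmd, nxt in zip(self.commands, self.commands[1:] + [None]):
            t_end = end_time_s if nxt is None else nxt.time_s
            if not cmd.tone.is_silence:
                total += max(0.0, t_end - cmd.time_s)
        return total

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cmd in self.commands:
            rows.append(
                {
                    "time_s": cmd.time_s,
                    "role": cmd.cause,
                    "frequency_khz": (
                        "" if cmd.tone.is_silence else cmd.tone.frequency_khz
                    ),
                    "spl_db": "" if cmd.tone.is_silence else cmd.tone.spl_db,
                }
            )
        return pd.DataFrame(
            rows, columns=["time_s", "role", "frequency_khz", "spl_db"]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_session(
    traj,
    schedule: PhaseSchedule,
    assignment: SoundscapeAssignment,
    arena=None,
    session_id: str = "session",
) -> ToneEventLog:
    """Replay the controller over a full trajectory.

    Pure function of its inputs; the log starts with a command at the first
    frame (silence at t=0 for a schedule with habituation).  Raises
    :class:`TruncationError` when the trajectory does not cover the schedule.
    """
    a = arena if arena is not None else ArenaSpec()
    if traj.time_s[-1] < schedule.total_s - 1.5 / a.fps:
        raise TruncationError(
            f"trajectory ends at {traj.time_s[-1]:.2f} s but the schedule "
            f"runs to {schedule.total_s:.2f} s"
        )
    state = EngineState()
    log = ToneEventLog(session_id=session_id, assignment=assignment)
    for i in range(len(traj.time_s)):
        pos = (
            (traj.x_cm[i], traj.y_cm[i])
            if traj.valid[i]
            else None
        )
        cmd, state = step(pos, traj.time_s[i], schedule, assignment, state, a)
        if cmd is not None:
            log.commands.append(cmd)
    return log
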