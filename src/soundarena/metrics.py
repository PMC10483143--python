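"""Behavioral readouts of a session: occupancy, preference, time course,
AUC, locomotion, and position heat maps.

All quantities are computed in role space (Q1 silence, Q2-Q4 tones) from a
trajectory plus the session's soundscape assignment.  Invalid (dropout)
frames are excluded from every denominator; the preference index is a
percentage-point difference of phase-time *fractions*, since the habituation
and exposure phases differ in duration and raw seconds are not comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .arena import (
    ArenaSpec,
    PhaseSchedule,
    ROLES,
    SessionConfig,
    SoundscapeAssignment,
    assign_quadrant_array,
)
from .errors import EmptyWindowError, InputError, PairingError, ParameterError
from .tracking import Trajectory

#: steps implying faster motion than this are tracking artifacts
MAX_SPEED_CM_S = 100.0


@dataclass(frozen=True)
class OccupancyResult:
    """Per-role time in one phase window, in seconds and phase fractions."""

    phase: str
    seconds: dict[str, float]
    fraction: dict[str, float]
    valid_time_s: float


@dataclass(frozen=True)
class BinnedTimeCourse:
    """Occupancy fractions per time bin; habituation is a single bin."""

    bin_edges_s: np.ndarray
    fractions: dict[str, np.ndarray]  # role -> per-bin fraction
    n_habituation_bins: int
    truncated_last_bin: bool

    @property
    def exposure_midpoints_min(self) -> np.ndarray:
        """Bin midpoints of the exposure bins, minutes from exposure onset."""
        edges = self.bin_edges_s[self.n_habituation_bins :]
        mids = (edges[:-1] + edges[1:]) / 2.0
        return (mids - self.bin_edges_s[self.n_habituation_bins]) / 60.0


def frame_roles(
    traj: Trajectory, assignment: SoundscapeAssignment, arena: ArenaSpec
) -> np.ndarray:
    """Role label per frame ('' for frames without a usable position)."""
    labels = assign_quadrant_array(traj.x_cm, traj.y_cm, arena)
    inv = assignment.physical_to_role
    out = np.empty(len(labels), dtype=object)
    for i, lab in enumerate(labels):
        out[i] = inv[lab] if lab else ""
    return np.asarray(out)


def occupancy(
    traj: Trajectory,
    assignment: SoundscapeAssignment,
    arena: ArenaSpec,
    window: tuple[float, float],
    phase: str = "window",
) -> OccupancyResult:
    """Per-role occupancy over ``[t0, t1)``.

    Time per role is (valid frames in the role's quadrant) x frame period;
    fractions are over valid frames only.
    """
    t0, t1 = window
    sel = (traj.time_s >= t0) & (traj.time_s < t1) & traj.valid
    if not sel.any():
        raise EmptyWindowError(f"no valid frames in window [{t0}, {t1})")
    roles = frame_roles(traj, assignment, arena)[sel]
    dt = traj.median_dt
    n = len(roles)
    seconds = {}
    fraction = {}
    for role in ROLES:
        k = int(np.sum(roles == role))
        seconds[role] = k * dt
        fraction[role] = k / n
    return OccupancyResult(
        phase=phase, seconds=seconds, fraction=fraction, valid_time_s=n * dt
    )


def silent_vs_other(occ: OccupancyResult) -> tuple[float, float]:
    """Silent-quadrant fraction vs the mean of the three tone-role fractions."""
    tone_mean = float(np.mean([occ.fraction[r] for r in ("Q2", "Q3", "Q4")]))
    return (occ.fraction["Q1"], tone_mean)


def preference_index(
    occ_exposure: OccupancyResult, occ_habituation: OccupancyResult
) -> dict[str, float]:
    """Per-role exposure minus habituation occupancy, in percentage points.

    The four components sum to zero by construction.
    """
    if occ_exposure.phase == occ_habituation.phase:
        raise PairingError(
            "preference index needs one exposure and one habituation result"
        )
    return {
        r: 100.0 * (occ_exposure.fraction[r] - occ_habituation.fraction[r])
        for r in ROLES
    }


def binned_timecourse(
    traj: Trajectory,
    assignment: SoundscapeAssignment,
    arena: ArenaSpec,
    schedule: PhaseSchedule,
    bin_s: float = 300.0,
) -> BinnedTimeCourse:
    """Occupancy time course: one habituation bin, then exposure bins.

    Exposure is split into ``exposure_s / bin_s`` bins; a non-dividing last
    bin is truncated and flagged.
    """
    if bin_s <= 0:
        raise ParameterError("bin_s must be positive")
    edges = [0.0, schedule.habituation_s]
    t = schedule.habituation_s
    truncated = False
    while t < schedule.total_s - 1e-9:
        t_next = min(t + bin_s, schedule.total_s)
        edges.append(t_next)
        if t_next - t < bin_s - 1e-9:
            truncated = True
        t = t_next
    edges_arr = np.asarray(edges)
    fractions = {r: [] for r in ROLES}
    for lo, hi in zip(edges_arr[:-1], edges_arr[1:]):
        occ = occupancy(traj, assignment, arena, (lo, hi))
        for r in ROLES:
            fractions[r].append(occ.fraction[r])
    return BinnedTimeCourse(
        bin_edges_s=edges_arr,
        fractions={r: np.asarray(v) for r, v in fractions.items()},
        n_habituation_bins=1,
        truncated_last_bin=truncated,
    )


def auc(
    tc: BinnedTimeCourse,
    role: str,
    include_habituation: bool = False,
    scale: str = "fraction",
) -> float:
    """Area under the exposure time course of one role, fraction x minutes.

    Trapezoidal integral of the per-bin fraction against bin midpoints (in
    minutes from exposure onset); exposure bins only.  ``include_habituation``
    prepends the habituation bin; ``scale="minutes"`` integrates per-bin
    minutes in the quadrant (fraction x bin width) instead of fractions.
    """
    if role not in ROLES:
        raise ParameterError(f"unknown role {role!r}; expected one of {ROLES}")
    if scale not in ("fraction", "minutes"):
        raise ParameterError("scale must be 'fraction' or 'minutes'")
    start = 0 if include_habituation else tc.n_habituation_bins
    f = tc.fractions[role][start:]
    if len(f) < 2:
        raise ParameterError("AUC needs at least two exposure bins")
    edges = tc.bin_edges_s[start:]
    mids_min = (edges[:-1] + edges[1:]) / 2.0 / 60.0  # shift-invariant under trapezoid
    if scale == "minutes":
        f = f * np.diff(edges) / 60.0
    return float(np.trapezoid(f, mids_min))


def distance_traveled(
    traj: Trajectory,
    assignment: SoundscapeAssignment,
    arena: ArenaSpec,
    max_speed_cm_s: float = MAX_SPEED_CM_S,
) -> tuple[float, dict[str, float]]:
    """Total and per-role path length over valid frames.

    Steps are Euclidean distances between consecutive *valid* frames (skipping
    across dropouts), attributed to the role of the starting frame; steps
    implying speed above ``max_speed_cm_s`` are excluded as artifacts.
    """
    idx = np.nonzero(traj.valid)[0]
    if len(idx) < 2:
        raise InputError("need >= 2 valid frames to measure distance")
    x = traj.x_cm[idx]
    y = traj.y_cm[idx]
    t = traj.time_s[idx]
    steps = np.hypot(np.diff(x), np.diff(y))
    dt = np.diff(t)
    ok = steps / dt <= max_speed_cm_s
    roles = frame_roles(traj, assignment, arena)[idx][:-1]
    per_role = {r: float(steps[ok & (roles == r)].sum()) for r in ROLES}
    return (float(steps[ok].sum()), per_role)


def heatmap(
    traj: Trajectory, arena: ArenaSpec, bin_cm: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D occupancy histogram in seconds per cell.

    Returns ``(matrix, x_edges, y_edges)`` with ``matrix[iy, ix]``; the matrix
    sums to the valid time.
    """
    if bin_cm <= 0:
        raise ParameterError("bin_cm must be positive")
    x_edges = np.arange(0.0, arena.width_cm + bin_cm, bin_cm)
    y_edges = np.arange(0.0, arena.height_cm + bin_cm, bin_cm)
    x_edges[-1] = max(x_edges[-1], arena.width_cm)
    y_edges[-1] = max(y_edges[-1], arena.height_cm)
    sel = traj.valid
    dt = traj.median_dt
    h, _, _ = np.histogram2d(
        traj.y_cm[sel], traj.x_cm[sel], bins=[y_edges, x_edges]
    )
    return h * dt, x_edges, y_edges


@dataclass
class SessionResult:
    """All per-session readouts, ready for cohort-level statistics."""

    session_id: str
    occupancy_habituation: OccupancyResult
    occupancy_exposure: OccupancyResult
    preference: dict[str, float]
    timecourse: BinnedTimeCourse
    auc_by_role: dict[str, float]
    distance_total_cm: float
    distance_by_role_cm: dict[str, float]
    heatmap_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable summary (heat map reduced to its mass)."""
        return {
            "session_id": self.session_id,
            "occupancy": {
                phase: {
                    "seconds": occ.seconds,
                    "fraction": occ.fraction,
                    "valid_time_s": occ.valid_time_s,
                }
                for phase, occ in (
                    ("habituation", self.occupancy_habituation),
                    ("exposure", self.occupancy_exposure),
                )
            },
            "preference_index_pct": self.preference,
            "timecourse": {
                "bin_edges_s": self.timecourse.bin_edges_s.tolist(),
                "fractions": {
                    r: v.tolist() for r, v in self.timecourse.fractions.items()
                },
            },
            "auc_fraction_min": self.auc_by_role,
            "distance_total_cm": self.distance_total_cm,
            "distance_by_role_cm": self.distance_by_role_cm,
            "heatmap_mass_s": float(self.heatmap_s.sum()),
            "metadata": self.metadata,
        }

    def tidy(self) -> pd.DataFrame:
        """Long-format per-quadrant table for cohort assembly."""
        rows = []
        for role in ROLES:
            for phase, occ in (
                ("habituation", self.occupancy_habituation),
                ("exposure", self.occupancy_exposure),
            ):
                rows.append(
                    {
                        "session": self.session_id,
                        "phase": phase,
                        "role": role,
                        "seconds": occ.seconds[role],
                        "fraction": occ.fraction[role],
                        "pref_index": self.preference[role],
                        "auc": self.auc_by_role[role],
                        "distance_cm": self.distance_by_role_cm[role],
                    }
                )
        return pd.DataFrame(rows)


def analyze_session(
    traj: Trajectory,
    config: SessionConfig,
    heatmap_bin_cm: float = 1.0,
    bin_s: float = 300.0,
) -> SessionResult:
    """Run the full per-session metrics battery."""
    sched = config.schedule
    occ_hab = occupancy(
        traj, config.assignment, config.arena, sched.habituation_window, "habituation"
    )
    occ_exp = occupancy(
        traj, config.assignment, config.arena, sched.exposure_window, "exposure"
    )
    tc = binned_timecourse(traj, config.assignment, config.arena, sched, bin_s)
    total, per_role = distance_traveled(traj, config.assignment, config.arena)
    hm, _, _ = heatmap(traj, config.arena, heatmap_bin_cm)
    return SessionResult(
        session_id=config.session_id,
        occupancy_habituation=occ_hab,
        occupancy_exposure=occ_exp,
        preference=preference_index(occ_exp, occ_hab),
        timecourse=tc,
        auc_by_role={r: auc(tc, r) for r in ROLES},
        distance_total_cm=total,
        distance_by_role_cm=per_role,
        heatmap_s=hm,
    )
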