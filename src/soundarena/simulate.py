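"""Synthetic sessions: agent trajectories, dwell-process trajectories, and
rendered frame stacks.

Two generators exist on purpose.  The *agent* model is a correlated random
walk with an optional reorientation-toward-silence mechanism: it produces
behaviorally plausible tracks for integration tests and for the avoidance
phenotype class (silent-quadrant enrichment emerging after a latency).  The
*dwell* model is a semi-Markov quadrant process with exponential dwells whose
stationary role occupancy equals a requested vector exactly: it gives precise
control for estimator-recovery tests.  Neither claims biological realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
import yaml

from . import engine as _engine
from .arena import (
    ArenaSpec,
    PhaseSchedule,
    ROLES,
    SoundscapeAssignment,
    counterbalance_assignments,
)
from .errors import ConfigurationError, CoordinateError, ParameterError
from .tracking import Trajectory


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of a simulated mouse.

    ``avoidance_strength`` is the per-second probability of reorienting
    toward the silent quadrant while a tone is audible; ``onset_latency_s``
    delays that mechanism after the first tone exposure.
    """

    mean_speed_cm_s: float = 8.0
    speed_shape: float = 2.0
    turn_sd_rad: float = 0.25
    avoidance_strength: float = 0.0
    onset_latency_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed_cm_s <= 0 or self.speed_shape <= 0:
            raise ParameterError("speeds must be positive")
        if self.turn_sd_rad < 0:
            raise ParameterError("turn_sd_rad must be >= 0")
        if not (0.0 <= self.avoidance_strength <= 1.0):
            raise ParameterError("avoidance_strength must be in [0, 1]")
        if self.onset_latency_s < 0:
            raise ParameterError("onset_latency_s must be >= 0")


@dataclass(frozen=True)
class DwellModelParams:
    """Quadrant dwell process with a prescribed stationary occupancy."""

    occupancy: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mean_dwell_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.occupancy, dtype=float)
        if len(v) != 4 or np.any(v < 0):
            raise ParameterError("occupancy must be 4 non-negative entries")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ParameterError("occupancy must sum to 1")
        if self.mean_dwell_s <= 0:
            raise ParameterError("mean_dwell_s must be positive")


def _reflect(v: float, lo: float, hi: float) -> float:
    period = 2.0 * (hi - lo)
    z = (v - lo) % period
    return lo + (z if z <= hi - lo else period - z)


def _reflect_array(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    period = 2.0 * (hi - lo)
    z = np.mod(v - lo, period)
    return lo + np.minimum(z, period - z)


def simulate_agent(
    params: AgentParams,
    arena: ArenaSpec,
    schedule: PhaseSchedule,
    assignment: SoundscapeAssignment,
    duration_s: Optional[float] = None,
) -> Trajectory:
    """Discrete-time correlated random walk through the closed-loop engine.

    Per frame the heading gets wrapped-normal noise and the step length is
    gamma-distributed (mean ``mean_speed_cm_s / fps``); walls reflect.  The
    engine runs internally so the tone state is known; while a tone is on and
    the session time exceeds first exposure plus ``onset_latency_s``, the
    heading is reset toward the silent quadrant's centroid (plus noise) with
    probability ``avoidance_strength / fps`` per frame.  Deterministic given
    the seed.
    """
    rng = np.random.default_rng(params.seed)
    total = schedule.total_s if duration_s is None else float(duration_s)
    n = int(round(total * arena.fps))
    fps = arena.fps
    dt = 1.0 / fps
    scale = params.mean_speed_cm_s / (fps * params.speed_shape)

    turns = rng.normal(0.0, params.turn_sd_rad, size=n)
    steps = rng.gamma(params.speed_shape, scale, size=n)
    u_avoid = rng.random(size=n)
    avoid_noise = rng.normal(0.0, 0.3, size=n)

    silent_cx, silent_cy = arena.quadrant_center(assignment.silent_physical)
    p_avoid = params.avoidance_strength / fps

    x = np.empty(n)
    y = np.empty(n)
    cx, cy = arena.center
    heading = rng.uniform(-math.pi, math.pi)
    state = _engine.EngineState()
    first_tone_t: Optional[float] = None
    w, h = arena.width_cm, arena.height_cm

    px, py = cx, cy
    for i in range(n):
        t = i * dt
        _engine.step((px, py), t, schedule, assignment, state, arena)
        tone_on = state.last_tone is not None and not state.last_tone.is_silence
        if tone_on and first_tone_t is None:
            first_tone_t = t
        if (
            tone_on
            and first_tone_t is not None
            and t >= first_tone_t + params.onset_latency_s
            and u_avoid[i] < p_avoid
        ):
            heading = math.atan2(silent_cy - py, silent_cx - px) + avoid_noise[i]
        else:
            heading += turns[i]
        px = _reflect(px + steps[i] * math.cos(heading), 0.0, w)
        py = _reflect(py + steps[i] * math.sin(heading), 0.0, h)
        x[i] = px
        y[i] = py

    return Trajectory(
        time_s=np.arange(n) * dt,
        x_cm=x,
        y_cm=y,
        valid=np.ones(n, dtype=bool),
    )


def dwell_segments(
    params: DwellModelParams, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Role-index sequence and exponential dwell durations covering
    ``duration_s`` (last segment truncated at the boundary)."""
    v = np.asarray(params.occupancy, dtype=float)
    cdf = np.cumsum(v)
    idx = np.empty(0, dtype=int)
    durs = np.empty(0, dtype=float)
    covered = 0.0
    while covered < duration_s:
        # draw in batches; expected segment count is duration / mean_dwell
        k = max(16, int(1.5 * (duration_s - covered) / params.mean_dwell_s))
        idx = np.concatenate([idx, np.searchsorted(cdf, rng.random(k))])
        durs = np.concatenate([durs, rng.exponential(params.mean_dwell_s, k)])
        covered = durs.sum()
    ends = np.cumsum(durs)
    last = int(np.searchsorted(ends, duration_s, side="left"))
    idx = idx[: last + 1]
    durs = durs[: last + 1].copy()
    durs[-1] -= ends[last] - duration_s
    return idx, durs


def dwell_fractions(
    params: DwellModelParams, duration_s: float, seed: Optional[int] = None
) -> np.ndarray:
    """Exact per-role time fractions of one realized dwell process.

    Continuous-time bookkeeping over the segment process only (no per-frame
    rendering); useful for calibration studies over many cohorts.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    idx, durs = dwell_segments(params, duration_s, rng)
    out = np.zeros(4)
    np.add.at(out, idx, durs)
    return out / duration_s


#: margin keeping dwell-walk positions off the virtual boundaries, cm
_DWELL_MARGIN_CM = 0.5


def simulate_dwell(
    params: DwellModelParams,
    arena: ArenaSpec,
    schedule: PhaseSchedule,
    assignment: SoundscapeAssignment,
    duration_s: Optional[float] = None,
) -> Trajectory:
    """Trajectory from the quadrant dwell process.

    Each segment picks a role from the stationary vector and holds it for an
    exponential dwell; within a segment the position follows a small bounded
    random walk inside the role's physical quadrant.  The emitted
    exposure-phase occupancy converges to the requested vector as the session
    grows.
    """
    rng = np.random.default_rng(params.seed)
    total = schedule.total_s if duration_s is None else float(duration_s)
    n = int(round(total * arena.fps))
    time_s = np.arange(n) / arena.fps

    idx, durs = dwell_segments(params, total, rng)
    boundaries = np.cumsum(durs)
    frame_seg = np.searchsorted(boundaries, time_s, side="right")
    frame_seg = np.minimum(frame_seg, len(idx) - 1)
    frame_role = idx[frame_seg]

    # quadrant-local bounded walk, folded into the (margin-shrunk) half-box
    half_w = arena.width_cm / 2.0
    half_h = arena.height_cm / 2.0
    m = _DWELL_MARGIN_CM
    step_sd = 0.5  # cm per frame
    lx = _reflect_array(
        half_w / 2.0 + np.cumsum(rng.normal(0, step_sd, n)), m, half_w - m
    )
    ly = _reflect_array(
        half_h / 2.0 + np.cumsum(rng.normal(0, step_sd, n)), m, half_h - m
    )

    phys = [assignment.role_to_physical[ROLES[k]] for k in range(4)]
    offsets = {
        "A": (0.0, 0.0),
        "B": (half_w, 0.0),
        "C": (0.0, half_h),
        "D": (half_w, half_h),
    }
    off = np.asarray([offsets[p] for p in phys])  # (4, 2)
    x = lx + off[frame_role, 0]
    y = ly + off[frame_role, 1]

    return Trajectory(
        time_s=time_s, x_cm=x, y_cm=y, valid=np.ones(n, dtype=bool)
    )


def render_frames(
    traj: Trajectory,
    arena: ArenaSpec,
    blob_sd_px: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a trajectory as a stack of grayscale frames.

    Each frame carries a unit-amplitude Gaussian blob at the animal position
    (bright on dark, matching the tracker's polarity convention) plus white
    noise.  Requires pixel calibration; dropout frames render blank.
    """
    if arena.px_per_cm is None:
        raise ConfigurationError("render_frames requires px_per_cm calibration")
    ppc = arena.px_per_cm
    w_px = int(round(arena.width_cm * ppc))
    h_px = int(round(arena.height_cm * ppc))
    finite = traj.valid & ~np.isnan(traj.x_cm)
    if np.any(
        (traj.x_cm[finite] < 0)
        | (traj.x_cm[finite] > arena.width_cm)
        | (traj.y_cm[finite] < 0)
        | (traj.y_cm[finite] > arena.height_cm)
    ):
        raise CoordinateError("trajectory position falls off the canvas")
    rng = np.random.default_rng(seed)
    n = len(traj)
    stack = np.zeros((n, h_px, w_px))
    reach = int(math.ceil(4 * blob_sd_px))
    for i in range(n):
        if finite[i]:
            bx = traj.x_cm[i] * ppc
            by = traj.y_cm[i] * ppc
            x0 = max(0, int(bx) - reach)
            x1 = min(w_px, int(bx) + reach + 1)
            y0 = max(0, int(by) - reach)
            y1 = min(h_px, int(by) + reach + 1)
            ys, xs = np.mgrid[y0:y1, x0:x1]
            stack[i, y0:y1, x0:x1] = np.exp(
                -((xs - bx) ** 2 + (ys - by) ** 2) / (2 * blob_sd_px**2)
            )
    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack


@dataclass
class SimulatedSession:
    """One simulated animal's session, ready for the analysis pipeline."""

    subject_id: str
    genotype: str
    pair: int
    assignment: SoundscapeAssignment
    trajectory: Trajectory
    params: AgentParams = field(repr=False, default_factory=AgentParams)


def _child_seed(master: int, index: int) -> int:
    # counter-based fan-out so cohort growth never reshuffles earlier sessions
    return int((master * 100003 + index * 7919 + 17) % (2**31))


def simulate_cohort(
    n_per_genotype: int,
    wt_params: AgentParams,
    ko_params: AgentParams,
    arena: Optional[ArenaSpec] = None,
    schedule: Optional[PhaseSchedule] = None,
    seed: int = 0,
    frequencies_khz: tuple[float, float, float] = (20.0, 24.0, 28.0),
    spl_db: float = 70.0,
) -> list[SimulatedSession]:
    """Paired WT/KO cohort with counterbalanced soundscape assignments.

    Both genotypes of a pair share one assignment (tested the same day with
    the soundscape held constant within the pair); assignments are
    counterbalanced across pairs.
    """
    if n_per_genotype < 1:
        raise ParameterError("n_per_genotype must be >= 1")
    arena = arena or ArenaSpec()
    schedule = schedule or PhaseSchedule()
    assignments = counterbalance_assignments(
        n_per_genotype, _child_seed(seed, 0), frequencies_khz, spl_db
    )
    sessions = []
    for pair in range(n_per_genotype):
        for g, params in (("WT", wt_params), ("KO", ko_params)):
            p = replace(params, seed=_child_seed(seed, 1 + 2 * pair + (g == "KO")))
            traj = simulate_agent(p, arena, schedule, assignments[pair])
            sessions.append(
                SimulatedSession(
                    subject_id=f"{g}{pair + 1:02d}",
                    genotype=g,
                    pair=pair,
                    assignment=assignments[pair],
                    trajectory=traj,
                    params=p,
                )
            )
    return sessions


def load_profile(name: str) -> AgentParams:
    """Agent parameter profile from the packaged config (``wt`` or ``ko``)."""
    text = resources.files("soundarena").joinpath("data/profiles.yaml").read_text()
    profiles = yaml.safe_load(text)
    if name not in profiles:
        raise ConfigurationError(
            f"unknown profile {name!r}; available: {sorted(profiles)}"
        )
    return AgentParams(**profiles[name])
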