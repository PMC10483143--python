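"""Centroid extraction from grayscale frames and trajectory file I/O.

The tracker is deliberately minimal — threshold plus intensity-weighted
center of mass — because the assay only needs a testable stand-in for an
external real-time tracker, validated against synthetic frames with known
ground truth.  Frames are indexed ``frame[y, x]`` with y increasing upward
(same orientation as arena coordinates; the synthetic convention renders the
animal bright on a dark background).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .arena import ArenaSpec, pixel_to_cm
from .errors import FormatError, InputError

#: dropouts up to this many frames are forward-filled (0.5 s at 20 fps)
MAX_FFILL_FRAMES = 10


@dataclass
class Trajectory:
    """Timestamped centroid track with per-frame dropout flags.

    ``valid[i]`` is False for frames where tracking was lost; such frames may
    still carry a forward-filled position (usable by the closed-loop engine)
    but are excluded from all analysis denominators.
    """

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_cm = np.asarray(self.x_cm, dtype=float)
        self.y_cm = np.asarray(self.y_cm, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.time_s)
        if not (len(self.x_cm) == len(self.y_cm) == len(self.valid) == n):
            raise FormatError("trajectory fields have mismatched lengths")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise FormatError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if len(self) else 0.0

    @property
    def median_dt(self) -> float:
        if len(self) < 2:
            raise InputError("need >= 2 frames to estimate frame period")
        return float(np.median(np.diff(self.time_s)))


def extract_centroid(
    frame: np.ndarray, threshold: float
) -> Optional[tuple[float, float]]:
    """Intensity-weighted center of mass of above-threshold pixels.

    Returns ``(x, y)`` in pixels, or ``None`` when no pixel exceeds the
    threshold (a dropout is a value, not an error).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise InputError("empty frame")
    mask = frame > threshold
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    w = frame[ys, xs]
    total = w.sum()
    return (float((xs * w).sum() / total), float((ys * w).sum() / total))


def track_frames(
    frames, arena: ArenaSpec, threshold: float
) -> Trajectory:
    """Track a frame stack into a calibrated trajectory.

    Dropout frames are flagged invalid; gaps of at most MAX_FFILL_FRAMES are
    forward-filled with the last valid position (still flagged invalid) so the
    closed-loop engine can hold its state across them.  Longer gaps and
    leading dropouts carry NaN positions.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.size == 0 or frames.ndim != 3:
        raise InputError("expected a non-empty (n, height, width) frame stack")
    n = frames.shape[0]
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    last_xy: Optional[tuple[float, float]] = None
    gap = 0
    for i in range(n):
        c = extract_centroid(frames[i], threshold)
        if c is None:
            gap += 1
            if last_xy is not None and gap <= MAX_FFILL_FRAMES:
                x[i], y[i] = last_xy
            continue
        gap = 0
        x_cm, y_cm = pixel_to_cm(c[0], c[1], arena)
        x[i], y[i] = x_cm, y_cm
        last_xy = (x_cm, y_cm)
        valid[i] = True
    time_s = np.arange(n) / arena.fps
    return Trajectory(time_s=time_s, x_cm=x, y_cm=y, valid=valid)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the cm-dialect CSV (time_s, x_cm, y_cm, valid); 6 decimals."""
    df = pd.DataFrame(
        {
            "time_s": traj.time_s,
            "x_cm": traj.x_cm,
            "y_cm": traj.y_cm,
            "valid": traj.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_trajectory(path: str | Path, arena: Optional[ArenaSpec] = None) -> Trajectory:
    """Read a trajectory CSV in either accepted dialect.

    Dialects: ``time_s,x_cm,y_cm[,valid]`` (calibrated) or
    ``frame,x_px,y_px[,valid]`` (pixel; requires an arena with ``px_per_cm``
    and ``fps``, timestamps synthesized from the frame index).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"time_s", "x_cm", "y_cm"} <= cols:
        time_s = df["time_s"].to_numpy(float)
        x = df["x_cm"].to_numpy(float)
        y = df["y_cm"].to_numpy(float)
    elif {"frame", "x_px", "y_px"} <= cols:
        if arena is None or arena.px_per_cm is None:
            raise FormatError(
                "pixel-dialect trajectory requires an arena with px_per_cm"
            )
        time_s = df["frame"].to_numpy(float) / arena.fps
        x = df["x_px"].to_numpy(float) / arena.px_per_cm
        y = df["y_px"].to_numpy(float) / arena.px_per_cm
    else:
        raise FormatError(
            "unknown trajectory dialect; accepted columns: "
            "(time_s, x_cm, y_cm[, valid]) or (frame, x_px, y_px[, valid])"
        )
    valid = (
        df["valid"].to_numpy().astype(bool)
        if "valid" in cols
        else ~(np.isnan(x) | np.isnan(y))
    )
    return Trajectory(time_s=time_s, x_cm=x, y_cm=y, valid=valid)
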