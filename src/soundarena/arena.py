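"""Arena geometry, quadrant partition, and tone/soundscape configuration.

The open field is a square arena divided into four *virtual* quadrants by its
two midlines.  Physical quadrants carry fixed labels in arena coordinates
(origin lower-left, cm, y up)::

    C | D        A = lower-left   B = lower-right
    --+--        C = upper-left   D = upper-right
    A | B

Quadrant *roles* (Q1..Q4) are the functional identity used in analysis: Q1 is
always silence, Q2-Q4 carry tones.  Which physical corner plays which role is
randomized per animal pair (counterbalancing), so all downstream analysis is
performed in role space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError, CoordinateError, ParameterError

PHYSICAL_LABELS = ("A", "B", "C", "D")
ROLES = ("Q1", "Q2", "Q3", "Q4")
TONE_ROLES = ("Q2", "Q3", "Q4")

#: frequency sets in kHz; the assay uses one set per session
AUDIBLE_KHZ = (8.0, 12.0, 16.0)
ULTRASOUND_KHZ = (20.0, 24.0, 28.0)
SPL_RANGE_DB = (50.0, 80.0)

#: default sound levels per condition (dB SPL measured at the arena floor)
DEFAULT_SPL = {"audible": 50.0, "ultrasound": 70.0}


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry, frame rate and optional pixel calibration of the open field.

    ``px_per_cm`` absent means trajectory input is already in cm.
    ``wall_height_cm`` is informational only.
    """

    width_cm: float = 44.0
    height_cm: float = 44.0
    wall_height_cm: float = 30.0
    fps: float = 20.0
    px_per_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.height_cm <= 0:
            raise ParameterError("arena dimensions must be positive")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if self.px_per_cm is not None and self.px_per_cm <= 0:
            raise ParameterError("px_per_cm must be positive when present")

    @property
    def frame_period_s(self) -> float:
        return 1.0 / self.fps

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_cm / 2.0, self.height_cm / 2.0)

    def quadrant_center(self, label: str) -> tuple[float, float]:
        """Centroid of a physical quadrant, in cm."""
        qx = self.width_cm / 4.0
        qy = self.height_cm / 4.0
        return {
            "A": (qx, qy),
            "B": (3 * qx, qy),
            "C": (qx, 3 * qy),
            "D": (3 * qx, 3 * qy),
        }[label]


@dataclass(frozen=True)
class ToneSpec:
    """A pure tone (frequency in kHz, level in dB SPL) or silence.

    Silence is represented by ``frequency_khz is None`` and carries no level.
    """

    frequency_khz: Optional[float] = None
    spl_db: Optional[float] = None

    def __post_init__(self) -> None:
        if self.frequency_khz is None:
            if self.spl_db is not None:
                raise ParameterError("silence carries no sound level")
            return
        allowed = AUDIBLE_KHZ + ULTRASOUND_KHZ
        if self.frequency_khz not in allowed:
            raise ParameterError(
                f"frequency {self.frequency_khz} kHz not in assay set {allowed}"
            )
        if self.spl_db is None:
            raise ParameterError("a tone requires a sound level")
        if not (SPL_RANGE_DB[0] <= self.spl_db <= SPL_RANGE_DB[1]):
            raise ParameterError(
                f"spl_db {self.spl_db} outside tested range {SPL_RANGE_DB}"
            )

    @property
    def is_silence(self) -> bool:
        return self.frequency_khz is None

    @property
    def band(self) -> str:
        if self.is_silence:
            return "silence"
        return "audible" if self.frequency_khz in AUDIBLE_KHZ else "ultrasound"


SILENCE = ToneSpec()


@dataclass(frozen=True)
class SoundscapeAssignment:
    """Mapping of quadrant roles to physical quadrants and to tones.

    ``role_to_physical`` is a bijection Q1..Q4 -> A..D.  ``role_to_tone``
    assigns silence to Q1 and one tone each to Q2..Q4; within a session all
    three tones share one sound level.
    """

    role_to_physical: dict[str, str]
    role_to_tone: dict[str, ToneSpec]

    def __post_init__(self) -> None:
        if set(self.role_to_physical) != set(ROLES):
            raise ConfigurationError("role_to_physical must cover Q1..Q4")
        if set(self.role_to_physical.values()) != set(PHYSICAL_LABELS):
            raise ConfigurationError("role_to_physical must be a bijection onto A..D")
        if set(self.role_to_tone) != set(ROLES):
            raise ConfigurationError("role_to_tone must cover Q1..Q4")
        if not self.role_to_tone["Q1"].is_silence:
            raise ConfigurationError("Q1 must be the silent role")
        spls = set()
        for role in TONE_ROLES:
            tone = self.role_to_tone[role]
            if tone.is_silence:
                raise ConfigurationError(f"{role} must carry a tone")
            spls.add(tone.spl_db)
        if len(spls) != 1:
            raise ConfigurationError("tone roles must share one sound level")

    @property
    def physical_to_role(self) -> dict[str, str]:
        return {p: r for r, p in self.role_to_physical.items()}

    @property
    def silent_physical(self) -> str:
        return self.role_to_physical["Q1"]


@dataclass(frozen=True)
class PhaseSchedule:
    """Session phase durations: silent habituation then tone exposure."""

    habituation_s: float = 300.0
    exposure_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.habituation_s < 0:
            raise ParameterError("habituation_s must be >= 0")
        if self.exposure_s <= 0:
            raise ParameterError("exposure_s must be > 0")

    @property
    def total_s(self) -> float:
        return self.habituation_s + self.exposure_s

    @property
    def habituation_window(self) -> tuple[float, float]:
        return (0.0, self.habituation_s)

    @property
    def exposure_window(self) -> tuple[float, float]:
        return (self.habituation_s, self.total_s)


def assign_quadrant(x: float, y: float, arena: ArenaSpec) -> str:
    """Physical quadrant label of a point, by the half-open midline rule.

    x in [0, W/2) is left, [W/2, W] right; y likewise lower/upper, so the
    assignment is total and deterministic on the closed arena.
    """
    if not (0.0 <= x <= arena.width_cm):
        raise CoordinateError(f"x={x} outside [0, {arena.width_cm}]")
    if not (0.0 <= y <= arena.height_cm):
        raise CoordinateError(f"y={y} outside [0, {arena.height_cm}]")
    right = x >= arena.width_cm / 2.0
    upper = y >= arena.height_cm / 2.0
    return ("D" if right else "C") if upper else ("B" if right else "A")


def assign_quadrant_array(
    x: np.ndarray, y: np.ndarray, arena: ArenaSpec
) -> np.ndarray:
    """Vectorized :func:`assign_quadrant`; NaN positions map to ''."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if np.any((x[ok] < 0) | (x[ok] > arena.width_cm)):
        raise CoordinateError("x outside arena bounds")
    if np.any((y[ok] < 0) | (y[ok] > arena.height_cm)):
        raise CoordinateError("y outside arena bounds")
    idx = (x >= arena.width_cm / 2.0).astype(int) + 2 * (
        y >= arena.height_cm / 2.0
    ).astype(int)
    labels = np.array(["A", "B", "C", "D"])[idx]
    labels[~ok] = ""
    return labels


def pixel_to_cm(x_px: float, y_px: float, arena: ArenaSpec) -> tuple[float, float]:
    """Convert pixel coordinates to cm (origin lower-left, y up).

    Requires ``px_per_cm`` on the arena; raises if the converted point falls
    outside the arena.
    """
    if arena.px_per_cm is None:
        raise ConfigurationError("px_per_cm calibration missing from ArenaSpec")
    x_cm = x_px / arena.px_per_cm
    y_cm = y_px / arena.px_per_cm
    if not (0.0 <= x_cm <= arena.width_cm):
        raise CoordinateError(f"x={x_px} px maps to {x_cm} cm, outside arena")
    if not (0.0 <= y_cm <= arena.height_cm):
        raise CoordinateError(f"y={y_px} px maps to {y_cm} cm, outside arena")
    return (x_cm, y_cm)


def make_assignment(
    silent_physical: str,
    tone_physicals: Optional[list[str]] = None,
    frequencies_khz: tuple[float, float, float] = ULTRASOUND_KHZ,
    spl_db: float = 70.0,
) -> SoundscapeAssignment:
    """Build an assignment from the silent corner and an ordered tone layout.

    ``tone_physicals`` lists the physical quadrants of Q2, Q3, Q4 in that
    order; default is the remaining labels in alphabetical order.
    """
    if tone_physicals is None:
        tone_physicals = [p for p in PHYSICAL_LABELS if p != silent_physical]
    role_to_physical = {"Q1": silent_physical}
    role_to_tone: dict[str, ToneSpec] = {"Q1": SILENCE}
    for role, phys, freq in zip(TONE_ROLES, tone_physicals, frequencies_khz):
        role_to_physical[role] = phys
        role_to_tone[role] = ToneSpec(freq, spl_db)
    return SoundscapeAssignment(role_to_physical, role_to_tone)


def counterbalance_assignments(
    n_pairs: int,
    seed: int,
    frequencies_khz: tuple[float, float, float] = ULTRASOUND_KHZ,
    spl_db: float = 70.0,
    permute_tones: bool = True,
) -> list[SoundscapeAssignment]:
    """One soundscape assignment per animal pair, counterbalanced.

    The silent role's physical quadrant is balanced in blocks of four (each
    block a seeded permutation of A..D); a remainder of fewer than four pairs
    is drawn without replacement.  By default the three tone roles are also
    permuted among the remaining corners per pair.
    """
    if n_pairs < 1:
        raise ParameterError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    silent: list[str] = []
    while len(silent) < n_pairs:
        block = [str(lab) for lab in rng.permutation(PHYSICAL_LABELS)]
        take = min(4, n_pairs - len(silent))
        silent.extend(block[:take])
    out = []
    for s in silent:
        rest = [p for p in PHYSICAL_LABELS if p != s]
        if permute_tones:
            rest = [str(lab) for lab in rng.permutation(rest)]
        out.append(make_assignment(s, rest, frequencies_khz, spl_db))
    return out


@dataclass
class SessionConfig:
    """Everything needed to replay or analyze one session."""

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    assignment: SoundscapeAssignment = field(
        default_factory=lambda: make_assignment("A")
    )
    seed: int = 0
    session_id: str = "session"


def save_config(config: SessionConfig, path: str | Path) -> None:
    """Write a session config as flat YAML (coordinate convention recorded)."""
    tones = {}
    for role in ROLES:
        tone = config.assignment.role_to_tone[role]
        tones[role] = (
            None
            if tone.is_silence
            else {"frequency_khz": tone.frequency_khz, "spl_db": tone.spl_db}
        )
    doc = {
        "coordinate_convention": "origin lower-left, cm, y up",
        "session_id": config.session_id,
        "arena": {
            "width_cm": config.arena.width_cm,
            "height_cm": config.arena.height_cm,
            "wall_height_cm": config.arena.wall_height_cm,
            "fps": config.arena.fps,
            "px_per_cm": config.arena.px_per_cm,
        },
        "schedule": {
            "habituation_s": config.schedule.habituation_s,
            "exposure_s": config.schedule.exposure_s,
        },
        "role_to_physical": dict(config.assignment.role_to_physical),
        "role_to_tone": tones,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path: str | Path) -> SessionConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        arena = ArenaSpec(**doc["arena"])
        schedule = PhaseSchedule(**doc["schedule"])
        role_to_tone = {}
        for role, spec in doc["role_to_tone"].items():
            role_to_tone[role] = SILENCE if spec is None else ToneSpec(**spec)
        assignment = SoundscapeAssignment(dict(doc["role_to_physical"]), role_to_tone)
    except KeyError as exc:
        raise ConfigurationError(f"session config missing key {exc}") from exc
    return SessionConfig(
        arena=arena,
        schedule=schedule,
        assignment=assignment,
        seed=int(doc.get("seed", 0)),
        session_id=str(doc.get("session_id", "session")),
    )
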