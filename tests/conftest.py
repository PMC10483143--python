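import numpy as np
import pytest

from soundarena import (
    ArenaSpec,
    PhaseSchedule,
    Trajectory,
    make_assignment,
)


@pytest.fixture
def arena():
    return ArenaSpec()


@pytest.fixture
def calibrated_arena():
    return ArenaSpec(px_per_cm=10.0)


@pytest.fixture
def schedule():
    return PhaseSchedule()


@pytest.fixture
def assignment():
    # silence in the lower-left corner, tones alphabetical
    return make_assignment("A")


@pytest.fixture
def short_schedule():
    return PhaseSchedule(habituation_s=5.0, exposure_s=20.0)


def random_walk_trajectory(
    n: int,
    arena: ArenaSpec,
    seed: int = 0,
    step_sd: float = 1.0,
    dropout_p: float = 0.0,
) -> Trajectory:
    """Seeded bounded random walk used as a generic test trajectory."""
    rng = np.random.default_rng(seed)
    period_x = 2 * arena.width_cm
    period_y = 2 * arena.height_cm
    x = np.mod(arena.width_cm / 2 + np.cumsum(rng.normal(0, step_sd, n)), period_x)
    y = np.mod(arena.height_cm / 2 + np.cumsum(rng.normal(0, step_sd, n)), period_y)
    x = np.minimum(x, period_x - x)
    y = np.minimum(y, period_y - y)
    valid = rng.random(n) >= dropout_p
    return Trajectory(
        time_s=np.arange(n) / arena.fps, x_cm=x, y_cm=y, valid=valid
    )


@pytest.fixture
def walk_factory(arena):
    def make(n=1000, seed=0, step_sd=1.0, dropout_p=0.0):
        return random_walk_trajectory(n, arena, seed, step_sd, dropout_p)

    return make
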