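"""Behavioral readouts: occupancy, preference, time course, AUC, distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soundarena import (
    ArenaSpec,
    PhaseSchedule,
    Trajectory,
    auc,
    binned_timecourse,
    distance_traveled,
    heatmap,
    make_assignment,
    occupancy,
    preference_index,
    silent_vs_other,
)
from soundarena.arena import ROLES, assign_quadrant
from soundarena.errors import (
    EmptyWindowError,
    InputError,
    PairingError,
    ParameterError,
)
from soundarena.metrics import OccupancyResult

from conftest import random_walk_trajectory

CENTERS = {"A": (11.0, 11.0), "B": (33.0, 11.0), "C": (11.0, 33.0), "D": (33.0, 33.0)}


def occupancy_oracle(traj, assignment, arena, window):
    """Independent per-frame tally of role occupancy fractions."""
    t0, t1 = window
    counts = dict.fromkeys(ROLES, 0)
    total = 0
    for i in range(len(traj)):
        if traj.valid[i] and t0 <= traj.time_s[i] < t1:
            phys = assign_quadrant(traj.x_cm[i], traj.y_cm[i], arena)
            counts[assignment.physical_to_role[phys]] += 1
            total += 1
    return {r: counts[r] / total for r in ROLES}


def make_traj(labels, fps=20.0):
    """One frame per label, at the labeled quadrant center."""
    xs = [CENTERS[lab][0] for lab in labels]
    ys = [CENTERS[lab][1] for lab in labels]
    n = len(labels)
    return Trajectory(
        time_s=np.arange(n) / fps,
        x_cm=np.array(xs),
        y_cm=np.array(ys),
        valid=np.ones(n, bool),
    )


class TestOccupancy:
    def test_one_frame_per_quadrant(self, arena, assignment):
        traj = make_traj(["A", "B", "C", "D"])
        occ = occupancy(traj, assignment, arena, (0.0, 1.0))
        assert all(occ.fraction[r] == 0.25 for r in ROLES)

    def test_all_in_silent_quadrant(self, arena, assignment):
        traj = make_traj(["A"] * 10)
        occ = occupancy(traj, assignment, arena, (0.0, 1.0))
        assert occ.fraction["Q1"] == 1.0

    def test_matches_brute_force_oracle(self, arena, assignment, walk_factory):
        traj = walk_factory(n=1000, seed=17, step_sd=3.0, dropout_p=0.05)
        occ = occupancy(traj, assignment, arena, (0.0, 50.0))
        oracle = occupancy_oracle(traj, assignment, arena, (0.0, 50.0))
        for r in ROLES:
            assert occ.fraction[r] == pytest.approx(oracle[r], abs=1e-12)

    def test_fractions_and_seconds_consistent(self, arena, assignment, walk_factory):
        traj = walk_factory(n=500, seed=3, step_sd=3.0)
        occ = occupancy(traj, assignment, arena, (0.0, 25.0))
        assert sum(occ.fraction.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(occ.seconds.values()) == pytest.approx(occ.valid_time_s, abs=1e-9)

    def test_empty_window_raises(self, arena, assignment, walk_factory):
        traj = walk_factory(n=100)
        with pytest.raises(EmptyWindowError):
            occupancy(traj, assignment, arena, (100.0, 200.0))


class TestSilentVsOther:
    @pytest.mark.parametrize(
        "fracs,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), (0.25, 0.25)),
            ((0.46, 0.18, 0.18, 0.18), (0.46, 0.18)),
            ((1.0, 0.0, 0.0, 0.0), (1.0, 0.0)),
        ],
    )
    def test_examples(self, fracs, expected):
        occ = OccupancyResult(
            phase="exposure",
            seconds={r: f * 100 for r, f in zip(ROLES, fracs)},
            fraction=dict(zip(ROLES, fracs)),
            valid_time_s=100.0,
        )
        silent, tone_mean = silent_vs_other(occ)
        assert silent == pytest.approx(expected[0])
        assert tone_mean == pytest.approx(expected[1])


def _occ(phase, fracs):
    return OccupancyResult(
        phase=phase,
        seconds={r: f for r, f in zip(ROLES, fracs)},
        fraction=dict(zip(ROLES, fracs)),
        valid_time_s=1.0,
    )


class TestPreferenceIndex:
    def test_identical_phases_all_zero(self):
        pref = preference_index(
            _occ("exposure", (0.25,) * 4), _occ("habituation", (0.25,) * 4)
        )
        assert all(v == 0.0 for v in pref.values())

    def test_reported_silent_enrichment(self):
        """Baseline ~25% per quadrant rising to ~46% in silence gives a +21
        point preference for silence and -7 for each tone quadrant."""
        pref = preference_index(
            _occ("exposure", (0.46, 0.18, 0.18, 0.18)),
            _occ("habituation", (0.25, 0.25, 0.25, 0.25)),
        )
        assert pref["Q1"] == pytest.approx(21.0)
        for r in ("Q2", "Q3", "Q4"):
            assert pref[r] == pytest.approx(-7.0)

    def test_components_sum_to_zero(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.dirichlet(np.ones(4))
            b = rng.dirichlet(np.ones(4))
            pref = preference_index(_occ("exposure", a), _occ("habituation", b))
            assert sum(pref.values()) == pytest.approx(0.0, abs=1e-9)

    def test_phase_mismatch_raises(self):
        with pytest.raises(PairingError):
            preference_index(_occ("exposure", (0.25,) * 4), _occ("exposure", (0.25,) * 4))


class TestBinnedTimecourse:
    def test_default_schedule_has_one_plus_six_bins(self, arena, assignment, schedule):
        traj = random_walk_trajectory(int(2100 * arena.fps), arena, seed=1, step_sd=3.0)
        tc = binned_timecourse(traj, assignment, arena, schedule)
        assert len(tc.bin_edges_s) - 1 == 7
        assert tc.n_habituation_bins == 1
        assert not tc.truncated_last_bin

    def test_constant_position_every_bin_pure(self, arena, assignment):
        sched = PhaseSchedule(habituation_s=10.0, exposure_s=60.0)
        n = int(70 * arena.fps)
        traj = Trajectory(
            time_s=np.arange(n) / arena.fps,
            x_cm=np.full(n, 33.0),
            y_cm=np.full(n, 33.0),
            valid=np.ones(n, bool),
        )
        tc = binned_timecourse(traj, assignment, arena, sched, bin_s=20.0)
        assert np.allclose(tc.fractions["Q4"], 1.0)  # D is Q4's corner here
        for r in ("Q1", "Q2", "Q3"):
            assert np.allclose(tc.fractions[r], 0.0)

    def test_per_bin_fractions_sum_to_one(self, arena, assignment, schedule):
        traj = random_walk_trajectory(int(2100 * arena.fps), arena, seed=2, step_sd=3.0)
        tc = binned_timecourse(traj, assignment, arena, schedule)
        total = sum(tc.fractions[r] for r in ROLES)
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_time_weighted_bins_equal_whole_exposure(self, arena, assignment, schedule):
        """Concatenation identity: the frame-weighted mean of the exposure
        bins reproduces whole-exposure occupancy."""
        traj = random_walk_trajectory(int(2100 * arena.fps), arena, seed=3, step_sd=3.0)
        tc = binned_timecourse(traj, assignment, arena, schedule)
        occ = occupancy(traj, assignment, arena, schedule.exposure_window)
        for r in ROLES:
            assert tc.fractions[r][1:].mean() == pytest.approx(occ.fraction[r], abs=1e-9)

    def test_truncated_last_bin_flagged(self, arena, assignment):
        sched = PhaseSchedule(habituation_s=10.0, exposure_s=50.0)
        traj = random_walk_trajectory(int(60 * arena.fps), arena, seed=4, step_sd=3.0)
        tc = binned_timecourse(traj, assignment, arena, sched, bin_s=20.0)
        assert tc.truncated_last_bin

    def test_nonpositive_bin_raises(self, arena, assignment, schedule, walk_factory):
        with pytest.raises(ParameterError):
            binned_timecourse(walk_factory(100), assignment, arena, schedule, bin_s=0)


class TestAUC:
    def _tc(self, fractions):
        from soundarena.metrics import BinnedTimeCourse

        k = len(fractions)
        edges = np.concatenate([[0.0, 300.0], 300.0 + 300.0 * np.arange(1, k + 1)])
        q1 = np.concatenate([[0.25], fractions])
        other = (1 - q1) / 3
        return BinnedTimeCourse(
            bin_edges_s=edges,
            fractions={"Q1": q1, "Q2": other, "Q3": other, "Q4": other},
            n_habituation_bins=1,
            truncated_last_bin=False,
        )

    def test_constant_quarter_occupancy(self):
        tc = self._tc([0.25] * 6)
        assert auc(tc, "Q1") == pytest.approx(0.25 * 25.0)

    def test_full_occupancy(self):
        tc = self._tc([1.0] * 6)
        assert auc(tc, "Q1") == pytest.approx(25.0)

    def test_linear_ramp_closed_form(self):
        f = np.linspace(0.0, 1.0, 6)
        tc = self._tc(f)
        mids = np.array([2.5, 7.5, 12.5, 17.5, 22.5, 27.5])
        expected = np.trapezoid(f, mids)  # = mean of interior trapezoids
        assert auc(tc, "Q1") == pytest.approx(expected)
        assert expected == pytest.approx(0.5 * 25.0)  # symmetric ramp

    def test_unknown_role_raises(self):
        with pytest.raises(ParameterError):
            auc(self._tc([0.25] * 6), "Q9")

    def test_alternative_conventions(self):
        tc = self._tc([0.25] * 6)
        # per-bin minutes in quadrant: 0.25 x 5 min over a 25-min span
        assert auc(tc, "Q1", scale="minutes") == pytest.approx(0.25 * 5 * 25)
        # with the habituation bin the midpoint span grows to 30 min
        assert auc(tc, "Q1", include_habituation=True) == pytest.approx(0.25 * 30)


class TestDistance:
    def test_stationary_zero(self, arena, assignment):
        traj = make_traj(["A"] * 10)
        total, per_role = distance_traveled(traj, assignment, arena)
        assert total == 0.0

    def test_straight_path_single_quadrant(self, arena, assignment):
        n = 11
        traj = Trajectory(
            time_s=np.arange(n) / 20.0,
            x_cm=1.0 + np.arange(n),  # 10 cm total, all in the left half
            y_cm=np.full(n, 5.0),
            valid=np.ones(n, bool),
        )
        total, per_role = distance_traveled(traj, assignment, arena)
        assert total == pytest.approx(10.0)
        assert per_role["Q1"] == pytest.approx(10.0)
        assert per_role["Q2"] == per_role["Q3"] == per_role["Q4"] == 0.0

    def test_matches_pairwise_oracle(self, arena, assignment, walk_factory):
        traj = walk_factory(n=1000, seed=23, step_sd=1.0, dropout_p=0.05)
        total, per_role = distance_traveled(traj, assignment, arena, max_speed_cm_s=1e9)
        idx = np.nonzero(traj.valid)[0]
        brute = sum(
            np.hypot(
                traj.x_cm[j] - traj.x_cm[i], traj.y_cm[j] - traj.y_cm[i]
            )
            for i, j in zip(idx, idx[1:])
        )
        assert total == pytest.approx(brute, abs=1e-9)
        assert sum(per_role.values()) == pytest.approx(total, abs=1e-9)

    def test_speed_filter_drops_artifact_jumps(self, arena, assignment):
        traj = Trajectory(
            time_s=np.arange(4) / 20.0,
            x_cm=np.array([1.0, 2.0, 40.0, 41.0]),  # 38 cm in 50 ms: artifact
            y_cm=np.full(4, 5.0),
            valid=np.ones(4, bool),
        )
        total, _ = distance_traveled(traj, assignment, arena)
        assert total == pytest.approx(2.0)

    def test_too_few_valid_frames(self, arena, assignment):
        traj = make_traj(["A", "B"])
        traj.valid[1] = False
        with pytest.raises(InputError):
            distance_traveled(traj, assignment, arena)


class TestHeatmap:
    def test_point_mass(self, arena):
        traj = make_traj(["A"] * 40)
        h, _, _ = heatmap(traj, arena)
        assert np.count_nonzero(h) == 1
        assert h.sum() == pytest.approx(40 / 20.0)

    def test_mass_equals_valid_time(self, arena, assignment, walk_factory):
        traj = walk_factory(n=800, seed=31, step_sd=3.0, dropout_p=0.1)
        h, _, _ = heatmap(traj, arena)
        occ = occupancy(traj, assignment, arena, (0.0, 40.0))
        assert h.sum() == pytest.approx(occ.valid_time_s, abs=1e-9)

    def test_uniform_coverage_cv_shrinks(self, arena):
        """Cell coefficient of variation decreases as frames accumulate."""
        rng = np.random.default_rng(11)

        def cv(n):
            traj = Trajectory(
                time_s=np.arange(n) / 20.0,
                x_cm=rng.uniform(0, 44, n),
                y_cm=rng.uniform(0, 44, n),
                valid=np.ones(n, bool),
            )
            h, _, _ = heatmap(traj, arena, bin_cm=11.0)
            return h.std() / h.mean()

        assert cv(40_000) < cv(2_000)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 100_000))
def test_conservation_properties(seed):
    """Fractions sum to 1, preference indices to 0, heat-map mass to valid
    time, for random trajectories."""
    arena = ArenaSpec()
    assignment = make_assignment("C")
    traj = random_walk_trajectory(600, arena, seed=seed, step_sd=4.0, dropout_p=0.1)
    try:
        occ_h = occupancy(traj, assignment, arena, (0.0, 10.0), "habituation")
        occ_e = occupancy(traj, assignment, arena, (10.0, 30.0), "exposure")
    except EmptyWindowError:
        return
    assert sum(occ_h.fraction.values()) == pytest.approx(1.0, abs=1e-9)
    pref = preference_index(occ_e, occ_h)
    assert sum(pref.values()) == pytest.approx(0.0, abs=1e-9)
    h, _, _ = heatmap(traj, arena)
    total_valid = traj.valid.sum() * traj.median_dt
    assert h.sum() == pytest.approx(total_valid, abs=1e-9)
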