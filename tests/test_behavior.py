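"""Task geometry, filtering, segmentation, classification and the synthetic
session generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, freqz

import reachplan as rp
from reachplan.behavior import (
    TrialRecord,
    count_velocity_peaks,
    tangential_speed,
    threshold_duration_fraction,
)


def min_jerk_trial(duration=0.8, amplitude=0.15, fs=500.0, pad_s=0.3, angle=0.3):
    """Noise-free minimum-jerk trial with quiescent padding."""
    n = int(round(duration * fs)) + 1
    s = np.linspace(0, 1, n)
    sigma = 10 * s**3 - 15 * s**4 + 6 * s**5
    d = amplitude * np.array([np.cos(angle), np.sin(angle)])
    move = np.outer(sigma, d)
    npad = int(round(pad_s * fs))
    xy = np.concatenate(
        [np.zeros((npad, 2)), move, np.tile(move[-1], (npad, 1))]
    )
    t = np.arange(len(xy)) / fs
    return TrialRecord(t=t, x=xy[:, 0], y=xy[:, 1], fs=fs)


class TestTaskGeometry:
    def test_front_target_is_straight_ahead(self, subject_a_front):
        params, _ = subject_a_front
        task = rp.task_geometry("front", 8.0, params)
        start_xy = rp.forward_kinematics(params, task.start_angles)
        assert np.allclose(
            np.asarray(task.target_xy) - start_xy, [0.0, 0.150], atol=1e-12
        )
        assert task.tolerance == pytest.approx(0.008)
        assert np.allclose(np.rad2deg(task.start_angles), [58.0, 96.0])

    def test_back_and_front_are_reflections(self, subject_a_front):
        params, _ = subject_a_front
        front = rp.task_geometry("front", 8.0, params)
        back = rp.task_geometry("back", 8.0, params)
        start_xy = rp.forward_kinematics(params, front.start_angles)
        assert np.allclose(
            np.asarray(front.target_xy) - start_xy,
            -(np.asarray(back.target_xy) - start_xy),
            atol=1e-12,
        )

    def test_all_directions_reachable_every_subject(self):
        for subj in "ABCDEF":
            for direction in ("front", "back", "left", "right"):
                params, _ = rp.load_subject_parameters(subj, direction)
                task = rp.task_geometry(direction, 8.0, params)
                assert np.hypot(*task.target_xy) <= params.L1 + params.L2

    def test_unknown_direction_rejected(self, subject_a_front):
        params, _ = subject_a_front
        with pytest.raises(KeyError):
            rp.task_geometry("diagonal", 8.0, params)


class TestFilterPositions:
    def test_constant_series_unchanged(self):
        x = np.full(300, 0.123)
        assert np.allclose(rp.filter_positions(x, 500.0), x, atol=1e-12)

    @pytest.mark.parametrize("freq,fs", [(1.0, 500.0), (50.0, 500.0)])
    def test_transfer_function_oracle(self, freq, fs):
        # forward-backward filtering applies the squared magnitude response
        t = np.arange(int(fs * 4)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = rp.filter_positions(x, fs)
        b, a = butter(3, 10.0 / (fs / 2))
        _, h = freqz(b, a, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        measured = y[mid].std() / x[mid].std()
        assert measured == pytest.approx(expected, rel=0.01, abs=1e-4)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            rp.filter_positions(np.zeros(10), 500.0)


class TestSegmentMovement:
    def test_recovers_quintic_threshold_crossings(self):
        """The 5%-of-peak crossings of the quintic speed profile have a
        closed form: 30 s^2 (1-s)^2 = 0.05 * 1.875, giving s in {0.0594,
        0.9406}; the segmented duration is their span times D."""
        D = 0.8
        roots = np.roots([30, -60, 30, 0, -0.05 * 1.875])
        s_cross = np.sort(roots[np.isreal(roots)].real)
        s_lo = s_cross[(s_cross > 0) & (s_cross < 0.5)][0]
        expected = (1 - 2 * s_lo) * D
        trial = min_jerk_trial(duration=D)
        _, _, dur = rp.segment_movement(trial)
        assert dur == pytest.approx(expected, abs=0.02)

    def test_stationary_trial_rejected(self):
        t = np.arange(500) / 500.0
        trial = TrialRecord(t=t, x=np.zeros(500), y=np.zeros(500), fs=500.0)
        with pytest.raises(ValueError):
            rp.segment_movement(trial)

    def test_time_shift_equivariance(self):
        trial = min_jerk_trial()
        t0, t1, dur = rp.segment_movement(trial)
        shifted = TrialRecord(
            t=trial.t + 0.5, x=trial.x, y=trial.y, fs=trial.fs
        )
        s0, s1, sdur = rp.segment_movement(shifted)
        assert s0 == pytest.approx(t0 + 0.5, abs=1e-9)
        assert s1 == pytest.approx(t1 + 0.5, abs=1e-9)
        assert sdur == pytest.approx(dur, abs=1e-9)

    @given(
        phi=st.floats(min_value=-np.pi, max_value=np.pi),
        dx=st.floats(min_value=-0.5, max_value=0.5),
    )
    @settings(max_examples=15, deadline=None)
    def test_rigid_motion_invariance(self, phi, dx):
        """Rotating and translating a trial leaves its segmentation fixed."""
        trial = min_jerk_trial()
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        xy = np.column_stack([trial.x, trial.y]) @ R.T + [dx, 0.1]
        moved = TrialRecord(t=trial.t, x=xy[:, 0], y=xy[:, 1], fs=trial.fs)
        _, _, d0 = rp.segment_movement(trial)
        _, _, d1 = rp.segment_movement(moved)
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestClassifyTrial:
    def test_planner_trial_succeeds(self, subject_a_front, front_task):
        params, _ = subject_a_front
        traj, _, _ = rp.plan_min_torque_change(params, front_task, 0.8)
        xy = rp.forward_kinematics(params, traj.theta)
        npad = 150
        full = np.concatenate(
            [np.tile(xy[0], (npad, 1)), xy, np.tile(xy[-1], (npad, 1))]
        )
        t = np.arange(len(full)) / 500.0
        trial = TrialRecord(t=t, x=full[:, 0], y=full[:, 1], fs=500.0)
        rp.segment_movement(trial)
        result = rp.classify_trial(trial, front_task)
        assert result.success and result.analyzable

    def test_corrective_submovement_fails(self, subject_a_front, front_task):
        # inject a second velocity bump (20% of peak) after the main reach
        params, _ = subject_a_front
        trial = min_jerk_trial(duration=0.8, amplitude=0.15, angle=np.pi / 2)
        n = int(0.3 * 500)
        s = np.linspace(0, 1, n)
        sigma = 10 * s**3 - 15 * s**4 + 6 * s**5
        bump = np.zeros_like(trial.y)
        i0 = len(trial.y) - n - 30
        bump[i0 : i0 + n] = 0.018 * sigma
        bump[i0 + n :] = 0.018
        trial.y = trial.y + bump
        rp.segment_movement(trial)
        assert count_velocity_peaks(trial) > 1
        start_xy = rp.forward_kinematics(params, front_task.start_angles)
        shifted = TrialRecord(
            t=trial.t, x=trial.x + start_xy[0], y=trial.y + start_xy[1],
            fs=trial.fs,
        )
        rp.segment_movement(shifted)
        result = rp.classify_trial(shifted, front_task)
        assert not result.success
        assert result.reason == "multi-peak"
        assert not result.analyzable

    def test_near_miss_still_analyzable(self, subject_a_front):
        # endpoint 1 mm outside an 8 mm target: failure, but the duration
        # still enters the analysis
        params, _ = subject_a_front
        task = rp.task_geometry("front", 8.0, params)
        start_xy = rp.forward_kinematics(params, task.start_angles)
        trial = min_jerk_trial(duration=0.8, amplitude=0.159, angle=np.pi / 2)
        moved = TrialRecord(
            t=trial.t, x=trial.x + start_xy[0], y=trial.y + start_xy[1],
            fs=trial.fs,
        )
        rp.segment_movement(moved)
        result = rp.classify_trial(moved, task)
        assert not result.success
        assert result.reason == "endpoint-outside-target"
        assert result.analyzable

    def test_unsegmented_trial_rejected(self, subject_a_front, front_task):
        trial = min_jerk_trial()
        with pytest.raises(ValueError):
            rp.classify_trial(trial, front_task)


@pytest.fixture(scope="module")
def session(subject_a_front):
    params, k = subject_a_front
    return params, k, rp.generate_synthetic_session(
        params, k, lam=1.44e6,
        conditions=[("front", 8.0), ("front", 15.0), ("front", 25.0)],
        n_per_condition=100, seed=31,
    )


class TestSyntheticSession:

    def test_segmentation_recovers_ground_truth(self, session):
        _, _, trials = session
        errs = []
        for tr in trials:
            rp.segment_movement(tr)
            errs.append(abs(tr.duration - tr.truth["duration_s"]))
        assert np.median(errs) < 0.05

    def test_success_rate_increases_with_tolerance(self, session):
        params, _, trials = session
        rates = {}
        for tr in trials:
            if tr.duration is None:
                rp.segment_movement(tr)
            c = rp.classify_trial(
                tr, rp.task_geometry(tr.direction, tr.tolerance_mm, params)
            )
            rates.setdefault(tr.tolerance_mm, []).append(c.success)
        r = {tol: np.mean(v) for tol, v in rates.items()}
        assert r[8.0] < r[25.0]
        assert r[8.0] <= r[15.0] <= 1.0

    def test_noise_free_sessions_always_succeed(self, subject_a_front):
        params, _ = subject_a_front
        trials = rp.generate_synthetic_session(
            params, rp.NoiseParameters(0, 0), lam=1.44e6,
            conditions=[("front", 8.0)], n_per_condition=5, seed=2,
            jitter_sd=1e-6,
        )
        for tr in trials:
            rp.segment_movement(tr)
            c = rp.classify_trial(
                tr, rp.task_geometry("front", 8.0, params)
            )
            assert c.success

    def test_threshold_fraction_near_quintic_value(
        self, subject_a_front, normalized_plan
    ):
        # the planned bell speed is close to quintic: crossing span ~ 0.88
        params, _ = subject_a_front
        nt, _ = normalized_plan
        frac = threshold_duration_fraction(params, nt)
        assert 0.82 < frac < 0.93

    def test_trials_sampled_at_500hz_with_padding(self, session):
        _, _, trials = session
        tr = trials[0]
        assert tr.fs == 500.0
        assert np.allclose(np.diff(tr.t), 1 / 500.0)
        assert tr.t[-1] >= tr.truth["planned_duration_s"] + 0.6 - 2e-3
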