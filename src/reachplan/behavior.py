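"""Task geometry, trial preprocessing, trial classification and a synthetic
motion-capture session generator.

Measured-style trials are hand-position time series at 500 Hz.  Preprocessing
follows the standard pipeline for reaching data: zero-phase low-pass
filtering, tangential velocity by numerical differentiation, and movement
segmentation at 5% of the peak tangential velocity.  The synthetic generator
replays the full planning-plus-noise model (per-draw optimal duration,
signal-dependent torque noise through the forward dynamics) so that the
analysis chain can be validated against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from .arm import (
    DIRECTION_ANGLES,
    ArmParameters,
    NoiseParameters,
    TaskSpec,
    TorqueProfile,
    _integrate_batch,
    commanded_torque,
    forward_kinematics,
)
from .planner import PlannerConfig, normalized_trajectory, rescale_trajectory
from .duration import (
    D_BOUNDS_DEFAULT,
    RpropConfig,
    _rprop_batch,
    compute_a,
    compute_mu,
)
from .noise import sample_gamma

#: start posture common to all tasks: (shoulder, elbow) in degrees
START_ANGLES_DEG = (58.0, 96.0)

#: reach amplitude, m
REACH_DISTANCE = 0.150

SAMPLING_RATE_HZ = 500.0


@dataclass
class TrialRecord:
    """One trial's hand-position time series plus condition metadata."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float
    direction: str = ""
    tolerance_mm: float = np.nan
    truth: dict = field(default_factory=dict)
    t_start: float | None = None
    t_end: float | None = None
    duration: float | None = None
    success: bool | None = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time stamps must be strictly increasing")


def task_geometry(
    direction: str, tolerance_mm: float, params: ArmParameters
) -> TaskSpec:
    """Build the standard reaching task: start posture (58, 96) deg, target
    150 mm away along the direction angle, tolerance radius in mm."""
    if direction not in DIRECTION_ANGLES:
        raise KeyError(f"unknown direction {direction!r}")
    if tolerance_mm <= 0:
        raise ValueError("tolerance must be positive")
    start = np.deg2rad(START_ANGLES_DEG)
    start_xy = forward_kinematics(params, start)
    phi = DIRECTION_ANGLES[direction]
    target = start_xy + REACH_DISTANCE * np.array([np.cos(phi), np.sin(phi)])
    task = TaskSpec(
        start_angles=tuple(start),
        target_xy=tuple(target),
        tolerance=tolerance_mm * 1e-3,
        direction_label=direction,
    )
    task.validate_reachable(params)
    return task


# ---------------------------------------------------------------------------
# preprocessing and segmentation
# ---------------------------------------------------------------------------

def filter_positions(
    series: np.ndarray, fs: float, cutoff_hz: float = 10.0, order: int = 3
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    series = np.asarray(series, dtype=float)
    if series.shape[0] <= 6 * order:
        raise ValueError("series too short to filter")
    b, a = butter(order, cutoff_hz / (fs / 2.0))
    return filtfilt(b, a, series, axis=0)


def tangential_speed(trial: TrialRecord, prefiltered: bool = False) -> np.ndarray:
    """Hand speed from (optionally filtered) positions, central differences."""
    xy = np.column_stack([trial.x, trial.y])
    if not prefiltered:
        xy = filter_positions(xy, trial.fs)
    dt = 1.0 / trial.fs
    v = np.gradient(xy, dt, axis=0)
    return np.hypot(v[:, 0], v[:, 1])


def segment_movement(
    trial: TrialRecord,
    threshold_frac: float = 0.05,
    prefiltered: bool = False,
    min_peak_speed: float = 0.01,
):
    """Movement onset/offset at threshold_frac of peak tangential velocity.

    Onset is the first sample at or above the threshold, offset the last; the
    duration is their difference.  ``min_peak_speed`` (m/s) rejects trials
    with no detectable movement.  Results are stored on the trial and
    returned as (t_start, t_end, duration).
    """
    v = tangential_speed(trial, prefiltered=prefiltered)
    peak = float(v.max())
    if peak < min_peak_speed:
        raise ValueError("tangential velocity never exceeds the threshold")
    thr = threshold_frac * peak
    above = np.flatnonzero(v >= thr)
    i0, i1 = above[0], above[-1]
    trial.t_start = float(trial.t[i0])
    trial.t_end = float(trial.t[i1])
    trial.duration = trial.t_end - trial.t_start
    if trial.duration <= 0:
        raise ValueError("degenerate segmentation")
    return trial.t_start, trial.t_end, trial.duration


def count_velocity_peaks(
    trial: TrialRecord,
    prominence_frac: float = 0.05,
    prefiltered: bool = False,
) -> int:
    """Local maxima of the segmented speed profile above a prominence floor."""
    if trial.t_start is None:
        raise ValueError("segment the trial first")
    v = tangential_speed(trial, prefiltered=prefiltered)
    sel = (trial.t >= trial.t_start) & (trial.t <= trial.t_end)
    vseg = v[sel]
    peaks, _ = find_peaks(vseg, prominence=prominence_frac * vseg.max())
    # a monotone-free bell has its max in the interior; ensure at least 1
    return max(int(len(peaks)), 1 if vseg.max() > 0 else 0)


@dataclass(frozen=True)
class Classification:
    success: bool
    reason: str
    analyzable: bool   # single-peak trials enter the duration analysis


def classify_trial(trial: TrialRecord, task: TaskSpec) -> Classification:
    """Success = endpoint within tolerance AND a single-peak speed profile.

    Trials failing only the endpoint criterion remain analyzable (their
    durations are still used); multi-peak trials indicate corrective
    submovements and are excluded entirely.
    """
    if trial.t_start is None:
        raise ValueError("segment the trial before classification")
    n_peaks = count_velocity_peaks(trial)
    idx_end = int(np.searchsorted(trial.t, trial.t_end))
    idx_end = min(idx_end, len(trial.t) - 1)
    endpoint = np.array([trial.x[idx_end], trial.y[idx_end]])
    dist = float(np.hypot(*(endpoint - np.asarray(task.target_xy))))
    if n_peaks > 1:
        return Classification(False, "multi-peak", False)
    if dist > task.tolerance:
        return Classification(False, "endpoint-outside-target", True)
    return Classification(True, "ok", True)


def threshold_duration_fraction(
    params: ArmParameters, norm_traj, threshold_frac: float = 0.05
) -> float:
    """Fraction of the planned duration between the 5%-of-peak crossings.

    Segmented (measured-style) durations are systematically shorter than the
    planned duration because the speed tails below threshold are cut off;
    this factor converts planned durations to the segmentation convention.
    """
    from .planner import tangential_velocity

    v = tangential_velocity(params, norm_traj)
    thr = threshold_frac * v.max()
    above = np.flatnonzero(v >= thr)
    s = np.linspace(0.0, 1.0, len(v))
    return float(s[above[-1]] - s[above[0]])


# ---------------------------------------------------------------------------
# synthetic session generator
# ---------------------------------------------------------------------------

def generate_synthetic_session(
    params: ArmParameters,
    k: NoiseParameters,
    lam: float,
    conditions,
    n_per_condition: int = 32,
    seed: int = 0,
    planner_config: PlannerConfig | None = None,
    d_bounds=D_BOUNDS_DEFAULT,
    pad_s: float = 0.3,
    jitter_sd: float = 1e-4,
) -> list[TrialRecord]:
    """Simulate a session of reaching trials with known ground truth.

    ``conditions`` is an iterable of (direction, tolerance_mm).  Per trial a
    gamma draw fixes the planned duration D* (Rprop), the normalized plan is
    rescaled to D*, signal-dependent torque noise is added and replayed
    through the forward dynamics, and the hand path is emitted at 500 Hz with
    quiescent, slightly jittered padding before and after the movement.
    Ground truth stores the planned duration and its threshold-convention
    equivalent (the quantity movement segmentation estimates).
    """
    rng = np.random.default_rng(seed)
    mu = compute_mu(d_bounds)
    trials: list[TrialRecord] = []
    rcfg = RpropConfig()
    norm_cache: dict = {}
    for direction, tol_mm in conditions:
        if direction not in norm_cache:
            task0 = task_geometry(direction, 8.0, params)
            norm_traj, norm_tau = normalized_trajectory(
                params, task0, planner_config, mu=mu
            )
            norm_cache[direction] = (
                norm_traj,
                norm_tau,
                compute_a(norm_tau),
                threshold_duration_fraction(params, norm_traj),
            )
        norm_traj, norm_tau, a, frac = norm_cache[direction]
        task = task_geometry(direction, tol_mm, params)
        gammas = sample_gamma(
            params, norm_traj, norm_tau, k, n_per_condition,
            rng.integers(2**31),
        )
        d_star, _, _ = _rprop_batch(
            a, gammas, lam, task.tolerance, d_bounds, rcfg
        )
        n = norm_traj.n_samples
        # batched noisy replay on each trial's own movement grid
        taus = np.empty((n_per_condition, n, 2))
        dts = np.empty((n_per_condition, 1))
        for j, D in enumerate(d_star):
            traj = rescale_trajectory(norm_traj, float(D))
            tau = commanded_torque(
                params, traj.theta, traj.theta_dot, traj.theta_ddot
            )
            sd = k.k * np.abs(tau)
            taus[j] = tau + rng.standard_normal((n, 2)) * sd
            dts[j] = D / (n - 1)
        theta0 = np.repeat(norm_traj.theta[:1], n_per_condition, axis=0)
        thetad0 = np.zeros_like(theta0)
        th, _ = _integrate_batch(params, taus, theta0, thetad0, dts)
        xy = forward_kinematics(params, th)   # (m, n, 2)

        n_pad = int(round(pad_s * SAMPLING_RATE_HZ))
        for j in range(n_per_condition):
            D = float(d_star[j])
            t_move = np.linspace(0.0, D, n)
            t_out = np.arange(0.0, D + 0.5 / SAMPLING_RATE_HZ, 1.0 / SAMPLING_RATE_HZ)
            x_mv = np.interp(t_out, t_move, xy[j, :, 0])
            y_mv = np.interp(t_out, t_move, xy[j, :, 1])
            x = np.concatenate(
                [
                    np.full(n_pad, x_mv[0]) + rng.normal(0, jitter_sd, n_pad),
                    x_mv,
                    np.full(n_pad, x_mv[-1]) + rng.normal(0, jitter_sd, n_pad),
                ]
            )
            y = np.concatenate(
                [
                    np.full(n_pad, y_mv[0]) + rng.normal(0, jitter_sd, n_pad),
                    y_mv,
                    np.full(n_pad, y_mv[-1]) + rng.normal(0, jitter_sd, n_pad),
                ]
            )
            t = np.arange(len(x)) / SAMPLING_RATE_HZ
            trials.append(
                TrialRecord(
                    t=t, x=x, y=y, fs=SAMPLING_RATE_HZ,
                    direction=direction, tolerance_mm=float(tol_mm),
                    truth={
                        "planned_duration_s": D,
                        "duration_s": frac * D,
                        "gamma": float(gammas[j]),
                    },
                )
            )
    return trials


def session_duration_table(trials, stat: str = "mean"):
    """Aggregate segmented durations into a (direction, tolerance) table."""
    import pandas as pd

    rows = []
    for tr in trials:
        if tr.duration is None:
            segment_movement(tr)
        rows.append(
            {"direction": tr.direction, "tolerance_mm": tr.tolerance_mm,
             "duration_s": tr.duration}
        )
    df = pd.DataFrame(rows)
    agg = (
        df.groupby(["direction", "tolerance_mm"])["duration_s"]
        .agg([stat, "count"])
        .reset_index()
        .rename(columns={stat: "mean_duration_s", "count": "n"})
    )
    return agg
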