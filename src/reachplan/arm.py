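"""Two-link planar arm: kinematics, rigid-body dynamics, subject parameters.

The arm moves in the horizontal plane (air-sled support), so there is no
gravity term.  Joint torques obey

    tau = M(theta) theta_dd + h1(theta) [th1d*th2d] + h2(theta) [th1d^2, th2d^2]
          + B theta_d

with the inertia matrix M, Coriolis vector coefficient h1, centrifugal
coefficient matrix h2 and a constant joint-viscosity matrix B.  Shoulder is
the origin of the task frame; x points to the subject's right, y forward.
All angles are radians, lengths metres, torques N*m.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

DIRECTIONS = ("front", "back", "left", "right")

#: direction label -> reach angle in the task frame (rad)
DIRECTION_ANGLES = {
    "right": 0.0,
    "front": np.pi / 2,
    "left": np.pi,
    "back": 3 * np.pi / 2,
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmParameters:
    """Physical parameters of one subject's two-link arm.

    ``L``: link lengths, ``S``: joint-to-centre-of-mass distances, ``m``:
    link masses, ``I``: moments of inertia *about the joint*, ``B``: 2x2
    joint viscosity matrix (kg m^2/s).  ``direction_label`` records which
    movement direction the viscosity block was estimated for.
    """

    L1: float
    L2: float
    S1: float
    S2: float
    m1: float
    m2: float
    I1: float
    I2: float
    B: np.ndarray
    subject_id: str = ""
    direction_label: str = ""

    def __post_init__(self):
        for name in ("L1", "L2", "S1", "S2", "m1", "m2", "I1", "I2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.S1 >= self.L1 or self.S2 >= self.L2:
            raise ValueError("centre-of-mass distances must satisfy S_i < L_i")
        B = np.asarray(self.B, dtype=float)
        if B.shape != (2, 2):
            raise ValueError("B must be 2x2")
        if not np.allclose(B, B.T):
            raise ValueError("B must be symmetric")
        if np.any(np.linalg.eigvalsh(B) <= 0):
            raise ValueError("B must be positive definite")
        object.__setattr__(self, "B", B)


@dataclass(frozen=True)
class NoiseParameters:
    """Signal-dependent noise coefficients (dimensionless, one per joint)."""

    k1: float
    k2: float

    def __post_init__(self):
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("noise coefficients must be non-negative")

    @property
    def k(self) -> np.ndarray:
        return np.array([self.k1, self.k2])


@dataclass
class JointTrajectory:
    """Sampled joint-space trajectory.

    ``normalized`` distinguishes a movement indexed by real time t in
    [0, duration] from one indexed by s = t/D in [0, 1] (duration 1.0);
    derivative arrays are with respect to the running index either way.
    """

    theta: np.ndarray       # (n, 2) joint angles
    theta_dot: np.ndarray   # (n, 2)
    theta_ddot: np.ndarray  # (n, 2)
    duration: float
    normalized: bool = False

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        self.theta_dot = np.atleast_2d(np.asarray(self.theta_dot, dtype=float))
        self.theta_ddot = np.atleast_2d(np.asarray(self.theta_ddot, dtype=float))
        if not (self.theta.shape == self.theta_dot.shape == self.theta_ddot.shape):
            raise ValueError("angle/velocity/acceleration arrays must share a shape")
        if self.n_samples < 3:
            raise ValueError("a trajectory needs at least 3 samples")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        return self.theta.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.duration, self.n_samples)


@dataclass
class TorqueProfile:
    """Sampled joint-torque profile matching a :class:`JointTrajectory`."""

    tau: np.ndarray  # (n, 2)
    duration: float
    normalized: bool = False

    def __post_init__(self):
        self.tau = np.atleast_2d(np.asarray(self.tau, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.tau.shape[0]


@dataclass(frozen=True)
class TaskSpec:
    """One reaching task: start posture, target point and tolerance radius."""

    start_angles: tuple  # (theta1, theta2) rad
    target_xy: tuple     # (x, y) m, shoulder at origin
    tolerance: float     # W*, m
    direction_label: str = ""

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def validate_reachable(self, params: ArmParameters) -> None:
        r = float(np.hypot(*self.target_xy))
        if r > params.L1 + params.L2:
            raise ValueError("target outside the arm's reach")


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def forward_kinematics(params: ArmParameters, angles) -> np.ndarray:
    """Hand position (x, y) for joint angles; supports (..., 2) arrays."""
    angles = np.asarray(angles, dtype=float)
    t1 = angles[..., 0]
    t12 = angles[..., 0] + angles[..., 1]
    x = params.L1 * np.cos(t1) + params.L2 * np.cos(t12)
    y = params.L1 * np.sin(t1) + params.L2 * np.sin(t12)
    return np.stack([x, y], axis=-1)


def jacobian(params: ArmParameters, angles) -> np.ndarray:
    """2x2 Jacobian d(x, y)/d(theta1, theta2) at one posture (or (...,2,2))."""
    angles = np.asarray(angles, dtype=float)
    t1 = angles[..., 0]
    t12 = angles[..., 0] + angles[..., 1]
    j11 = -params.L1 * np.sin(t1) - params.L2 * np.sin(t12)
    j12 = -params.L2 * np.sin(t12)
    j21 = params.L1 * np.cos(t1) + params.L2 * np.cos(t12)
    j22 = params.L2 * np.cos(t12)
    return np.stack(
        [np.stack([j11, j12], axis=-1), np.stack([j21, j22], axis=-1)], axis=-2
    )


def inverse_kinematics(params: ArmParameters, xy, elbow_sign: float = 1.0) -> np.ndarray:
    """Joint angles reaching hand point ``xy``; elbow_sign picks the branch."""
    x, y = float(xy[0]), float(xy[1])
    r2 = x * x + y * y
    c2 = (r2 - params.L1**2 - params.L2**2) / (2 * params.L1 * params.L2)
    if c2 > 1 + 1e-12 or c2 < -1 - 1e-12:
        raise ValueError("hand point is outside the reachable annulus")
    c2 = np.clip(c2, -1.0, 1.0)
    t2 = np.sign(elbow_sign) * np.arccos(c2)
    t1 = np.arctan2(y, x) - np.arctan2(
        params.L2 * np.sin(t2), params.L1 + params.L2 * np.cos(t2)
    )
    return np.array([t1, t2])


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def mass_matrix(params: ArmParameters, angles) -> np.ndarray:
    """Configuration-dependent inertia matrix M(theta), shape (..., 2, 2)."""
    angles = np.asarray(angles, dtype=float)
    c2 = np.cos(angles[..., 1])
    a = params.m2 * params.L1 * params.S2
    m11 = params.I1 + params.I2 + params.m2 * params.L1**2 + 2 * a * c2
    m12 = params.I2 + a * c2
    m22 = np.broadcast_to(params.I2, m11.shape).astype(float)
    return np.stack(
        [np.stack([m11, m12], axis=-1), np.stack([m12, m22], axis=-1)], axis=-2
    )


def commanded_torque(
    params: ArmParameters,
    theta: np.ndarray,
    theta_dot: np.ndarray,
    theta_ddot: np.ndarray,
    b_scale: float = 1.0,
) -> np.ndarray:
    """Inverse dynamics at sample level: tau for (n, 2) kinematic arrays.

    ``b_scale`` multiplies the viscosity matrix; the time-normalized torque
    uses the least-squares coefficient mu here (viscous force scales as 1/D
    rather than 1/D^2, and mu*B/D^2 is its best in-band approximation).
    """
    theta = np.atleast_2d(theta)
    theta_dot = np.atleast_2d(theta_dot)
    theta_ddot = np.atleast_2d(theta_ddot)
    a = params.m2 * params.L1 * params.S2
    s2 = np.sin(theta[:, 1])
    M = mass_matrix(params, theta)                      # (n, 2, 2)
    inertial = np.einsum("nij,nj->ni", M, theta_ddot)
    # Coriolis: cross-product vector [th1d*th2d]; centrifugal: [th1d^2, th2d^2]
    cross = theta_dot[:, 0] * theta_dot[:, 1]
    coriolis = np.stack([-2 * a * s2 * cross, np.zeros_like(cross)], axis=-1)
    centrifugal = np.stack(
        [-a * s2 * theta_dot[:, 1] ** 2, a * s2 * theta_dot[:, 0] ** 2], axis=-1
    )
    viscous = b_scale * theta_dot @ params.B.T
    return inertial + coriolis + centrifugal + viscous


def inverse_dynamics(params: ArmParameters, traj: JointTrajectory) -> TorqueProfile:
    """Joint torques realizing a time-indexed trajectory."""
    if traj.normalized:
        raise ValueError("inverse_dynamics expects a time-indexed trajectory")
    tau = commanded_torque(params, traj.theta, traj.theta_dot, traj.theta_ddot)
    return TorqueProfile(tau=tau, duration=traj.duration, normalized=False)


def _accel(params: ArmParameters, theta, theta_dot, tau):
    """Forward-dynamics right-hand side; batched over leading axis."""
    rhs = tau - commanded_torque(
        params, theta, theta_dot, np.zeros_like(theta)
    )
    M = mass_matrix(params, theta)
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    if np.any(np.abs(det) < 1e-12):
        raise FloatingPointError("inertia matrix numerically singular")
    inv00 = M[..., 1, 1] / det
    inv01 = -M[..., 0, 1] / det
    inv11 = M[..., 0, 0] / det
    a1 = inv00 * rhs[..., 0] + inv01 * rhs[..., 1]
    a2 = inv01 * rhs[..., 0] + inv11 * rhs[..., 1]
    return np.stack([a1, a2], axis=-1)


def _integrate_batch(
    params: ArmParameters,
    tau: np.ndarray,      # (m, n, 2) torque samples on a uniform grid
    theta0: np.ndarray,   # (m, 2)
    theta_dot0: np.ndarray,
    dt,                   # scalar or (m, 1)
):
    """Fixed-step RK4 integration of the arm under sampled torques.

    Torque is linearly interpolated at half steps.  Returns (theta, theta_dot)
    arrays of shape (m, n, 2).
    """
    m, n, _ = tau.shape
    dt = np.asarray(dt, dtype=float).reshape(-1, 1)
    th = np.empty((m, n, 2))
    thd = np.empty((m, n, 2))
    th[:, 0] = theta0
    thd[:, 0] = theta_dot0
    for i in range(n - 1):
        t0 = tau[:, i]
        t1 = tau[:, i + 1]
        th_half = 0.5 * (t0 + t1)
        x, v = th[:, i], thd[:, i]
        k1v = _accel(params, x, v, t0)
        k1x = v
        k2v = _accel(params, x + 0.5 * dt * k1x, v + 0.5 * dt * k1v, th_half)
        k2x = v + 0.5 * dt * k1v
        k3v = _accel(params, x + 0.5 * dt * k2x, v + 0.5 * dt * k2v, th_half)
        k3x = v + 0.5 * dt * k2v
        k4v = _accel(params, x + dt * k3x, v + dt * k3v, t1)
        k4x = v + dt * k3v
        th[:, i + 1] = x + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        thd[:, i + 1] = v + dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return th, thd


def forward_dynamics(
    params: ArmParameters,
    torques: TorqueProfile,
    initial_angles,
    initial_velocities,
) -> JointTrajectory:
    """Integrate the arm under a sampled torque profile (fixed-step RK4)."""
    if torques.normalized:
        raise ValueError("forward_dynamics expects a time-indexed torque profile")
    n = torques.n_samples
    dt = torques.duration / (n - 1)
    th, thd = _integrate_batch(
        params,
        torques.tau[None],
        np.atleast_2d(np.asarray(initial_angles, dtype=float)),
        np.atleast_2d(np.asarray(initial_velocities, dtype=float)),
        dt,
    )
    thdd = _accel(params, th[0], thd[0], torques.tau)
    return JointTrajectory(
        theta=th[0], theta_dot=thd[0], theta_ddot=thdd,
        duration=torques.duration, normalized=False,
    )


# ---------------------------------------------------------------------------
# subject parameter fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("reachplan.data").joinpath(name)


def load_parameter_table(name: str = "arm_parameters.csv") -> pd.DataFrame:
    """Load one of the packaged per-subject parameter tables as a DataFrame."""
    with importlib.resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p)


def load_subject_parameters(
    subject_id: str, direction_label: str
) -> tuple[ArmParameters, NoiseParameters]:
    """Packaged arm-dynamics and noise parameters for one subject/direction."""
    subject_id = subject_id.upper()
    direction_label = direction_label.lower()
    if direction_label not in DIRECTIONS:
        raise KeyError(f"unknown direction {direction_label!r}")
    arm_tab = load_parameter_table("arm_parameters.csv")
    row = arm_tab[(arm_tab.subject == subject_id) & (arm_tab.direction == direction_label)]
    if row.empty:
        raise KeyError(f"unknown subject {subject_id!r}")
    r = row.iloc[0]
    params = ArmParameters(
        L1=r.L1, L2=r.L2, S1=r.S1, S2=r.S2, m1=r.m1, m2=r.m2, I1=r.I1, I2=r.I2,
        B=np.array([[r.B11, r.B12], [r.B21, r.B22]]),
        subject_id=subject_id, direction_label=direction_label,
    )
    noise_tab = load_parameter_table("noise_parameters.csv")
    nrow = noise_tab[noise_tab.subject == subject_id]
    noise = NoiseParameters(k1=float(nrow.iloc[0].k1), k2=float(nrow.iloc[0].k2))
    return params, noise


def load_lambda_weight(subject_id: str, direction_label: str | None = None) -> float:
    """Packaged cost-function weight lambda; direction None gives the mean."""
    tab = load_parameter_table("lambda_weights.csv")
    rows = tab[tab.subject == subject_id.upper()]
    if rows.empty:
        raise KeyError(f"unknown subject {subject_id!r}")
    if direction_label is None:
        return float(rows.lam.mean())
    sel = rows[rows.direction == direction_label.lower()]
    if sel.empty:
        raise KeyError(f"unknown direction {direction_label!r}")
    return float(sel.iloc[0].lam)


# ---------------------------------------------------------------------------
# trajectory CSV I/O
# ---------------------------------------------------------------------------

def write_trajectory_csv(path, params: ArmParameters, traj: JointTrajectory) -> None:
    """Write a trajectory as time_s,theta1_rad,theta2_rad,x_m,y_m."""
    xy = forward_kinematics(params, traj.theta)
    pd.DataFrame(
        {
            "time_s": traj.times,
            "theta1_rad": traj.theta[:, 0],
            "theta2_rad": traj.theta[:, 1],
            "x_m": xy[:, 0],
            "y_m": xy[:, 1],
        }
    ).to_csv(path, index=False)


def read_trajectory_csv(path) -> JointTrajectory:
    """Read a trajectory CSV; derivatives recovered by central differences."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    theta = df[["theta1_rad", "theta2_rad"]].to_numpy()
    dt = t[1] - t[0]
    theta_dot = np.gradient(theta, dt, axis=0)
    theta_ddot = np.gradient(theta_dot, dt, axis=0)
    return JointTrajectory(
        theta=theta, theta_dot=theta_dot, theta_ddot=theta_ddot,
        duration=float(t[-1] - t[0]), normalized=False,
    )
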