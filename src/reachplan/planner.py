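"""Minimum commanded-torque-change trajectory planning at a fixed duration.

The planner finds a point-to-point joint trajectory minimizing the
discretized smoothness cost

    C_tau = sum_i  integral_0^D (d tau_i / dt)^2 dt

with the torques obtained from the arm's inverse dynamics.  Each joint angle
is represented as the minimum-jerk quintic between the boundary angles plus
a polynomial correction under the envelope s^3 (1-s)^3, which vanishes to
second order at both ends, so the boundary conditions (rest-to-rest, exact
start/target angles) hold by construction.  The optimizer is L-BFGS-B on the
polynomial coefficients.

A movement planned at the reference duration of 1.0 s serves as the
time-normalized trajectory: all duration-dependent constants of the
duration-planning cost are computed from it, and candidate durations are
realized by rescaling (theta(t) = theta_norm(t/D)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import minimize

from .arm import (
    ArmParameters,
    JointTrajectory,
    TaskSpec,
    TorqueProfile,
    commanded_torque,
    forward_kinematics,
    inverse_kinematics,
)

#: output sampling rate for time-indexed trajectories, Hz
OUTPUT_RATE_HZ = 500.0

#: number of grid *intervals* of the frozen normalized s-grid
NORMALIZED_INTERVALS = 500


@dataclass
class PlannerConfig:
    """Discretization and convergence settings for the planner."""

    n_samples: int = 100          # planning s-grid points
    n_basis: int = 8              # correction polynomial coefficients per joint
    max_iterations: int = 400
    convergence_tol: float = 1e-12  # relative cost change (L-BFGS-B ftol)
    init_scheme: str = "minimum-jerk"

    def __post_init__(self):
        if self.n_samples < 50:
            raise ValueError("use at least 50 planning samples")
        if self.convergence_tol <= 0:
            raise ValueError("convergence tolerance must be positive")


# ---------------------------------------------------------------------------
# minimum-jerk reference
# ---------------------------------------------------------------------------

def _quintic(s: np.ndarray):
    """Rest-to-rest quintic blend and its first two s-derivatives."""
    sigma = 10 * s**3 - 15 * s**4 + 6 * s**5
    dsigma = 30 * s**2 - 60 * s**3 + 30 * s**4
    ddsigma = 60 * s - 180 * s**2 + 120 * s**3
    return sigma, dsigma, ddsigma


def min_jerk_reference(start_xy, target_xy, duration: float, n_samples: int):
    """Straight-line minimum-jerk hand path.

    Returns (positions (n,2), velocities (n,2), accelerations (n,2), times).
    """
    s = np.linspace(0.0, 1.0, n_samples)
    sigma, dsigma, ddsigma = _quintic(s)
    p0 = np.asarray(start_xy, dtype=float)
    dp = np.asarray(target_xy, dtype=float) - p0
    pos = p0 + np.outer(sigma, dp)
    vel = np.outer(dsigma, dp) / duration
    acc = np.outer(ddsigma, dp) / duration**2
    return pos, vel, acc, s * duration


# ---------------------------------------------------------------------------
# direct trajectory optimization
# ---------------------------------------------------------------------------

def _basis_coeffs(n_basis: int) -> np.ndarray:
    """Power-series coefficients of s^3 (1-s)^3 * T_j(2s-1), j < n_basis."""
    env = P.polypow(np.array([0.0, 1.0]), 3)
    env = P.polymul(env, P.polypow(np.array([1.0, -1.0]), 3))
    cols = []
    for j in range(n_basis):
        cheb = np.polynomial.chebyshev.cheb2poly(np.eye(n_basis)[j])
        cols.append(P.polymul(env, cheb))
    width = max(len(c) for c in cols)
    out = np.zeros((n_basis, width))
    for j, c in enumerate(cols):
        out[j, : len(c)] = c
    return out


class _JointPath:
    """Smooth two-joint path: quintic base plus envelope-polynomial correction.

    Evaluation at any s-grid is exact (no interpolation), which is what makes
    rescaling and resampling loss-free.
    """

    def __init__(self, theta0, theta1, coeffs, n_basis):
        self.theta0 = np.asarray(theta0, dtype=float)
        self.dtheta = np.asarray(theta1, dtype=float) - self.theta0
        self.coeffs = np.asarray(coeffs, dtype=float).reshape(n_basis, 2)
        self._poly = _basis_coeffs(n_basis)         # (n_basis, deg+1)
        self._dpoly = P.polyder(self._poly.T).T
        self._ddpoly = P.polyder(self._poly.T, 2).T

    def _eval_basis(self, s, poly):
        # vandermonde evaluation, (n, n_basis)
        return P.polyval(s, poly.T).T

    def __call__(self, s: np.ndarray):
        """theta(s), dtheta/ds, d2theta/ds2 on grid s."""
        sigma, dsigma, ddsigma = _quintic(s)
        th = self.theta0 + np.outer(sigma, self.dtheta)
        thd = np.outer(dsigma, self.dtheta)
        thdd = np.outer(ddsigma, self.dtheta)
        th += self._eval_basis(s, self._poly) @ self.coeffs
        thd += self._eval_basis(s, self._dpoly) @ self.coeffs
        thdd += self._eval_basis(s, self._ddpoly) @ self.coeffs
        return th, thd, thdd

    def sample(self, duration: float, n_samples: int, normalized: bool = False):
        s = np.linspace(0.0, 1.0, n_samples)
        th, thd, thdd = self(s)
        scale = 1.0 if normalized else duration
        return JointTrajectory(
            theta=th,
            theta_dot=thd / scale,
            theta_ddot=thdd / scale**2,
            duration=1.0 if normalized else duration,
            normalized=normalized,
        )


def _torque_change_cost(params, path: _JointPath, duration, s):
    th, thd, thdd = path(s)
    tau = commanded_torque(params, th, thd / duration, thdd / duration**2)
    dt = duration / (len(s) - 1)
    return float(np.sum(np.diff(tau, axis=0) ** 2) / dt), tau


def plan_joint_trajectory(
    params: ArmParameters,
    start_angles,
    target_angles,
    duration: float,
    config: PlannerConfig | None = None,
):
    """Minimum commanded-torque-change plan between two joint postures.

    Returns (path, cost, converged) where ``path`` is the smooth
    :class:`_JointPath` solution (sample it at any grid).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    config = config or PlannerConfig()
    s = np.linspace(0.0, 1.0, config.n_samples)
    nb = config.n_basis
    path = _JointPath(start_angles, target_angles, np.zeros(2 * nb), nb)

    def objective(c):
        path.coeffs = c.reshape(nb, 2)
        cost, _ = _torque_change_cost(params, path, duration, s)
        return cost

    res = minimize(
        objective,
        np.zeros(2 * nb),
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "ftol": config.convergence_tol,
            "gtol": 1e-10,
        },
    )
    path.coeffs = res.x.reshape(nb, 2)
    return path, float(res.fun), bool(res.success)


def plan_min_torque_change(
    params: ArmParameters,
    task: TaskSpec,
    duration: float,
    config: PlannerConfig | None = None,
    n_out: int | None = None,
):
    """Plan a reach defined by a :class:`TaskSpec` at a fixed duration.

    Returns (JointTrajectory, TorqueProfile, cost).  The output is sampled at
    500 Hz (n = 500*D intervals) unless ``n_out`` is given.
    """
    task.validate_reachable(params)
    start = np.asarray(task.start_angles, dtype=float)
    target = inverse_kinematics(
        params, task.target_xy, elbow_sign=np.sign(start[1]) or 1.0
    )
    path, cost, _ = plan_joint_trajectory(params, start, target, duration, config)
    if n_out is None:
        n_out = int(round(OUTPUT_RATE_HZ * duration)) + 1
    traj = path.sample(duration, n_out)
    tau = commanded_torque(params, traj.theta, traj.theta_dot, traj.theta_ddot)
    return traj, TorqueProfile(tau=tau, duration=duration), cost


def normalized_trajectory(
    params: ArmParameters,
    task: TaskSpec,
    config: PlannerConfig | None = None,
    mu: float | None = None,
):
    """Time-normalized plan (reference duration 1.0 s) and normalized torque.

    The returned torque is the normalized commanded torque in which the
    viscous term carries the least-squares coefficient mu (default: mu for
    the standard duration band [0.40, 1.50] s), so that tau(t) for a movement
    of duration D is approximately tau_norm(t/D)/D^2.
    """
    if mu is None:
        from .duration import compute_mu

        mu = compute_mu((0.40, 1.50))
    task.validate_reachable(params)
    start = np.asarray(task.start_angles, dtype=float)
    target = inverse_kinematics(
        params, task.target_xy, elbow_sign=np.sign(start[1]) or 1.0
    )
    path, _, _ = plan_joint_trajectory(params, start, target, 1.0, config)
    traj = path.sample(1.0, NORMALIZED_INTERVALS + 1, normalized=True)
    tau = commanded_torque(
        params, traj.theta, traj.theta_dot, traj.theta_ddot, b_scale=mu
    )
    return traj, TorqueProfile(tau=tau, duration=1.0, normalized=True)


def rescale_trajectory(norm: JointTrajectory, duration: float) -> JointTrajectory:
    """Map a normalized trajectory to real time: theta(t) = theta_norm(t/D)."""
    if not norm.normalized:
        raise ValueError("rescale_trajectory expects a normalized trajectory")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return JointTrajectory(
        theta=norm.theta.copy(),
        theta_dot=norm.theta_dot / duration,
        theta_ddot=norm.theta_ddot / duration**2,
        duration=duration,
        normalized=False,
    )


def rescale_torque(norm_tau: TorqueProfile, duration: float) -> TorqueProfile:
    """Commanded torque at duration D under the normalized-torque scaling
    tau(t) = tau_norm(t/D) / D^2 (the viscous term inside tau_norm carries
    the in-band coefficient mu)."""
    if not norm_tau.normalized:
        raise ValueError("rescale_torque expects a normalized torque profile")
    if duration <= 0:
        raise ValueError("duration must be positive")
    return TorqueProfile(
        tau=norm_tau.tau / duration**2, duration=duration, normalized=False
    )


def tangential_velocity(params: ArmParameters, traj: JointTrajectory) -> np.ndarray:
    """Hand speed profile |J(theta) theta_dot| along a trajectory."""
    from .arm import jacobian as _jacobian

    jac = _jacobian(params, traj.theta)
    v = np.einsum("nij,nj->ni", jac, traj.theta_dot)
    return np.hypot(v[:, 0], v[:, 1])
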