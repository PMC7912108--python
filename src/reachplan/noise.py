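"""Signal-dependent motor noise and the endpoint-error model.

Motor noise is multiplicative: the torque perturbation at joint i has
standard deviation k_i |tau_i|.  Linearizing the hand response through the
joint viscosity (torque perturbation -> joint-velocity perturbation via
B^-1 -> hand-velocity perturbation via the Jacobian) gives the endpoint
deviations

    dx(D) ~ (1/D) sum_i k_i alpha_ix,   dy(D) ~ (1/D) sum_i k_i alpha_iy,

where the alphas are integrals over the *normalized* movement of
J B^-1 tau_norm z(s) against a standard-normal white sequence z.  The
endpoint-error magnitude is then W_hat = gamma / D with the
duration-free random constant

    gamma = sqrt( (sum_i k_i alpha_ix)^2 + (sum_i k_i alpha_iy)^2 ).

All stochastic integrals use the frozen 501-sample s-grid (500 intervals);
the k coefficients are defined relative to this discretization, and Monte
Carlo endpoint scatter uses the same fixed-sample-count convention so both
routes obey the same 1/D law.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .arm import (
    ArmParameters,
    JointTrajectory,
    NoiseParameters,
    TorqueProfile,
    _integrate_batch,
    forward_kinematics,
    jacobian,
    mass_matrix,
)

__all__ = [
    "NoiseParameters",
    "EndpointSample",
    "alpha_components",
    "sample_gamma",
    "endpoint_error",
    "simulate_endpoint_scatter",
    "confidence_ellipse",
    "estimate_noise_parameters",
]


@dataclass(frozen=True)
class EndpointSample:
    """One noise realization's hand-endpoint deviation."""

    dx: float
    dy: float
    w_hat: float   # Euclidean deviation, m
    gamma: float   # duration-normalized magnitude w_hat * D, m*s


def _trapezoid_weights(n: int) -> np.ndarray:
    w = np.full(n, 1.0 / (n - 1))
    w[0] *= 0.5
    w[-1] *= 0.5
    return w


def _alpha_integrands(params: ArmParameters, norm_traj: JointTrajectory,
                      norm_tau: TorqueProfile):
    """c_ix(s), c_iy(s): per-joint integrand rows, each shape (n, 2)."""
    if not (norm_traj.normalized and norm_tau.normalized):
        raise ValueError("alpha components require normalized inputs")
    if norm_traj.n_samples != norm_tau.n_samples:
        raise ValueError("trajectory and torque grids differ")
    Binv = np.linalg.inv(params.B)
    J = jacobian(params, norm_traj.theta)       # (n, 2, 2)
    JB = np.einsum("nij,jk->nik", J, Binv)      # rows: x, y
    cx = JB[:, 0, :] * norm_tau.tau             # (n, 2): joint i contribution
    cy = JB[:, 1, :] * norm_tau.tau
    return cx, cy


def alpha_components(
    params: ArmParameters,
    norm_traj: JointTrajectory,
    norm_tau: TorqueProfile,
    z_draw: np.ndarray,
):
    """Discretized alpha integrals for one white-noise draw.

    ``z_draw``: shape (2, n) — one standard-normal sequence per joint on the
    trajectory's s-grid.  Returns (alpha_1x, alpha_2x, alpha_1y, alpha_2y).
    """
    cx, cy = _alpha_integrands(params, norm_traj, norm_tau)
    z = np.asarray(z_draw, dtype=float)
    if z.shape != (2, norm_traj.n_samples):
        raise ValueError("z_draw must have one sequence per joint on the s-grid")
    w = _trapezoid_weights(norm_traj.n_samples)
    ax = (w[:, None] * cx * z.T).sum(axis=0)
    ay = (w[:, None] * cy * z.T).sum(axis=0)
    return ax[0], ax[1], ay[0], ay[1]


def sample_gamma(
    params: ArmParameters,
    norm_traj: JointTrajectory,
    norm_tau: TorqueProfile,
    k: NoiseParameters,
    n_draws: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """I.i.d. realizations of the duration-normalized endpoint magnitude gamma."""
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    cx, cy = _alpha_integrands(params, norm_traj, norm_tau)
    n = norm_traj.n_samples
    w = _trapezoid_weights(n)[:, None]
    kvec = k.k
    z = rng.standard_normal((n_draws, n, 2))
    sx = np.einsum("dnj,nj->d", z, w * cx * kvec)
    sy = np.einsum("dnj,nj->d", z, w * cy * kvec)
    return np.hypot(sx, sy)


def gamma_coordinate_std(
    params: ArmParameters,
    norm_traj: JointTrajectory,
    norm_tau: TorqueProfile,
    k: NoiseParameters,
) -> tuple[float, float]:
    """Closed-form SDs of the x and y coordinate sums sum_i k_i alpha_i."""
    cx, cy = _alpha_integrands(params, norm_traj, norm_tau)
    w = _trapezoid_weights(norm_traj.n_samples)[:, None]
    kvec = k.k
    vx = float(np.sum((w * cx * kvec) ** 2))
    vy = float(np.sum((w * cy * kvec) ** 2))
    return np.sqrt(vx), np.sqrt(vy)


def endpoint_error(gamma, duration: float):
    """Endpoint-error magnitude W_hat = gamma / D."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return np.asarray(gamma, dtype=float) / duration


# ---------------------------------------------------------------------------
# Monte-Carlo endpoint scatter through the full forward dynamics
# ---------------------------------------------------------------------------

def _settled_endpoint(params: ArmParameters, theta, theta_dot) -> np.ndarray:
    """Hand endpoint after the post-movement transient decays.

    Once the command ends, the residual joint velocity decays through the
    viscosity and contributes an extra displacement B^-1 M theta_dot
    (linearized free dynamics), so the settled hand point is the terminal
    position plus J B^-1 M theta_dot.
    """
    xy = forward_kinematics(params, theta)
    J = jacobian(params, theta)
    M = mass_matrix(params, theta)
    Binv = np.linalg.inv(params.B)
    extra = np.einsum("nij,jl,nlm,nm->ni", J, Binv, M, np.atleast_2d(theta_dot))
    return xy + extra


def _scatter_deviations(
    params: ArmParameters,
    traj: JointTrajectory,
    tau: TorqueProfile,
    k_per_joint: np.ndarray,     # (2,) noise scale per joint
    n_draws: int,
    rng: np.random.Generator,
    joint_mask: np.ndarray | None = None,
    settle: str = "asymptotic",
) -> np.ndarray:
    """Endpoint deviations (n_draws, 2) from noise-added torque replays."""
    n = traj.n_samples
    dt = traj.duration / (n - 1)
    sd = np.abs(tau.tau) * k_per_joint          # (n, 2)
    if joint_mask is not None:
        sd = sd * joint_mask
    noise = rng.standard_normal((n_draws, n, 2)) * sd
    tau_noisy = tau.tau[None] + noise
    theta0 = np.repeat(traj.theta[:1], n_draws, axis=0)
    thetad0 = np.repeat(traj.theta_dot[:1], n_draws, axis=0)
    th, thd = _integrate_batch(params, tau_noisy, theta0, thetad0, dt)
    # noise-free replay as the reference endpoint (same integrator, same grid)
    th0, thd0 = _integrate_batch(
        params, tau.tau[None], traj.theta[:1], traj.theta_dot[:1], dt
    )
    if settle == "asymptotic":
        end = _settled_endpoint(params, th[:, -1], thd[:, -1])
        ref = _settled_endpoint(params, th0[:, -1], thd0[:, -1])
    else:
        end = forward_kinematics(params, th[:, -1])
        ref = forward_kinematics(params, th0[:, -1])
    return end - ref


def simulate_endpoint_scatter(
    params: ArmParameters,
    traj: JointTrajectory,
    tau: TorqueProfile,
    k: NoiseParameters,
    n_draws: int,
    seed: int | np.random.Generator = 0,
    settle: str = "asymptotic",
) -> list[EndpointSample]:
    """Endpoint scatter by adding signal-dependent torque noise per draw.

    Per sample and joint the torque noise SD is k_i |tau_i(t)|; the noisy
    torque is replayed through the forward dynamics and the hand deviation
    from the noise-free endpoint recorded.  ``settle="asymptotic"`` (default)
    measures the endpoint after the residual velocity has decayed through
    the viscosity; ``settle="none"`` takes the position at the last sample.
    Pass the commanded torque (rescaled normalized torque) to probe the
    planning noise model, or a measured-trial inverse-dynamics torque to
    reproduce the parameter-estimation procedure.
    """
    if traj.normalized or tau.normalized:
        raise ValueError("scatter simulation expects time-indexed inputs")
    rng = np.random.default_rng(seed)
    dev = _scatter_deviations(params, traj, tau, k.k, n_draws, rng, settle=settle)
    out = []
    for dx, dy in dev:
        w = float(np.hypot(dx, dy))
        out.append(EndpointSample(float(dx), float(dy), w, w * traj.duration))
    return out


def write_scatter_csv(path, samples) -> None:
    """Write endpoint samples as a dx_m,dy_m CSV."""
    import pandas as pd

    pd.DataFrame(
        {"dx_m": [s.dx for s in samples], "dy_m": [s.dy for s in samples]}
    ).to_csv(path, index=False)


def read_scatter_csv(path, duration: float) -> list[EndpointSample]:
    """Read a dx_m,dy_m CSV back into endpoint samples at a known duration."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for dx, dy in zip(df.dx_m, df.dy_m):
        w = float(np.hypot(dx, dy))
        out.append(EndpointSample(float(dx), float(dy), w, w * duration))
    return out


# ---------------------------------------------------------------------------
# confidence ellipse and noise-parameter estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipse:
    cx: float
    cy: float
    a: float          # major semi-axis
    b: float          # minor semi-axis
    angle_rad: float  # orientation of the major axis

    def as_dict(self):
        return {"cx": self.cx, "cy": self.cy, "a": self.a, "b": self.b,
                "angle_rad": self.angle_rad}


def _sample_xy(samples) -> np.ndarray:
    arr = np.array([[s.dx, s.dy] for s in samples], dtype=float)
    return arr


def confidence_ellipse(samples, level: float = 0.95) -> Ellipse:
    """Chi-square confidence ellipse of an endpoint cloud."""
    xy = _sample_xy(samples)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    cov = np.cov(xy.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[0] / evals[1] < 1e-12:
        raise ValueError("degenerate endpoint covariance")
    q = chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    mean = xy.mean(axis=0)
    return Ellipse(
        float(mean[0]), float(mean[1]),
        float(np.sqrt(q * evals[0])), float(np.sqrt(q * evals[1])), angle,
    )


def estimate_noise_parameters(
    reference_scatter,
    params: ArmParameters,
    traj: JointTrajectory,
    tau: TorqueProfile,
    grid: np.ndarray | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> NoiseParameters:
    """Grid-search (k1, k2) matching a reference endpoint scatter.

    Candidate scatter is built from two probe simulations (noise at one joint
    at a time, full forward dynamics) by linear superposition — the endpoint
    response is linear in the noise amplitude to first order — and the
    criterion is the Frobenius distance between candidate and reference
    endpoint covariance matrices, the operational form of requiring the 95%
    confidence ellipses to overlap.
    """
    ref = _sample_xy(reference_scatter)
    if ref.size == 0:
        raise ValueError("reference scatter is empty")
    if grid is None:
        grid = np.arange(0.0, 2.0 + 1e-9, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty search grid")
    ref_cov = np.cov(ref.T) if ref.shape[0] > 1 else np.zeros((2, 2))

    probe = 0.5
    rng = np.random.default_rng(seed)
    u1 = _scatter_deviations(
        params, traj, tau, np.array([probe, probe]), n_draws, rng,
        joint_mask=np.array([1.0, 0.0]),
    ) / probe
    u2 = _scatter_deviations(
        params, traj, tau, np.array([probe, probe]), n_draws, rng,
        joint_mask=np.array([0.0, 1.0]),
    ) / probe

    # covariance of k1*u1 + k2*u2 is quadratic in (k1, k2)
    c11 = np.cov(u1.T)
    c22 = np.cov(u2.T)
    c12 = ((u1 - u1.mean(0)).T @ (u2 - u2.mean(0))) / (n_draws - 1)
    c12 = c12 + c12.T

    k1g = grid[:, None]
    k2g = grid[None, :]

    def entry(i, j):
        return (
            k1g**2 * c11[i, j] + k2g**2 * c22[i, j] + k1g * k2g * c12[i, j]
        ) - ref_cov[i, j]

    dist = entry(0, 0) ** 2 + entry(1, 1) ** 2 + 2 * entry(0, 1) ** 2
    i, j = np.unravel_index(np.argmin(dist), dist.shape)
    return NoiseParameters(k1=float(grid[i]), k2=float(grid[j]))
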