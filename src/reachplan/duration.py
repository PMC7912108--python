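"""Movement-duration planning by cost minimization.

The duration D of a reach is chosen to minimize

    C(D) = C_tau + lambda * C_err,
    C_tau ~ a / D^5,                  (smoothness: commanded-torque change)
    C_err ~ (W* - gamma / D)^2,      (cost of time: tolerance mismatch)

where ``a`` is the integrated squared torque-change of the time-normalized
movement, ``gamma`` a per-noise-draw endpoint-error constant, ``W*`` the
target tolerance radius and ``lambda`` the relative weight of accuracy
against smoothness.  Minimization uses steepest descent with Rprop step
adaptation: the step length eta grows geometrically while the gradient sign
is stable and shrinks when it flips, ignoring the gradient magnitude.

Because gamma is random (signal-dependent noise), D* is computed per draw;
a movement's headline planned duration is the median over draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm import ArmParameters, NoiseParameters, TaskSpec, TorqueProfile
from .noise import sample_gamma
from .planner import (
    OUTPUT_RATE_HZ,
    PlannerConfig,
    normalized_trajectory,
    rescale_trajectory,
)
from .arm import commanded_torque

#: duration search interval, s
D_BOUNDS_DEFAULT = (0.40, 1.50)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DurationCostModel:
    """Scalars defining the duration cost C(D) for one noise draw."""

    a: float             # torque-change constant of the normalized movement
    gamma: float         # endpoint-error constant for this draw, m*s
    lam: float           # weight of the tolerance term
    tolerance: float     # W*, m
    mu: float = 0.5681   # viscosity approximation coefficient (duration band)
    d_bounds: tuple = D_BOUNDS_DEFAULT

    def __post_init__(self):
        if self.a < 0 or self.lam < 0:
            raise ValueError("a and lambda must be non-negative")
        lo, hi = self.d_bounds
        if not 0 < lo < hi:
            raise ValueError("invalid duration bounds")


@dataclass
class RpropConfig:
    """Sign-based step-size schedule of the Rprop descent."""

    eta_init: float = 0.010
    eta_plus: float = 1.20
    eta_minus: float = 0.50
    eta_max: float = 50.0
    eta_min: float = 0.000001
    max_iter: int = 300
    step_tol: float = 2.5e-6   # stop once the step length falls below this, s

    def __post_init__(self):
        if not 0 < self.eta_minus < 1 < self.eta_plus:
            raise ValueError("need 0 < eta- < 1 < eta+")
        if not self.eta_min < self.eta_init < self.eta_max:
            raise ValueError("need eta_min < eta_init < eta_max")


@dataclass
class DurationSolution:
    """Result of one duration optimization."""

    d_star: float
    cost: float
    cost_tau: float
    cost_err: float
    iterations: int
    converged: bool
    gamma_used: float


# ---------------------------------------------------------------------------
# constants a and mu
# ---------------------------------------------------------------------------

def compute_a(norm_tau: TorqueProfile) -> float:
    """Torque-change constant a = sum_i int_0^1 (d tau_norm_i / ds)^2 ds."""
    if norm_tau.n_samples < 3:
        raise ValueError("need at least 3 torque samples")
    n = norm_tau.n_samples
    s = np.linspace(0.0, 1.0, n)
    dtau = np.gradient(norm_tau.tau, s, axis=0)
    return float(np.trapezoid(np.sum(dtau**2, axis=1), s))


def compute_mu(d_bounds=D_BOUNDS_DEFAULT) -> float:
    """Least-squares coefficient replacing the 1/D viscous scaling by mu/D^2.

    Minimizing int_[Dmin,Dmax] (1/D - mu/D^2)^2 dD gives the closed form
    mu = (int D^-3 dD) / (int D^-4 dD) over the duration band.
    """
    lo, hi = d_bounds
    if not 0 < lo < hi:
        raise ValueError("invalid duration interval")
    num = 0.5 * (lo**-2 - hi**-2)
    den = (lo**-3 - hi**-3) / 3.0
    return float(num / den)


# ---------------------------------------------------------------------------
# cost and gradient
# ---------------------------------------------------------------------------

def cost(D, model: DurationCostModel):
    """(C, C_tau, C_err) at duration D (scalar or array)."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("duration must be positive")
    c_tau = model.a / D**5
    c_err = (model.tolerance - model.gamma / D) ** 2
    return c_tau + model.lam * c_err, c_tau, c_err


def cost_gradient(D, model: DurationCostModel):
    """dC/dD = -5a/D^6 + 2 lambda (W* - gamma/D) gamma / D^2."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("duration must be positive")
    return (
        -5.0 * model.a / D**6
        + 2.0 * model.lam * (model.tolerance - model.gamma / D) * model.gamma / D**2
    )


# ---------------------------------------------------------------------------
# Rprop descent
# ---------------------------------------------------------------------------

def _rprop_batch(
    a, gammas, lam, tolerance, d_bounds, config: RpropConfig, d_init=None
):
    """Vectorized Rprop over a batch of gamma draws sharing (a, lam, W*).

    Returns (d_star, cost, iterations, converged) arrays.  The update rules
    are identical to :func:`rprop_minimize`; the scalar routine is the
    reference implementation.
    """
    gammas = np.atleast_1d(np.asarray(gammas, dtype=float))
    lo, hi = d_bounds
    m = gammas.size
    D = np.full(m, 0.5 * (lo + hi) if d_init is None else d_init)
    eta = np.full(m, config.eta_init)
    prev_sign = np.zeros(m)
    best_D = D.copy()
    best_absg = np.full(m, np.inf)
    active = np.ones(m, dtype=bool)
    iters = np.zeros(m, dtype=int)

    def grad(Darr, g):
        return -5.0 * a / Darr**6 + 2.0 * lam * (tolerance - g / Darr) * g / Darr**2

    for it in range(config.max_iter):
        if not active.any():
            break
        g = grad(D, gammas)
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite duration-cost gradient")
        sign = np.sign(g)
        absg = np.abs(g)
        improve = active & (absg < best_absg)
        best_absg[improve] = absg[improve]
        best_D[improve] = D[improve]

        same = active & (prev_sign * sign > 0)
        flip = active & (prev_sign * sign < 0)
        grow = same & (eta * config.eta_plus < config.eta_max)
        eta[grow] *= config.eta_plus
        shrink = flip & (eta * config.eta_minus > config.eta_min)
        eta[shrink] *= config.eta_minus

        step = -sign * eta
        newD = np.clip(D + step, lo, hi)
        clamped = active & ((newD == lo) | (newD == hi)) & (newD != D)
        eta[clamped] = config.eta_init
        stuck = active & (newD == D) & (sign != 0)
        done = active & ((np.abs(step) < config.step_tol) | stuck | (sign == 0))
        iters[active] = it + 1
        D = np.where(active, newD, D)
        prev_sign = np.where(active, sign, prev_sign)
        active = active & ~done

    # boundary solutions: keep the boundary point, not the best interior iterate
    at_bound = (D <= lo) | (D >= hi)
    final = np.where(at_bound, D, best_D)
    converged = ~active
    return final, iters, converged


def rprop_minimize(
    model: DurationCostModel,
    config: RpropConfig | None = None,
    d_init: float | None = None,
    gradient=None,
    cost_fn=None,
) -> DurationSolution:
    """Minimize the duration cost over the duration band with Rprop.

    The step length eta is adapted from gradient-sign agreement between
    successive iterations: same sign multiplies eta by eta+ (only while
    eta*eta+ stays below eta_max), a sign flip multiplies by eta- (only while
    eta*eta- stays above eta_min).  D moves by -sign(gradient)*eta, clamped
    to the bounds with eta reset on clamp.  ``gradient``/``cost_fn`` may
    override the model's analytic forms (used by the unit tests).
    """
    config = config or RpropConfig()
    lo, hi = model.d_bounds
    D = 0.5 * (lo + hi) if d_init is None else float(d_init)
    if not lo <= D <= hi:
        raise ValueError("initial duration outside bounds")
    gradf = gradient or (lambda d: float(cost_gradient(d, model)))
    eta = config.eta_init
    prev_sign = 0.0
    best_D, best_absg = D, np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        g = gradf(D)
        if not np.isfinite(g):
            raise FloatingPointError("non-finite duration-cost gradient")
        if abs(g) < best_absg:
            best_absg, best_D = abs(g), D
        sign = np.sign(g)
        if sign == 0:
            converged = True
            break
        if prev_sign * sign > 0 and eta * config.eta_plus < config.eta_max:
            eta *= config.eta_plus
        elif prev_sign * sign < 0 and eta * config.eta_minus > config.eta_min:
            eta *= config.eta_minus
        step = -sign * eta
        newD = float(np.clip(D + step, lo, hi))
        if newD in (lo, hi) and newD != D:
            eta = config.eta_init
        if newD == D:  # pinned at a bound
            converged = True
            D = newD
            break
        prev_sign = sign
        D = newD
        if abs(step) < config.step_tol:
            converged = True
            break
    d_star = D if (D <= lo or D >= hi) else best_D
    if cost_fn is not None:
        c = float(cost_fn(d_star))
        c_tau, c_err = np.nan, np.nan
    else:
        c, c_tau, c_err = (float(v) for v in cost(d_star, model))
    return DurationSolution(
        d_star=float(d_star), cost=c, cost_tau=float(c_tau),
        cost_err=float(c_err), iterations=it, converged=converged,
        gamma_used=model.gamma,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class DurationResult:
    """Per-draw duration solutions plus the rescaled representative plan."""

    solutions: list
    d_star: np.ndarray          # per-draw optimal durations
    d_star_median: float
    d_star_mean: float
    a: float
    gammas: np.ndarray
    trajectory: object          # JointTrajectory at the median D*
    torque: object              # TorqueProfile at the median D*
    norm_trajectory: object
    norm_torque: object


def solve_duration(
    params: ArmParameters,
    task: TaskSpec,
    k: NoiseParameters,
    lam: float,
    n_draws: int = 1000,
    seed: int = 0,
    planner_config: PlannerConfig | None = None,
    rprop_config: RpropConfig | None = None,
    d_bounds=D_BOUNDS_DEFAULT,
    mu: float | None = None,
) -> DurationResult:
    """Plan a reach end to end: normalized trajectory, a, per-draw gamma and
    D*, and the representative trajectory rescaled to the median D*.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    mu = compute_mu(d_bounds) if mu is None else mu
    norm_traj, norm_tau = normalized_trajectory(params, task, planner_config, mu=mu)
    a = compute_a(norm_tau)
    gammas = sample_gamma(params, norm_traj, norm_tau, k, n_draws, seed)
    rcfg = rprop_config or RpropConfig()
    d_star, iters, conv = _rprop_batch(
        a, gammas, lam, task.tolerance, d_bounds, rcfg
    )
    solutions = []
    for dstar, g, ni, cv in zip(d_star, gammas, iters, conv):
        model = DurationCostModel(
            a=a, gamma=float(g), lam=lam, tolerance=task.tolerance,
            mu=mu, d_bounds=tuple(d_bounds),
        )
        c, ct, ce = cost(dstar, model)
        solutions.append(
            DurationSolution(
                d_star=float(dstar), cost=float(c), cost_tau=float(ct),
                cost_err=float(ce), iterations=int(ni), converged=bool(cv),
                gamma_used=float(g),
            )
        )
    d_med = float(np.median(d_star))
    traj = rescale_trajectory(norm_traj, d_med)
    tau = TorqueProfile(
        tau=commanded_torque(params, traj.theta, traj.theta_dot, traj.theta_ddot),
        duration=d_med,
    )
    return DurationResult(
        solutions=solutions,
        d_star=d_star,
        d_star_median=d_med,
        d_star_mean=float(np.mean(d_star)),
        a=a,
        gammas=gammas,
        trajectory=traj,
        torque=tau,
        norm_trajectory=norm_traj,
        norm_torque=norm_tau,
    )


def duration_profile(
    params: ArmParameters,
    task_template: TaskSpec,
    k: NoiseParameters,
    lam_base: float,
    lam_multipliers=(0.5, 1.0, 2.0, 4.0),
    tolerance_grid_mm=(4.0, 8.0, 11.5, 15.0, 20.0, 25.0),
    n_draws: int = 1000,
    seed: int = 0,
    planner_config: PlannerConfig | None = None,
    rprop_config: RpropConfig | None = None,
    d_bounds=D_BOUNDS_DEFAULT,
):
    """Median-D* tolerance profiles for several lambda multipliers.

    gamma and a do not depend on the tolerance or lambda, so the normalized
    plan and the noise draws are shared across the whole grid.  Returns a
    dict {multiplier: {tolerance_mm: median D*}}.
    """
    if any(m <= 0 for m in lam_multipliers):
        raise ValueError("lambda multipliers must be positive")
    mu = compute_mu(d_bounds)
    norm_traj, norm_tau = normalized_trajectory(
        params, task_template, planner_config, mu=mu
    )
    a = compute_a(norm_tau)
    gammas = sample_gamma(params, norm_traj, norm_tau, k, n_draws, seed)
    rcfg = rprop_config or RpropConfig()
    out = {}
    for mult in lam_multipliers:
        curve = {}
        for tol_mm in tolerance_grid_mm:
            d_star, _, _ = _rprop_batch(
                a, gammas, lam_base * mult, tol_mm * 1e-3, d_bounds, rcfg
            )
            curve[tol_mm] = float(np.median(d_star))
        out[mult] = curve
    return out
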