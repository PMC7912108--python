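"""Fitting the cost-function weight lambda to measured movement durations.

lambda trades accuracy against smoothness in the duration cost; it is fitted
by grid search, minimizing the mean absolute error (MAE) between measured and
model durations over the (direction, tolerance) condition cells.  Measured
tables come from threshold-segmented trials, so by default the model cell
durations are converted to the same 5%-of-peak-velocity convention before
comparison; pass ``model_duration="planned"`` to compare raw planned
durations instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arm import ArmParameters, NoiseParameters
from .behavior import task_geometry, threshold_duration_fraction
from .duration import (
    D_BOUNDS_DEFAULT,
    RpropConfig,
    _rprop_batch,
    compute_a,
    compute_mu,
)
from .noise import sample_gamma
from .planner import PlannerConfig, normalized_trajectory

#: default lambda search grid: 41 log-spaced points spanning the search band
LAMBDA_GRID_DEFAULT = np.logspace(5, 7, 41)

#: measured tolerance conditions entering the MAE, mm
MEASURED_TOLERANCES_MM = (8.0, 15.0, 25.0)


def duration_table(direction, tolerance_mm, mean_duration_s, n=None) -> pd.DataFrame:
    """Convenience constructor for a duration table."""
    df = pd.DataFrame(
        {
            "direction": direction,
            "tolerance_mm": tolerance_mm,
            "mean_duration_s": mean_duration_s,
        }
    )
    df["n"] = n if n is not None else 0
    return df


def mae_durations(
    measured: pd.DataFrame, model: pd.DataFrame, by: str | None = None
):
    """Mean absolute error between matching condition cells, in seconds.

    ``by="direction"`` returns a per-direction Series instead of the pooled
    scalar.  Raises if any measured cell has no model counterpart.
    """
    merged = measured.merge(
        model, on=["direction", "tolerance_mm"], suffixes=("_meas", "_model")
    )
    if len(merged) < len(measured):
        raise ValueError("model table is missing condition cells")
    err = (merged.mean_duration_s_meas - merged.mean_duration_s_model).abs()
    if by == "direction":
        return err.groupby(merged.direction).mean()
    return float(err.mean())


def model_duration_cells(
    params_by_direction: dict,
    k: NoiseParameters,
    lam: float,
    tolerances_mm,
    n_draws: int,
    seed: int,
    prepared: dict,
    d_bounds=D_BOUNDS_DEFAULT,
    model_duration: str = "segmented",
    rprop_config: RpropConfig | None = None,
    stat: str = "mean",
) -> pd.DataFrame:
    """Model duration table at one lambda, using pre-computed per-direction
    normalized plans and frozen gamma draws (see :func:`prepare_directions`).

    ``stat`` is the per-cell reduction over draws; it must match the
    statistic of the measured table it will be compared against (cell means
    by default, as in a measured session table).
    """
    rcfg = rprop_config or RpropConfig()
    reduce = {"mean": np.mean, "median": np.median}[stat]
    rows = []
    for direction, (a, gammas, frac) in prepared.items():
        for tol in tolerances_mm:
            d_star, _, _ = _rprop_batch(
                a, gammas, lam, tol * 1e-3, d_bounds, rcfg
            )
            d = float(reduce(d_star))
            if model_duration == "segmented":
                d *= frac
            rows.append(
                {"direction": direction, "tolerance_mm": tol,
                 "mean_duration_s": d, "n": len(gammas)}
            )
    return pd.DataFrame(rows)


def prepare_directions(
    params_by_direction: dict,
    k: NoiseParameters,
    n_draws: int,
    seed: int,
    planner_config: PlannerConfig | None = None,
    d_bounds=D_BOUNDS_DEFAULT,
) -> dict:
    """Per-direction (a, frozen gamma draws, threshold fraction).

    ``params_by_direction`` maps direction label -> ArmParameters (the
    viscosity block is direction-specific).  The gamma draws are frozen per
    direction so a lambda grid search is deterministic.
    """
    mu = compute_mu(d_bounds)
    out = {}
    for i, (direction, params) in enumerate(sorted(params_by_direction.items())):
        task = task_geometry(direction, 8.0, params)
        norm_traj, norm_tau = normalized_trajectory(
            params, task, planner_config, mu=mu
        )
        a = compute_a(norm_tau)
        gammas = sample_gamma(
            params, norm_traj, norm_tau, k, n_draws, seed + 1000 * i
        )
        frac = threshold_duration_fraction(params, norm_traj)
        out[direction] = (a, gammas, frac)
    return out


def fit_lambda(
    measured: pd.DataFrame,
    params_by_direction: dict,
    k: NoiseParameters,
    grid: np.ndarray | None = None,
    per_direction: bool = True,
    n_draws: int = 200,
    seed: int = 0,
    planner_config: PlannerConfig | None = None,
    d_bounds=D_BOUNDS_DEFAULT,
    model_duration: str = "segmented",
    stat: str = "mean",
):
    """Grid-search lambda minimizing the duration MAE.

    Returns a dict with one lambda per direction present in ``measured`` plus
    their arithmetic mean under ``"mean"``; with ``per_direction=False`` only
    the pooled ``{"mean": ...}`` entry is returned.  The gamma draws are
    frozen across the grid so the argmin is reproducible.
    """
    grid = LAMBDA_GRID_DEFAULT if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    directions = sorted(measured.direction.unique())
    prepared = prepare_directions(
        {d: params_by_direction[d] for d in directions},
        k, n_draws, seed, planner_config, d_bounds,
    )
    tolerances = sorted(measured.tolerance_mm.unique())
    maes = np.empty((grid.size, len(directions)))
    for gi, lam in enumerate(grid):
        model = model_duration_cells(
            params_by_direction, k, float(lam), tolerances, n_draws, seed,
            prepared, d_bounds, model_duration, stat=stat,
        )
        maes[gi] = mae_durations(measured, model, by="direction").reindex(
            directions
        ).to_numpy()
    fitted = {
        d: float(grid[int(np.argmin(maes[:, j]))])
        for j, d in enumerate(directions)
    }
    mean_lam = float(np.mean(list(fitted.values())))
    if per_direction:
        return {**fitted, "mean": mean_lam}
    return {"mean": mean_lam}
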