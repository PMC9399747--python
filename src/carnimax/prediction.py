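"""Monte Carlo efficacy-curve simulation and milestone-time reporting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import draw_etas
from .estimation import FitResult
from .structural import EmaxParams, MilestoneTable, apply_eta, emax_effect, milestone_table

__all__ = ["EfficacyBands", "simulate_efficacy_curve", "milestone_report", "default_time_grid"]


@dataclass(frozen=True)
class EfficacyBands:
    """Median and 2.5/97.5 percentile efficacy bands over time."""

    times_weeks: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_weeks": self.times_weeks,
                "effect_p2.5": self.lower,
                "effect_p50": self.median,
                "effect_p97.5": self.upper,
            }
        )


def default_time_grid(horizon_weeks: float = 24.0, step_weeks: float = 0.1) -> np.ndarray:
    """Default simulation grid: 0 to 24 weeks in 0.1-week steps."""
    return np.arange(0.0, horizon_weeks + step_weeks / 2, step_weeks)


def _params_of(fit_or_params) -> EmaxParams:
    if isinstance(fit_or_params, FitResult):
        if not fit_or_params.converged:
            raise ValueError("prediction requires a converged fit")
        return fit_or_params.params
    return fit_or_params


def simulate_efficacy_curve(
    fit, time_grid=None, n_sim: int = 1000, seed: int = 20220810
) -> EfficacyBands:
    """Monte Carlo bands of the typical efficacy curve.

    Draws study-level etas per replicate, evaluates the structural curve
    on the grid and returns the median and 2.5/97.5 percentiles across
    replicates.  With both omegas zero the bands collapse onto the
    deterministic curve Emax * t / (ET50 + t).
    """
    params = _params_of(fit)
    grid = default_time_grid() if time_grid is None else np.asarray(time_grid, float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    rng = np.random.default_rng(seed)
    curves = np.empty((n_sim, grid.size))
    for r in range(n_sim):
        e1, e2 = draw_etas(params, rng)
        curves[r] = emax_effect(apply_eta(params, e1, e2), grid)
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    return EfficacyBands(times_weeks=grid, median=med, lower=lo, upper=hi)


def milestone_report(fit, fractions=(0.25, 0.50, 0.75, 0.80)) -> MilestoneTable:
    """Treatment durations to reach the requested fractions of Emax.

    Uses the ET50 point estimate; the inverse of the saturating curve is
    analytic, t = ET50 * f / (1 - f).
    """
    params = _params_of(fit)
    return milestone_table(params.et50_weeks, fractions)
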