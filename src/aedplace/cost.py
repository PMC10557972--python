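"""Cost–coverage increment analysis.

How much average performance does each additional facility buy?  For a
grid of budgets ``k``, the site set is re-optimized on the demand of the
best-performing period ``h_hat`` and its coverage is averaged over every
period's demand.  The increment between consecutive budgets, divided by
the budget step, is the marginal coverage gain per facility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .geometry import CandidateSet, HourlyDemand
from .mclp import MCLPInstance, MCLPSolution, evaluate_coverage, solve_exact, solve_greedy

__all__ = ["CostCoverageCurve", "cost_coverage_curve", "smooth_curve",
           "plateau_budget"]


@dataclass
class CostCoverageCurve:
    """Average performance as a function of budget, with per-unit increments."""

    k_grid: np.ndarray
    performance: np.ndarray
    increments: np.ndarray  # (N[t+1]-N[t]) / (k[t+1]-k[t])
    optimization_period: int
    solutions: dict[int, MCLPSolution] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        inc = np.concatenate([[np.nan], self.increments])
        return pd.DataFrame({"k": self.k_grid, "performance": self.performance,
                             "increment": inc})


def cost_coverage_curve(demands: dict[int, HourlyDemand],
                        candidates: CandidateSet, S: float,
                        k_grid, best_period: int,
                        solver: str = "exact") -> CostCoverageCurve:
    """Average performance of budget-``k`` solutions optimized on ``best_period``.

    For each budget the MCLP is solved on the best period's demand only,
    then that solution's coverage rate is averaged over all periods'
    demand distributions.
    """
    k_grid = np.asarray(sorted(set(int(k) for k in k_grid)), dtype=int)
    if k_grid.size == 0:
        raise ValueError("k_grid must be non-empty")
    if k_grid[0] < 1 or k_grid[-1] > len(candidates):
        raise ValueError(f"budgets must lie in [1, {len(candidates)}]")
    if best_period not in demands:
        raise ValueError(f"best_period {best_period} not among demand periods")
    solve = {"exact": solve_exact, "greedy": solve_greedy}[solver]
    periods = sorted(demands)
    perf = np.empty(k_grid.size)
    sols: dict[int, MCLPSolution] = {}
    for t, k in enumerate(k_grid):
        sol = solve(MCLPInstance.build(demands[best_period], candidates, S, int(k)))
        sols[int(k)] = sol
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rates = [evaluate_coverage(sol.chosen, demands[h], candidates, S).rate
                     for h in periods]
        perf[t] = float(np.mean(rates))
    increments = np.diff(perf) / np.diff(k_grid.astype(float))
    return CostCoverageCurve(k_grid, perf, increments, int(best_period), sols)


def smooth_curve(curve: CostCoverageCurve, penalty: float = 0.05) -> np.ndarray:
    """Penalized cubic smoothing spline of the performance curve (presentation only).

    Evaluated at the curve's own budgets; the raw values are retained on
    the curve object.  ``penalty -> 0`` interpolates the raw points;
    ``penalty -> inf`` tends to the straight-line fit.
    """
    if curve.k_grid.size < 4:
        raise ValueError("smoothing requires at least 4 budgets")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    spl = make_smoothing_spline(curve.k_grid.astype(float), curve.performance,
                                lam=float(penalty))
    return np.asarray(spl(curve.k_grid.astype(float)))


def plateau_budget(curve: CostCoverageCurve, threshold: float = 1e-4) -> int | None:
    """Smallest budget whose forward increment falls below ``threshold``.

    Returns ``None`` if no increment does (the curve never plateaus on
    the evaluated grid).
    """
    for k, inc in zip(curve.k_grid[:-1], curve.increments):
        if inc < threshold:
            return int(k)
    return None
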