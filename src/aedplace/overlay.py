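"""Two-stage overlayed spatio-temporal optimization.

Stage 1 solves one MCLP per time period, producing one site set per
period.  Stage 2 overlays the periods: each period's site set is
evaluated against every period's demand, giving a T x T table of
coverage rates ``R[h, h']`` (rows index demand periods ``h``, columns
index solutions ``h'``).  A solution's *average performance* ``N[h']``
is the unweighted mean of its column, and the selected solution is the
column argmax — the site set most robust across the day, rather than
the one best for any single hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CandidateSet, HourlyDemand
from .mclp import MCLPInstance, MCLPSolution, evaluate_coverage, solve_exact, solve_greedy

__all__ = ["OverlayMatrix", "stage1_hourly_solutions", "stage2_overlay",
           "select_best", "run_osto"]

_SOLVERS = {"exact": solve_exact, "greedy": solve_greedy}


@dataclass
class OverlayMatrix:
    """Cross-period coverage rates, per-solution performances, and the winner.

    ``rates.loc[h, h']`` is the coverage rate of period ``h'``'s solution
    applied to period ``h``'s demand; the diagonal holds each period's own
    optimized rate.  ``performances[h']`` is the column mean.
    """

    periods: list[int]
    solutions: dict[int, MCLPSolution]
    rates: pd.DataFrame
    performances: pd.Series
    best_period: int

    @property
    def best_solution(self) -> MCLPSolution:
        return self.solutions[self.best_period]

    @property
    def diagonal(self) -> pd.Series:
        return pd.Series({h: self.rates.loc[h, h] for h in self.periods})

    def diagonal_dominant(self) -> bool:
        """Whether every demand row attains its maximum on the diagonal."""
        r = self.rates.to_numpy()
        return bool(all(r[t, t] >= r[t].max() - 1e-9 for t in range(len(self.periods))))


def stage1_hourly_solutions(demands: dict[int, HourlyDemand],
                            candidates: CandidateSet, S: float, k: int,
                            solver: str = "exact") -> dict[int, MCLPSolution]:
    """Solve one MCLP per period (the per-hour optimization stage)."""
    if not demands:
        raise ValueError("at least one period of demand is required")
    if solver not in _SOLVERS:
        raise ValueError(f"solver must be one of {sorted(_SOLVERS)}")
    solve = _SOLVERS[solver]
    out: dict[int, MCLPSolution] = {}
    for h in sorted(demands):
        out[h] = solve(MCLPInstance.build(demands[h], candidates, S, k))
    return out


def stage2_overlay(solutions: dict[int, MCLPSolution],
                   demands: dict[int, HourlyDemand],
                   candidates: CandidateSet, S: float,
                   include_empty_periods: bool = True) -> OverlayMatrix:
    """Cross-evaluate every period's solution on every period's demand.

    Empty-demand periods contribute a vacuous rate of 1.0 to every column
    (flagged with a warning); ``include_empty_periods=False`` drops them
    from the performance mean, but they stay in the rate table.
    """
    if set(solutions) != set(demands):
        raise ValueError("solutions and demands must cover the same period set")
    periods = sorted(demands)
    empty = [h for h in periods if len(demands[h]) == 0]
    if empty:
        warnings.warn(f"period(s) {empty} have empty demand; their rows are "
                      "vacuously 1.0", stacklevel=2)
    rates = pd.DataFrame(index=periods, columns=periods, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # vacuous-coverage warnings already issued once
        for h_prime in periods:
            chosen = solutions[h_prime].chosen
            for h in periods:
                rates.loc[h, h_prime] = evaluate_coverage(
                    chosen, demands[h], candidates, S).rate
    rows = [h for h in periods if h not in empty] if not include_empty_periods else periods
    if not rows:
        raise ValueError("no non-empty periods to average over")
    performances = rates.loc[rows].mean(axis=0)
    best = select_best_period(performances)
    return OverlayMatrix(periods, dict(solutions), rates, performances, best)


def select_best_period(performances: pd.Series) -> int:
    """Argmax of average performance; ties go to the earliest period label."""
    best_val = performances.max()
    for h in performances.index:
        if performances[h] >= best_val - 1e-12:
            return int(h)
    raise AssertionError("unreachable")


def select_best(matrix: OverlayMatrix) -> tuple[int, MCLPSolution]:
    """The period whose solution has maximal average performance, and that solution."""
    best = select_best_period(matrix.performances)
    return best, matrix.solutions[best]


def run_osto(demands: dict[int, HourlyDemand], candidates: CandidateSet,
             S: float, k: int, solver: str = "exact",
             include_empty_periods: bool = True) -> OverlayMatrix:
    """Run both stages end-to-end and return the completed overlay matrix."""
    solutions = stage1_hourly_solutions(demands, candidates, S, k, solver)
    matrix = stage2_overlay(solutions, demands, candidates, S,
                            include_empty_periods=include_empty_periods)
    if solver == "exact" and not matrix.diagonal_dominant():
        raise AssertionError("diagonal dominance violated with the exact solver; "
                             "this indicates a solver defect")
    if solver == "greedy" and not matrix.diagonal_dominant():
        warnings.warn("overlay matrix is not diagonally dominant: the greedy "
                      "heuristic under-solved at least one period", stacklevel=2)
    return matrix
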