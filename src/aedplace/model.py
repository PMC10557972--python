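"""Model/Results interface for period-wise facility-placement optimization.

:class:`SpatioTemporalPlacement` is constructed from data (per-period
demand and candidate sites) plus the design parameters (service distance
``S``, budget ``k``); :meth:`~SpatioTemporalPlacement.fit` runs both
optimization stages and returns a :class:`PlacementResults` carrying the
per-period solutions, the cross-period rate table, the selected site
set, and diagnostics.  Cost-curve and clustering analyses hang off the
results object.

Example
-------
>>> from aedplace.synth import SynthConfig, generate_city
>>> from aedplace.model import SpatioTemporalPlacement
>>> cand, visits = generate_city(SynthConfig(n_pois=80, n_candidates=40,
...                                          periods=6, seed=1))
>>> model = SpatioTemporalPlacement.from_tables(visits, cand, S=800, k=3,
...                                             jitter=False, projected=True)
>>> res = model.fit()
>>> res.best_period  # doctest: +SKIP
3
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cost import CostCoverageCurve, cost_coverage_curve
from .diagnostics import (DensitySurface, DeviationalEllipse, kernel_density,
                          std_deviational_ellipse)
from .geometry import CandidateSet, HourlyDemand, demands_from_table
from .mclp import MCLPSolution, evaluate_coverage
from .overlay import OverlayMatrix, run_osto

__all__ = ["SpatioTemporalPlacement", "PlacementResults", "RelocationResult",
           "relocate"]


class SpatioTemporalPlacement:
    """Facility placement over period-varying demand.

    Parameters
    ----------
    demands : dict[int, HourlyDemand]
        Weighted demand points per period.
    candidates : CandidateSet
        Sites eligible to receive a facility.
    S : float
        Service distance in meters (coverage is binary at ``d <= S``).
    k : int
        Number of facilities to place.
    solver : {"exact", "greedy"}
        Exact integer programming, or the greedy heuristic for large
        instances.
    """

    def __init__(self, demands: dict[int, HourlyDemand],
                 candidates: CandidateSet, S: float = 100.0, k: int = 100,
                 solver: str = "exact", include_empty_periods: bool = True):
        if not demands:
            raise ValueError("at least one demand period is required")
        self.demands = dict(sorted(demands.items()))
        self.candidates = candidates
        self.S = float(S)
        self.k = int(k)
        self.solver = solver
        self.include_empty_periods = include_empty_periods

    @classmethod
    def from_tables(cls, poi_visits: pd.DataFrame, candidates: pd.DataFrame,
                    S: float = 100.0, k: int = 100, solver: str = "exact",
                    jitter: bool = True, walking_radius: float = 414.3,
                    sampling_fraction: float = 1.0, projected: bool = False,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    ) -> "SpatioTemporalPlacement":
        """Build a model from interchange tables.

        With ``jitter=True`` every visit becomes a unit-weight point
        spread into the walking circle; otherwise POI-period rows become
        count-weighted points.  ``sampling_fraction`` thins jittered
        visitors.  Lon/lat tables are projected to a shared local planar
        frame (``projected=True`` skips this).
        """
        from .geometry import project_coordinates
        if rng is None:
            rng = np.random.default_rng(seed)
        if not projected:
            lon = pd.concat([poi_visits.rename(columns={"poi_id": "id"})[["lon", "lat"]],
                             candidates[["lon", "lat"]]])
            center = (float(lon["lon"].mean()), float(lon["lat"].mean()))
            poi_visits, _ = project_coordinates(poi_visits, center=center)
            candidates, _ = project_coordinates(candidates, center=center)
        demands = demands_from_table(poi_visits, radius=walking_radius,
                                     fraction=sampling_fraction, rng=rng,
                                     jitter=jitter)
        cand = CandidateSet.from_frame(candidates)
        return cls(demands, cand, S=S, k=k, solver=solver)

    def fit(self) -> "PlacementResults":
        """Run per-period optimization and the cross-period overlay."""
        matrix = run_osto(self.demands, self.candidates, self.S, self.k,
                          solver=self.solver,
                          include_empty_periods=self.include_empty_periods)
        return PlacementResults(self, matrix)


@dataclass
class RelocationResult:
    """Before/after comparison for relocating an existing facility stock."""

    n_sites: int
    before_rates: pd.Series
    before_performance: float
    after: "PlacementResults"

    @property
    def after_performance(self) -> float:
        return float(self.after.performances[self.after.best_period])

    @property
    def improvement(self) -> float:
        return self.after_performance - self.before_performance


class PlacementResults:
    """Fitted placement: solutions, overlay rates, selection, diagnostics."""

    def __init__(self, model: SpatioTemporalPlacement, overlay: OverlayMatrix):
        self.model = model
        self.overlay = overlay

    # -- primary estimates -------------------------------------------------
    @property
    def best_period(self) -> int:
        return self.overlay.best_period

    @property
    def best_solution(self) -> MCLPSolution:
        return self.overlay.best_solution

    @property
    def best_sites(self) -> list:
        return self.best_solution.chosen_sorted

    @property
    def rates(self) -> pd.DataFrame:
        """T x T coverage rates: rows = demand periods, columns = solutions."""
        return self.overlay.rates

    @property
    def performances(self) -> pd.Series:
        return self.overlay.performances

    @property
    def solutions(self) -> dict[int, MCLPSolution]:
        return self.overlay.solutions

    def diagonal_rates(self) -> pd.Series:
        """Each period's own optimized coverage rate."""
        return self.overlay.diagonal

    # -- uncertainty -------------------------------------------------------
    def performance_se(self) -> pd.Series:
        """Standard error of each solution's mean rate across demand periods.

        Treats the per-period rates as a sample of the solution's
        performance over the day; purely descriptive of cross-period
        spread.
        """
        r = self.rates
        return r.std(axis=0, ddof=1) / np.sqrt(len(r))

    # -- follow-on analyses ------------------------------------------------
    def cost_curve(self, k_grid, solver: str | None = None,
                   best_period: int | None = None) -> CostCoverageCurve:
        """Average performance as a function of budget (optimized on the
        selected period's demand unless overridden)."""
        return cost_coverage_curve(
            self.model.demands, self.model.candidates, self.model.S,
            k_grid, self.best_period if best_period is None else best_period,
            solver=solver or self.model.solver)

    def density_surface(self, period: int, bandwidth: float | None = None,
                        spacing: float = 250.0) -> DensitySurface:
        return kernel_density(self.model.demands[period].coords(),
                              bandwidth=bandwidth, spacing=spacing)

    def deviational_ellipse(self, period: int, n_std: float = 1.0,
                            ) -> DeviationalEllipse:
        return std_deviational_ellipse(self.model.demands[period].coords(),
                                       n_std=n_std)

    # -- presentation ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fitted placement."""
        m = self.model
        lines = [
            "Spatio-temporal facility placement",
            "=" * 50,
            f"periods:            {len(self.overlay.periods)}",
            f"candidate sites:    {len(m.candidates)}",
            f"budget k:           {m.k}",
            f"service distance S: {m.S} m",
            f"solver:             {m.solver}",
            "-" * 50,
            "period  own_rate  avg_performance  perf_se",
        ]
        se = self.performance_se()
        for h in self.overlay.periods:
            flag = " <- selected" if h == self.best_period else ""
            lines.append(f"{h:6d}  {self.rates.loc[h, h]:8.4f}  "
                         f"{self.performances[h]:15.4f}  {se[h]:7.4f}{flag}")
        lines += [
            "-" * 50,
            f"selected period:    {self.best_period}",
            f"avg performance:    {self.performances[self.best_period]:.4f}",
            f"sites: {', '.join(map(str, self.best_sites[:10]))}"
            + (" ..." if len(self.best_sites) > 10 else ""),
        ]
        return "\n".join(lines)

    def plot_overlay(self, ax=None):
        """Heatmap of the cross-period rate table."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.rates.to_numpy(), origin="lower", aspect="auto",
                       vmin=0, vmax=1, cmap="viridis")
        ax.set_xlabel("solution period h'")
        ax.set_ylabel("demand period h")
        ax.figure.colorbar(im, ax=ax, label="coverage rate")
        return ax


def relocate(existing_sites: pd.DataFrame, demands: dict[int, HourlyDemand],
             candidates: CandidateSet, S: float, solver: str = "exact",
             projected: bool = True) -> RelocationResult:
    """Evaluate an existing facility stock, then re-optimize at equal size.

    The existing sites' coverage rate is averaged over all periods'
    demand (their *average performance*); the same number of facilities
    is then placed from the candidate set with the two-stage procedure.
    On the optimization period's demand the optimizer cannot do worse
    than any equal-size set drawn from the candidates; the cross-period
    improvement is reported, not guaranteed.
    """
    from .geometry import project_coordinates
    frame, _ = project_coordinates(existing_sites, projected=projected)
    existing = CandidateSet.from_frame(frame)
    periods = sorted(demands)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        before = pd.Series({h: evaluate_coverage(existing.ids, demands[h],
                                                 existing, S).rate
                            for h in periods})
    n = len(existing)
    model = SpatioTemporalPlacement(demands, candidates, S=S, k=n, solver=solver)
    after = model.fit()
    return RelocationResult(n, before, float(before.mean()), after)
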