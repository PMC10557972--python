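"""Point geometry and demand construction for coverage optimization.

Demand is a weighted point set per time period (typically visitors at
points of interest, POIs); candidate facility sites are an unweighted
point set.  Coverage is binary: a candidate at planar Euclidean distance
``d <= S`` of a demand point covers it (boundary inclusive).  All
coordinates are planar meters; longitude/latitude inputs must first go
through :func:`project_coordinates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DemandPoint",
    "HourlyDemand",
    "CandidateSet",
    "CoverageStructure",
    "pairwise_distances",
    "coverage_sets",
    "jitter_visitors",
    "sample_demand",
    "compute_sample_size",
    "walking_radius",
    "project_coordinates",
    "LocalTransverseMercator",
]

#: Mean Earth radius in meters (IUGG), used by the local projection.
EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class DemandPoint:
    """A single demand point: visitors to serve at a location.

    Parameters
    ----------
    id : hashable
        Opaque identifier, unique within one period.
    x, y : float
        Planar coordinates in meters.
    weight : float
        Non-negative demand weight ``a_i`` (number of visitors to serve).
    """

    id: object
    x: float
    y: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"demand point {self.id!r}: non-finite coordinates")
        if not (self.weight >= 0):
            raise ValueError(f"demand point {self.id!r}: weight must be >= 0")


@dataclass
class HourlyDemand:
    """One period's demand: an ordered collection of weighted points (``I_h``)."""

    period: int
    points: list[DemandPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.points]
        if len(ids) != len(set(ids)):
            raise ValueError(f"period {self.period}: duplicate demand point ids")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def total_weight(self) -> float:
        return float(sum(p.weight for p in self.points))

    def coords(self) -> np.ndarray:
        """(n, 2) array of point coordinates."""
        if not self.points:
            return np.empty((0, 2))
        return np.array([[p.x, p.y] for p in self.points], dtype=float)

    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.points], dtype=float)

    def ids(self) -> list:
        return [p.id for p in self.points]


@dataclass
class CandidateSet:
    """The set ``J`` of sites eligible to receive a facility."""

    ids: list
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("candidate ids must be unique")
        if not (len(self.ids) == self.xs.size == self.ys.size):
            raise ValueError("ids/xs/ys length mismatch")
        if not (np.isfinite(self.xs).all() and np.isfinite(self.ys).all()):
            raise ValueError("candidate coordinates must be finite")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, id_col: str = "site_id",
                   x_col: str = "x", y_col: str = "y") -> "CandidateSet":
        return cls(list(frame[id_col]),
                   frame[x_col].to_numpy(float),
                   frame[y_col].to_numpy(float))

    def __len__(self) -> int:
        return len(self.ids)

    def coords(self) -> np.ndarray:
        return np.column_stack([self.xs, self.ys])

    def subset(self, site_ids: Iterable) -> "CandidateSet":
        wanted = list(site_ids)
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise KeyError(f"unknown site id(s): {missing}")
        rows = [index[s] for s in wanted]
        return CandidateSet(wanted, self.xs[rows], self.ys[rows])


@dataclass
class CoverageStructure:
    """Coverage distance ``S`` and per-demand coverable-site sets ``N_i``.

    ``cover_sets[i]`` holds the candidate ids within distance ``S`` of
    demand point ``i`` (inclusive at ``d == S``).  The raw distance table
    is retained when available to support exact re-checks.
    """

    S: float
    cover_sets: Mapping[object, frozenset]
    distances: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValueError("coverage distance S must be > 0")


def pairwise_distances(demand: HourlyDemand, candidates: CandidateSet) -> pd.DataFrame:
    """Euclidean distance table between demand points (rows) and candidates (columns).

    Both point sets must be non-empty and expressed in a common planar
    meter frame.
    """
    if len(demand) == 0 or len(candidates) == 0:
        raise ValueError("pairwise_distances requires non-empty demand and candidates")
    di = demand.coords()
    dj = candidates.coords()
    d = np.hypot(di[:, 0:1] - dj[None, :, 0], di[:, 1:2] - dj[None, :, 1])
    return pd.DataFrame(d, index=demand.ids(), columns=candidates.ids)


def coverage_sets(demand: HourlyDemand, candidates: CandidateSet,
                  S: float, keep_distances: bool = True) -> CoverageStructure:
    """Build ``N_i = { j : d_ij <= S }`` for every demand point (boundary inclusive)."""
    if not S > 0:
        raise ValueError("coverage distance S must be > 0")
    if len(demand) == 0:
        return CoverageStructure(S, {}, None)
    dist = pairwise_distances(demand, candidates)
    cols = np.array(candidates.ids, dtype=object)
    mask = dist.to_numpy() <= S
    cover = {i: frozenset(cols[row]) for i, row in zip(dist.index, mask)}
    return CoverageStructure(S, cover, dist if keep_distances else None)


def jitter_visitors(poi_visits: pd.DataFrame, radius: float,
                    rng: np.random.Generator,
                    period_col: str = "hour") -> dict[int, HourlyDemand]:
    """Spread each POI-period visit count into unit-weight demand points.

    Each row ``(poi_id, x, y, period, count)`` with count ``c`` emits exactly
    ``c`` points of weight 1, drawn uniformly by area over the closed disc of
    ``radius`` meters centered on the POI (``r = R*sqrt(u)``, ``theta = 2*pi*u'``).
    A radius of 0 reproduces the POI location.  Zero-count rows emit nothing.

    Returns a dict mapping period label to :class:`HourlyDemand`.
    """
    if radius < 0:
        raise ValueError("jitter radius must be >= 0")
    counts = poi_visits["visits"].to_numpy()
    if not np.issubdtype(np.asarray(counts).dtype, np.number):
        raise ValueError("visit counts must be numeric")
    if (counts < 0).any():
        raise ValueError("visit counts must be non-negative")
    if not np.array_equal(counts, np.floor(counts)):
        raise ValueError("visit counts must be integers")

    out: dict[int, HourlyDemand] = {}
    for period, grp in poi_visits.groupby(period_col, sort=True):
        points: list[DemandPoint] = []
        for poi_id, x, y, c in zip(grp["poi_id"], grp["x"], grp["y"],
                                   grp["visits"].astype(int)):
            if c == 0:
                continue
            if radius == 0:
                px = np.full(c, float(x))
                py = np.full(c, float(y))
            else:
                r = radius * np.sqrt(rng.random(c))
                theta = 2.0 * np.pi * rng.random(c)
                px = x + r * np.cos(theta)
                py = y + r * np.sin(theta)
            for m in range(c):
                points.append(DemandPoint(f"{poi_id}#{m}", px[m], py[m], 1.0))
        out[int(period)] = HourlyDemand(int(period), points)
    return out


def sample_demand(demand: HourlyDemand, fraction: float | None = None,
                  n: int | None = None,
                  rng: np.random.Generator | None = None) -> HourlyDemand:
    """Uniform sample of demand points without replacement.

    Exactly one of ``fraction`` (0 < f <= 1, sample size ``floor(f * n_points)``)
    or ``n`` (0 <= n <= n_points) must be given.  Reproducible under a fixed
    generator state.
    """
    if (fraction is None) == (n is None):
        raise ValueError("specify exactly one of fraction or n")
    n_points = len(demand)
    if fraction is not None:
        if not (0 < fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if fraction == 1.0:
            return HourlyDemand(demand.period, list(demand.points))
        n = int(n_points * fraction)
    assert n is not None
    if not (0 <= n <= n_points):
        raise ValueError(f"sample size {n} out of range [0, {n_points}]")
    if rng is None:
        rng = np.random.default_rng()
    idx = np.sort(rng.choice(n_points, size=n, replace=False))
    return HourlyDemand(demand.period, [demand.points[k] for k in idx])


def demands_from_table(poi_visits: pd.DataFrame, radius: float = 0.0,
                       fraction: float = 1.0,
                       rng: np.random.Generator | None = None,
                       jitter: bool = True,
                       period_col: str = "hour") -> dict[int, HourlyDemand]:
    """Build per-period demand from a POI visit table.

    With ``jitter=True`` each visit becomes a unit-weight point spread
    into the walking circle of ``radius`` meters (``a_i = 1``); otherwise
    each POI-period row becomes a single point weighted by its count.
    ``fraction < 1`` subsamples each period's points uniformly without
    replacement after jittering.
    """
    if rng is None:
        rng = np.random.default_rng()
    if jitter:
        demands = jitter_visitors(poi_visits, radius, rng, period_col=period_col)
    else:
        demands = {}
        for period, grp in poi_visits.groupby(period_col, sort=True):
            grp = grp[grp["visits"] > 0]
            points = [DemandPoint(pid, float(x), float(y), float(c))
                      for pid, x, y, c in zip(grp["poi_id"], grp["x"],
                                              grp["y"], grp["visits"])]
            demands[int(period)] = HourlyDemand(int(period), points)
    if fraction < 1.0:
        demands = {h: sample_demand(d, fraction=fraction, rng=rng)
                   for h, d in demands.items()}
    return demands


def compute_sample_size(total_visits: int, days: int = 365, divisor: int = 6) -> int:
    """Sample size from an annual visit total: ``floor(total / days / divisor)``.

    Dividing by ``days`` gives average daily visits; dividing by ``divisor``
    keeps one in every ``divisor`` visits.  Truncates toward zero.
    """
    for name, v in (("total_visits", total_visits), ("days", days), ("divisor", divisor)):
        if not (isinstance(v, (int, np.integer)) and v > 0):
            raise ValueError(f"{name} must be a positive integer")
    return int(total_visits) // int(days) // int(divisor)


def walking_radius(speed_cm_per_s: float, duration_min: float) -> float:
    """Walking-circle radius in meters from gait speed (cm/s) and duration (min).

    Reported at 0.1 m resolution; e.g. a comfortable adult gait of
    138.10 cm/s sustained for 5 min reaches 414.3 m.
    """
    if speed_cm_per_s < 0 or duration_min < 0:
        raise ValueError("speed and duration must be >= 0")
    meters = speed_cm_per_s * duration_min * 60.0 / 100.0
    return round(meters, 1)


class LocalTransverseMercator:
    """Distance-faithful local planar frame (spherical transverse Mercator).

    Centered on a reference longitude/latitude (by default the data
    centroid), with the reference point at the planar origin.  The sphere
    forward/inverse pair is closed-form, so round-trips are exact to
    machine precision.
    """

    def __init__(self, lon0: float, lat0: float, radius: float = EARTH_RADIUS_M):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self.radius = float(radius)
        # false northing so the reference latitude maps to y = 0
        self._y0 = self.radius * math.radians(self.lat0)

    def forward(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lam = np.radians(np.asarray(lon, float) - self.lon0)
        phi = np.radians(np.asarray(lat, float))
        B = np.cos(phi) * np.sin(lam)
        x = self.radius * np.arctanh(B)
        y = self.radius * np.arctan2(np.tan(phi), np.cos(lam)) - self._y0
        return x, y

    def inverse(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xr = np.asarray(x, float) / self.radius
        yr = (np.asarray(y, float) + self._y0) / self.radius
        lat = np.degrees(np.arcsin(np.sin(yr) / np.cosh(xr)))
        lon = self.lon0 + np.degrees(np.arctan2(np.sinh(xr), np.cos(yr)))
        return lon, lat


def project_coordinates(points: pd.DataFrame, projected: bool = False,
                        center: tuple[float, float] | None = None,
                        ) -> tuple[pd.DataFrame, LocalTransverseMercator | None]:
    """Project lon/lat columns to planar meters ``x``/``y``.

    With ``projected=True`` (or when the frame already carries ``x``/``y``
    and no ``lon``/``lat``), the input is passed through unchanged.  The
    projection is a local transverse-Mercator frame centered at the data
    centroid unless ``center=(lon0, lat0)`` is given.

    Returns the augmented frame and the projection used (``None`` on
    passthrough).
    """
    frame = points.copy()
    if projected or ("lon" not in frame.columns and "x" in frame.columns):
        if "x" not in frame.columns or "y" not in frame.columns:
            raise ValueError("projected input requires x and y columns")
        return frame, None
    lon = frame["lon"].to_numpy(float)
    lat = frame["lat"].to_numpy(float)
    if np.abs(lon).max(initial=0) > 180 or np.abs(lat).max(initial=0) > 90:
        raise ValueError("longitude must be in [-180, 180], latitude in [-90, 90]")
    if center is None:
        center = (float(lon.mean()), float(lat.mean()))
    proj = LocalTransverseMercator(*center)
    frame["x"], frame["y"] = proj.forward(lon, lat)
    return frame, proj
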