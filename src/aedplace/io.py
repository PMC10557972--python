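"""Readers and writers for the interchange formats, plus run configuration.

Input formats are deliberately plain: a delimited POI visit table with
header ``poi_id,lon,lat,hour,visits`` (or ``x,y`` for already-projected
coordinates), site tables as ``site_id,lon,lat`` delimited text or a
GeoJSON FeatureCollection of Point features, and optional exclusion
polygons as GeoJSON.  Outputs are GeoJSON site sets, a delimited overlay
matrix with a trailing average-performance row, a delimited cost curve,
and a plain-text selection report.  Hours are serialized 0–23.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CandidateSet, project_coordinates
from .overlay import OverlayMatrix

logger = logging.getLogger("aedplace")

__all__ = ["RunConfig", "read_poi_visits", "read_sites", "read_exclusions",
           "apply_exclusions", "write_outputs", "write_sites_geojson",
           "write_overlay_matrix", "read_overlay_matrix", "write_curve"]

POI_COLUMNS_LONLAT = ["poi_id", "lon", "lat", "hour", "visits"]
POI_COLUMNS_XY = ["poi_id", "x", "y", "hour", "visits"]


@dataclass
class RunConfig:
    """Run parameters with field-standard defaults.

    ``S`` is the service distance in meters beyond which a demand point
    is uncovered (default 100 m, the distance recommended for on-foot
    defibrillator retrieval); ``k`` the facility budget; the walking
    radius (default 414.3 m, five minutes at a comfortable adult gait of
    138.10 cm/s) sizes the mobility circle used to jitter visitors; the
    sampling fraction (default 1/6) thins jittered visitors for
    tractability.
    """

    S: float = 100.0
    k: int = 100
    walking_radius: float = 414.3
    sampling_fraction: float = 1.0 / 6.0
    periods: int = 24
    seed: int = 0
    solver: str = "exact"            # exact | greedy
    coordinate_mode: str = "lonlat"  # lonlat | projected
    include_empty_periods: bool = True
    jitter: bool = True

    def __post_init__(self) -> None:
        if not self.S > 0:
            raise ValueError("S must be > 0")
        if not (0 < self.sampling_fraction <= 1):
            raise ValueError("sampling fraction must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.walking_radius < 0:
            raise ValueError("walking radius must be >= 0")
        if self.solver not in ("exact", "greedy"):
            raise ValueError("solver must be 'exact' or 'greedy'")
        if self.coordinate_mode not in ("lonlat", "projected"):
            raise ValueError("coordinate_mode must be 'lonlat' or 'projected'")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def read_poi_visits(path, periods: int = 24) -> pd.DataFrame:
    """Read and validate a POI visit table.

    Accepts either the lon/lat or the projected x/y header.  Hours must
    lie in ``[0, periods)`` and visits must be non-negative integers;
    malformed rows are reported with their line numbers.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if cols[:5] not in (POI_COLUMNS_LONLAT, POI_COLUMNS_XY):
        raise ValueError(
            f"{path}: header must be {','.join(POI_COLUMNS_LONLAT)} or "
            f"{','.join(POI_COLUMNS_XY)}; got {','.join(map(str, cols))}")
    bad_lines = []
    visits = pd.to_numeric(frame["visits"], errors="coerce")
    hours = pd.to_numeric(frame["hour"], errors="coerce")
    for idx in frame.index:
        v, h = visits[idx], hours[idx]
        ok = (np.isfinite(v) and v >= 0 and float(v).is_integer()
              and np.isfinite(h) and 0 <= h < periods and float(h).is_integer())
        if not ok:
            bad_lines.append(idx + 2)  # +1 header, +1 one-based
    if bad_lines:
        raise ValueError(f"{path}: malformed rows at line(s) {bad_lines[:10]} "
                         "(hour out of range or non-integer/negative visits)")
    frame["hour"] = hours.astype(int)
    frame["visits"] = visits.astype(int)
    logger.info("read %d POI-period rows, %d total visits from %s",
                len(frame), int(frame['visits'].sum()), path)
    return frame


def read_sites(path) -> pd.DataFrame:
    """Read a site table (``site_id,lon,lat`` / ``site_id,x,y`` delimited
    text, or a GeoJSON FeatureCollection of Points).

    Ids must be unique; duplicate coordinates are allowed with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        frame = _read_sites_geojson(path)
    else:
        frame = pd.read_csv(path)
        cols = list(frame.columns)
        if cols[0] != "site_id" or not ({"lon", "lat"} <= set(cols)
                                        or {"x", "y"} <= set(cols)):
            raise ValueError(f"{path}: header must start with site_id and "
                             "contain lon,lat or x,y")
    if frame["site_id"].duplicated().any():
        dups = frame.loc[frame["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"{path}: duplicate site ids {dups[:5]}")
    coord_cols = ["lon", "lat"] if "lon" in frame.columns else ["x", "y"]
    if frame.duplicated(subset=coord_cols).any():
        logger.warning("%s: duplicate coordinates among sites", path)
    logger.info("read %d sites from %s", len(frame), path)
    return frame


def _read_sites_geojson(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    rows = []
    for n, feat in enumerate(gj.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: feature {n} has non-Point geometry "
                             f"{geom.get('type')!r}")
        lon, lat = geom["coordinates"][:2]
        sid = (feat.get("properties") or {}).get("site_id", f"feature{n}")
        rows.append({"site_id": sid, "lon": lon, "lat": lat})
    return pd.DataFrame(rows, columns=["site_id", "lon", "lat"])


def read_exclusions(path) -> list:
    """Read exclusion polygons from a GeoJSON file (Polygon/MultiPolygon)."""
    from shapely.geometry import shape
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    polys = []
    for feat in feats:
        geom = shape(feat["geometry"] if "geometry" in feat else feat)
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"exclusion geometry must be polygonal, got {geom.geom_type}")
        polys.append(geom)
    return polys


def apply_exclusions(frame: pd.DataFrame, polygons: list,
                     x_col: str = "lon", y_col: str = "lat") -> pd.DataFrame:
    """Drop rows strictly inside any exclusion polygon (boundary points stay)."""
    if not polygons:
        return frame
    from shapely.geometry import Point
    keep = []
    for _, row in frame.iterrows():
        pt = Point(row[x_col], row[y_col])
        keep.append(not any(poly.contains(pt) for poly in polygons))
    out = frame[np.array(keep)].reset_index(drop=True)
    logger.info("exclusion filter: %d of %d rows retained", len(out), len(frame))
    return out


def candidate_set_from_frame(frame: pd.DataFrame,
                             projected: bool = False) -> CandidateSet:
    """Project (if needed) and wrap a site table as a :class:`CandidateSet`."""
    proj_frame, _ = project_coordinates(frame, projected=projected)
    return CandidateSet.from_frame(proj_frame)


def write_sites_geojson(path, solution, candidates: CandidateSet,
                        S: float, lonlat_frame: pd.DataFrame | None = None) -> None:
    """Write a chosen site set as a GeoJSON FeatureCollection.

    When the original lon/lat table is supplied, features carry WGS84
    coordinates; otherwise the planar meters are emitted as-is.
    """
    lookup = {}
    if lonlat_frame is not None and "lon" in lonlat_frame.columns:
        lookup = {sid: (lon, lat) for sid, lon, lat in
                  zip(lonlat_frame["site_id"], lonlat_frame["lon"],
                      lonlat_frame["lat"])}
    sub = candidates.subset(solution.chosen_sorted)
    feats = []
    for sid, x, y in zip(sub.ids, sub.xs, sub.ys):
        coords = list(lookup.get(sid, (x, y)))
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": coords},
            "properties": {"site_id": sid, "period": solution.period,
                           "k": solution.k, "S": S,
                           "objective": solution.objective,
                           "method": solution.method},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def write_overlay_matrix(path, matrix: OverlayMatrix) -> None:
    """Delimited T x T rate table plus a final ``avg_performance`` row.

    Rows are demand periods, columns are solutions; the trailing row
    holds each solution's average performance.
    """
    table = matrix.rates.copy()
    table.columns = [f"sol_h{h}" for h in matrix.periods]
    table.index = pd.Index([f"demand_h{h}" for h in matrix.periods], name="")
    perf = pd.DataFrame([matrix.performances.to_numpy()],
                        index=pd.Index(["avg_performance"], name=""),
                        columns=table.columns)
    pd.concat([table, perf]).round(6).to_csv(path)


def read_overlay_matrix(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read back a written overlay matrix into (rates, performances)."""
    raw = pd.read_csv(path, index_col=0)
    perf = raw.loc["avg_performance"]
    rates = raw.drop(index="avg_performance")
    periods = [int(c.removeprefix("sol_h")) for c in rates.columns]
    rates.columns = periods
    rates.index = [int(str(r).removeprefix("demand_h")) for r in rates.index]
    perf.index = periods
    return rates, perf


def write_curve(path, curve) -> None:
    curve.to_frame().round(8).to_csv(path, index=False)


def write_outputs(out_dir, matrix: OverlayMatrix, candidates: CandidateSet,
                  config: RunConfig, curve=None,
                  sites_lonlat: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write the full result bundle with stable filenames.

    Produces ``overlay_matrix.csv``, ``best_sites.geojson``,
    ``selection_report.txt``, ``config.json`` and (when a curve is given)
    ``cost_curve.csv``.  Re-running with identical inputs reproduces
    identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"matrix": out / "overlay_matrix.csv",
             "sites": out / "best_sites.geojson",
             "report": out / "selection_report.txt",
             "config": out / "config.json"}
    write_overlay_matrix(paths["matrix"], matrix)
    best = matrix.best_solution
    write_sites_geojson(paths["sites"], best, candidates, config.S, sites_lonlat)
    lines = [
        "overlay spatio-temporal optimization: selection report",
        f"periods: {len(matrix.periods)}",
        f"S: {config.S} m, k: {config.k}, solver: {config.solver}",
        f"best period: {matrix.best_period}",
        f"best average performance: {matrix.performances[matrix.best_period]:.6f}",
        f"diagonal rate of best period: {matrix.rates.loc[matrix.best_period, matrix.best_period]:.6f}",
        "chosen sites: " + ", ".join(map(str, best.chosen_sorted)),
    ]
    paths["report"].write_text("\n".join(lines) + "\n")
    paths["config"].write_text(config.to_json() + "\n")
    if curve is not None:
        paths["curve"] = out / "cost_curve.csv"
        write_curve(paths["curve"], curve)
    return paths
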