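"""Ordinary block kriging (BK) and block cokriging (BCK).

The areal mean of the pollutant over a subdistrict polygon is predicted as a
weighted sum of primary observations (ground stations) and, for BCK,
secondary observations (non-missing satellite covariate cells):

    Zhat1(v) = sum_i lam1_i Z1(s1_i) + sum_j lam2_j Z2(s2_j)

Unbiasedness requires sum(lam1) = 1 and sum(lam2) = 0; the weights minimising
the prediction variance solve a symmetric linear system of covariances
augmented with the two Lagrange constraint rows.  With no secondary data the
system reduces to ordinary block kriging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon
import shapely

from .variography import CoregionalizationModel

__all__ = [
    "StationRecord",
    "CovariateRecord",
    "Subdistrict",
    "KrigingSystem",
    "BlockPrediction",
    "Neighborhood",
    "discretize_block",
    "cov_between",
    "solve_bck_system",
    "predict_block",
    "interpolate_day",
]


@dataclass(frozen=True)
class StationRecord:
    """One daily ground observation of the primary variable (24-h mean PM2.5)."""

    station_id: str
    x: float  # projected easting, km
    y: float  # projected northing, km
    date: str  # ISO-8601
    pm25: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.pm25) or self.pm25 < 0:
            raise ValueError(
                f"station {self.station_id} {self.date}: pm25 must be "
                f"finite and nonnegative, got {self.pm25}"
            )


@dataclass(frozen=True)
class CovariateRecord:
    """One non-missing covariate cell (AOD, dimensionless) at its center."""

    cell_id: int
    x: float
    y: float
    date: str
    aod: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.aod):
            raise ValueError(f"covariate cell {self.cell_id}: value not finite")


@dataclass
class Subdistrict:
    """Block support: polygon, area, segmented population, scenario region."""

    id: str
    polygon: Polygon
    area_km2: float
    population: dict[str, float]  # keys: children, adults, seniors
    region: str = "default"

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError(f"subdistrict {self.id}: area must be positive")
        if not self.polygon.is_valid:
            raise ValueError(f"subdistrict {self.id}: invalid polygon")
        if any(v < 0 for v in self.population.values()):
            raise ValueError(f"subdistrict {self.id}: negative population")

    @property
    def total_population(self) -> float:
        return float(sum(self.population.values()))


@dataclass
class Neighborhood:
    """Local search configuration for the kriging system."""

    k1: int = 16  # nearest primary observations
    k2: int = 16  # nearest non-missing secondary observations
    radius_km: float = 500.0
    m_points: int = 64  # block discretization density
    min_stations: int = 10  # per-day minimum to interpolate at all


@dataclass
class KrigingSystem:
    """Solved BK/BCK system: weights, multipliers and cached covariances."""

    lhs: np.ndarray
    rhs: np.ndarray
    lam1: np.ndarray
    lam2: np.ndarray
    mu1: float
    mu2: float | None
    cvv: float  # within-block average covariance of the primary
    primary_xy: np.ndarray = field(repr=False, default=None)
    primary_values: np.ndarray = field(repr=False, default=None)
    secondary_xy: np.ndarray = field(repr=False, default=None)
    secondary_values: np.ndarray = field(repr=False, default=None)

    @property
    def method(self) -> str:
        return "BCK" if len(self.lam2) > 0 else "BK"


@dataclass
class BlockPrediction:
    subdistrict_id: str
    date: str
    estimate: float  # ug/m3
    se: float  # kriging standard error, ug/m3
    n1: int
    n2: int
    method: str  # BK | BCK
    clamped: bool = False


def discretize_block(polygon: Polygon, m_points: int) -> np.ndarray:
    """Regular grid of ~m_points points clipped to the polygon.

    Always returns at least one point (representative interior point as
    fallback for slivers).  With m_points = 1 the block collapses to a single
    interior point and block kriging degenerates to point kriging there.
    """
    if polygon.area <= 0:
        raise ValueError("degenerate polygon with zero area")
    if m_points < 1:
        raise ValueError("m_points must be >= 1")
    if m_points == 1:
        p = polygon.representative_point()
        return np.array([[p.x, p.y]])
    minx, miny, maxx, maxy = polygon.bounds
    w, h = maxx - minx, maxy - miny
    # choose per-axis counts so roughly m_points cells of the bbox grid fall
    # inside the polygon
    density = m_points / polygon.area
    nx = max(1, int(round(w * np.sqrt(density))))
    ny = max(1, int(round(h * np.sqrt(density))))
    xs = minx + (np.arange(nx) + 0.5) * w / nx
    ys = miny + (np.arange(ny) + 0.5) * h / ny
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    if len(pts) == 0:
        p = polygon.representative_point()
        pts = np.array([[p.x, p.y]])
    return pts


def cov_between(
    model: CoregionalizationModel,
    component: str,
    p: np.ndarray,
    q: np.ndarray,
) -> np.ndarray:
    """Covariance matrix C_ab(|p_i - q_j|) between two point sets (km)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    h = cdist(p, q)
    return model.covariance(component, h)


def _dedupe(xy: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at exactly identical coordinates, keep one record."""
    uniq, inverse = np.unique(xy, axis=0, return_inverse=True)
    if len(uniq) == len(xy):
        return xy, values
    sums = np.zeros(len(uniq))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(counts, inverse, 1.0)
    return uniq, sums / counts


def solve_bck_system(
    primary_xy: np.ndarray,
    primary_values: np.ndarray,
    secondary_xy: np.ndarray | None,
    secondary_values: np.ndarray | None,
    model: CoregionalizationModel,
    block_points: np.ndarray,
) -> KrigingSystem:
    """Solve the ordinary (co)kriging system for one block.

    The left-hand matrix stacks the primary/secondary covariance blocks and
    the two unbiasedness constraint rows; the right-hand side holds
    point-to-block average covariances and the constraint targets (1, 0).
    With ``n2 = 0`` the secondary constraint row is dropped (plain BK).
    Duplicate coordinates are averaged before solving; a still-singular
    system raises.
    """
    p_xy = np.atleast_2d(np.asarray(primary_xy, dtype=float))
    p_val = np.asarray(primary_values, dtype=float)
    if secondary_xy is None or len(np.atleast_1d(secondary_xy)) == 0:
        s_xy = np.empty((0, 2))
        s_val = np.empty(0)
    else:
        s_xy = np.atleast_2d(np.asarray(secondary_xy, dtype=float))
        s_val = np.asarray(secondary_values, dtype=float)
    p_xy, p_val = _dedupe(p_xy, p_val)
    s_xy, s_val = _dedupe(s_xy, s_val) if len(s_xy) else (s_xy, s_val)
    n1, n2 = len(p_xy), len(s_xy)
    if n1 < 1:
        raise ValueError("need at least one primary observation")
    bp = np.atleast_2d(np.asarray(block_points, dtype=float))
    m = len(bp)

    ncon = 2 if n2 > 0 else 1
    dim = n1 + n2 + ncon
    lhs = np.zeros((dim, dim))
    lhs[:n1, :n1] = cov_between(model, "11", p_xy, p_xy)
    if n2 > 0:
        lhs[:n1, n1:n1 + n2] = cov_between(model, "12", p_xy, s_xy)
        lhs[n1:n1 + n2, :n1] = lhs[:n1, n1:n1 + n2].T
        lhs[n1:n1 + n2, n1:n1 + n2] = cov_between(model, "22", s_xy, s_xy)
    lhs[:n1, n1 + n2] = 1.0
    lhs[n1 + n2, :n1] = 1.0
    if n2 > 0:
        lhs[n1:n1 + n2, n1 + n2 + 1] = 1.0
        lhs[n1 + n2 + 1, n1:n1 + n2] = 1.0

    rhs = np.zeros(dim)
    rhs[:n1] = cov_between(model, "11", p_xy, bp).mean(axis=1)
    if n2 > 0:
        rhs[n1:n1 + n2] = cov_between(model, "12", s_xy, bp).mean(axis=1)
    rhs[n1 + n2] = 1.0  # sum(lam1) = 1; secondary target stays 0

    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular kriging system (n1={n1}, n2={n2}): {exc}"
        ) from exc

    cvv = float(cov_between(model, "11", bp, bp).mean())
    return KrigingSystem(
        lhs=lhs,
        rhs=rhs,
        lam1=sol[:n1],
        lam2=sol[n1:n1 + n2],
        mu1=float(sol[n1 + n2]),
        mu2=float(sol[n1 + n2 + 1]) if n2 > 0 else None,
        cvv=cvv,
        primary_xy=p_xy,
        primary_values=p_val,
        secondary_xy=s_xy,
        secondary_values=s_val,
    )


def kriging_variance(system: KrigingSystem) -> float:
    """sigma^2 = Cbar(v,v) - lam' c - mu1 (ordinary cokriging variance)."""
    n = len(system.lam1) + len(system.lam2)
    lam = np.concatenate([system.lam1, system.lam2])
    var = system.cvv - lam @ system.rhs[:n] - system.mu1
    return float(var)


def predict_block(
    system: KrigingSystem,
    subdistrict_id: str = "",
    date: str = "",
) -> BlockPrediction:
    """Estimate and kriging standard error from a solved system.

    Negative estimates (possible with negative weights) are clamped to 0 and
    flagged; tiny negative variances from round-off are clipped.
    """
    est = float(system.lam1 @ system.primary_values)
    if len(system.lam2):
        est += float(system.lam2 @ system.secondary_values)
    var = max(kriging_variance(system), 0.0)
    clamped = est < 0.0
    return BlockPrediction(
        subdistrict_id=subdistrict_id,
        date=date,
        estimate=0.0 if clamped else est,
        se=float(np.sqrt(var)),
        n1=len(system.lam1),
        n2=len(system.lam2),
        method=system.method,
        clamped=clamped,
    )


def _nearest(
    xy: np.ndarray, ids: np.ndarray, target: np.ndarray, k: int, radius: float
) -> np.ndarray:
    """Indices of the k nearest points within radius; ties broken by id."""
    if len(xy) == 0:
        return np.empty(0, dtype=int)
    d = np.hypot(xy[:, 0] - target[0], xy[:, 1] - target[1])
    order = np.lexsort((ids, d))
    order = order[d[order] <= radius]
    return order[:k]


def interpolate_day(
    stations: list[StationRecord],
    covariate: list[CovariateRecord],
    model: CoregionalizationModel,
    subdistricts: list[Subdistrict],
    neighborhood: Neighborhood | None = None,
) -> list[BlockPrediction]:
    """One BCK (or BK-fallback) prediction per subdistrict for one day.

    Neighbors are the k1 nearest stations and k2 nearest non-missing
    covariate cells within the search radius of the block centroid.  Missing
    covariate cells simply never enter the system; a block with zero
    secondary neighbors falls back to plain BK (``method`` records which).
    """
    nb = neighborhood or Neighborhood()
    if len(stations) < nb.min_stations:
        raise ValueError(
            f"day has {len(stations)} stations, fewer than the minimum "
            f"{nb.min_stations}; skip this day"
        )
    date = stations[0].date
    p_xy = np.array([[s.x, s.y] for s in stations])
    p_val = np.array([s.pm25 for s in stations])
    p_ids = np.array([s.station_id for s in stations])
    if covariate:
        s_xy = np.array([[c.x, c.y] for c in covariate])
        s_val = np.array([c.aod for c in covariate])
        s_ids = np.array([c.cell_id for c in covariate])
    else:
        s_xy = np.empty((0, 2))
        s_val = np.empty(0)
        s_ids = np.empty(0, dtype=int)

    out = []
    for sd in subdistricts:
        bp = discretize_block(sd.polygon, nb.m_points)
        ctr = np.array([sd.polygon.centroid.x, sd.polygon.centroid.y])
        isel = _nearest(p_xy, p_ids, ctr, nb.k1, nb.radius_km)
        if len(isel) == 0:  # no station within radius: use global nearest k1
            isel = _nearest(p_xy, p_ids, ctr, nb.k1, np.inf)
        jsel = _nearest(s_xy, s_ids, ctr, nb.k2, nb.radius_km)
        system = solve_bck_system(
            p_xy[isel], p_val[isel],
            s_xy[jsel] if len(jsel) else None,
            s_val[jsel] if len(jsel) else None,
            model, bp,
        )
        out.append(predict_block(system, sd.id, date))
    return out
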