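"""Land-use and traffic predictors evaluated at arbitrary points.

The predictor set mirrors the standard LUR battery for a traffic pollutant:
position and distance-to-centre terms, terrain altitude, census-block
population attributes, green adjacency, and three local traffic metrics
computed in a single 150 m buffer (high-traffic road length, traffic density,
distance to the nearest high-traffic road).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point

from .scene import HIGH_TRAFFIC_VEHICLES, CityScene, RoadSegment, segments_to_arrays

#: canonical predictor ordering; also the stepwise tie-break order
PREDICTOR_SCHEMA: tuple[str, ...] = (
    "x_coord",
    "y_coord",
    "dist_centre",
    "altitude",
    "block_size",
    "block_residents",
    "inv_pop_density",
    "green_adjacent",
    "hi_road_len_150",
    "traffic_density_150",
    "dist_hi_road",
)

DEFAULT_BUFFER_RADIUS = 150.0


class Sign(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNCONSTRAINED = "unconstrained"


@dataclass(frozen=True)
class ExpectedSignTable:
    """Expected direction of association for each predictor.

    Predictors whose fitted slope contradicts the expected direction are
    excluded during model selection; the planar coordinates are left
    unconstrained because they absorb orography and prevailing-wind gradients
    of either sign.
    """

    signs: dict[str, Sign]

    def __post_init__(self) -> None:
        missing = set(PREDICTOR_SCHEMA) - set(self.signs)
        if missing:
            raise ValueError(f"sign table missing predictors: {sorted(missing)}")
        for c in ("x_coord", "y_coord"):
            if self.signs[c] is not Sign.UNCONSTRAINED:
                raise ValueError(f"{c} must be unconstrained")

    def __getitem__(self, name: str) -> Sign:
        return self.signs[name]

    def violates(self, name: str, slope: float) -> bool:
        s = self.signs.get(name, Sign.UNCONSTRAINED)
        if s is Sign.POSITIVE:
            return slope < 0
        if s is Sign.NEGATIVE:
            return slope > 0
        return False


DEFAULT_SIGNS = ExpectedSignTable(
    {
        "x_coord": Sign.UNCONSTRAINED,
        "y_coord": Sign.UNCONSTRAINED,
        "dist_centre": Sign.NEGATIVE,
        "altitude": Sign.NEGATIVE,
        "block_size": Sign.NEGATIVE,
        "block_residents": Sign.POSITIVE,
        "inv_pop_density": Sign.NEGATIVE,
        "green_adjacent": Sign.NEGATIVE,
        "hi_road_len_150": Sign.POSITIVE,
        "traffic_density_150": Sign.POSITIVE,
        "dist_hi_road": Sign.NEGATIVE,
    }
)


def _chord_lengths(
    px: np.ndarray, py: np.ndarray, ax: float, ay: float, bx: float, by: float, radius: float
) -> np.ndarray:
    """Length of one segment A-B inside discs of ``radius`` centred at points.

    The segment parameter t in [0, 1] is clipped to the circle analytically:
    |A + t(B-A) - P|^2 = r^2 is a quadratic in t whose root interval,
    intersected with [0, 1], gives the in-disc portion exactly.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    fx, fy = ax - px, ay - py
    # quadratic: seg2 t^2 + 2(f.d) t + |f|^2 - r^2 = 0
    half_b = fx * dx + fy * dy
    c = fx * fx + fy * fy - radius * radius
    disc = half_b * half_b - seg2 * c
    out = np.zeros_like(px, dtype=float)
    ok = disc > 0
    if np.any(ok):
        sq = np.sqrt(disc[ok])
        t1 = np.clip((-half_b[ok] - sq) / seg2, 0.0, 1.0)
        t2 = np.clip((-half_b[ok] + sq) / seg2, 0.0, 1.0)
        out[ok] = (t2 - t1) * np.sqrt(seg2)
    return out


def _point_segment_distance(
    px: np.ndarray, py: np.ndarray, ax: float, ay: float, bx: float, by: float
) -> np.ndarray:
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / seg2, 0.0, 1.0)
    return np.hypot(ax + t * dx - px, ay + t * dy - py)


def road_length_in_buffer(
    point: tuple[float, float] | np.ndarray,
    roads: Sequence[RoadSegment],
    radius: float = DEFAULT_BUFFER_RADIUS,
    min_vehicles: float = HIGH_TRAFFIC_VEHICLES,
) -> float | np.ndarray:
    """Metres of road with count strictly above ``min_vehicles`` within ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    px, py, scalar = _as_points(point)
    total = np.zeros_like(px)
    for r in roads:
        if r.vehicles_per_day > min_vehicles:
            total += _chord_lengths(px, py, *r.start, *r.end, radius)
    return float(total[0]) if scalar else total


def traffic_density_in_buffer(
    point: tuple[float, float] | np.ndarray,
    roads: Sequence[RoadSegment],
    radius: float = DEFAULT_BUFFER_RADIUS,
) -> float | np.ndarray:
    """Sum of count x in-buffer length over all counted roads, per buffer area.

    Uses every represented road (all carry counts >= 4,000 vehicles/day), not
    only the high-traffic subset.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    px, py, scalar = _as_points(point)
    total = np.zeros_like(px)
    for r in roads:
        total += r.vehicles_per_day * _chord_lengths(px, py, *r.start, *r.end, radius)
    total /= np.pi * radius * radius
    return float(total[0]) if scalar else total


def distance_to_nearest_major_road(
    point: tuple[float, float] | np.ndarray,
    roads: Sequence[RoadSegment],
    min_vehicles: float = HIGH_TRAFFIC_VEHICLES,
) -> float | np.ndarray:
    """Euclidean distance to the closest road strictly above ``min_vehicles``."""
    major = [r for r in roads if r.vehicles_per_day > min_vehicles]
    if not major:
        raise ValueError("no road exceeds the high-traffic threshold; distance undefined")
    px, py, scalar = _as_points(point)
    d = np.full_like(px, np.inf)
    for r in major:
        np.minimum(d, _point_segment_distance(px, py, *r.start, *r.end), out=d)
    return float(d[0]) if scalar else d


def _as_points(point) -> tuple[np.ndarray, np.ndarray, bool]:
    arr = np.asarray(point, dtype=float)
    if arr.ndim == 1:
        return arr[:1] * 0 + arr[0], arr[1:2] * 0 + arr[1], True
    return arr[:, 0], arr[:, 1], False


class PointOutsideBlocksError(ValueError):
    """A query point is not covered by any census block."""


def assemble_predictor_table(points: np.ndarray | pd.DataFrame, city: CityScene) -> pd.DataFrame:
    """One row of predictors per point.

    Block attributes come from the census block covering the point (boundary
    ties resolved toward the smallest block id); altitude is read from the
    scene's terrain field; traffic metrics use the single 150 m buffer.
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = xy[:, 0], xy[:, 1]
    inside = city.contains_points(x, y)
    if not inside.all():
        i = int(np.argmin(inside))
        raise PointOutsideBlocksError(f"point ({x[i]}, {y[i]}) lies outside the city extent")

    order = np.argsort([b.id for b in city.blocks], kind="stable")
    blocks = [city.blocks[i] for i in order]
    tree = STRtree([b.polygon for b in blocks])
    pts = [Point(px, py) for px, py in xy]
    pt_idx, blk_idx = tree.query(pts, predicate="intersects")
    owner = np.full(len(xy), -1, dtype=int)
    # blocks sorted by id: first match per point is the smallest-id cover
    for p, b in sorted(zip(pt_idx, blk_idx), key=lambda t: (t[0], t[1])):
        if owner[p] < 0:
            owner[p] = b
    if np.any(owner < 0):
        i = int(np.argmin(owner))
        raise PointOutsideBlocksError(f"point ({x[i]}, {y[i]}) is covered by no census block")

    chosen = [blocks[i] for i in owner]
    residents = np.array([b.residents for b in chosen], dtype=float)
    area = np.array([b.area for b in chosen], dtype=float)
    with np.errstate(divide="ignore"):
        inv_density = np.where(residents > 0, area / np.maximum(residents, 1e-300), np.nan)

    return pd.DataFrame(
        {
            "x_coord": x,
            "y_coord": y,
            "dist_centre": np.hypot(x - city.centre[0], y - city.centre[1]),
            "altitude": np.asarray(city.altitude_field(x, y), dtype=float),
            "block_size": area,
            "block_residents": residents,
            "inv_pop_density": inv_density,
            "green_adjacent": np.array([float(b.green_adjacent) for b in chosen]),
            "hi_road_len_150": road_length_in_buffer(xy, city.roads),
            "traffic_density_150": traffic_density_in_buffer(xy, city.roads),
            "dist_hi_road": distance_to_nearest_major_road(xy, city.roads),
        }
    )
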