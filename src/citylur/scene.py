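"""Domain containers for a planar study area.

Coordinates are planar metres in a projected system (the real-world analogue
is a UTM zone); no geodesy is performed anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

#: roads below this daily count carry no traffic data and are never represented
MIN_COUNTED_VEHICLES = 4_000
#: strict threshold above which a road is "high traffic"
HIGH_TRAFFIC_VEHICLES = 10_000


class ConfigurationError(ValueError):
    """Invalid scene or simulation configuration."""


@dataclass(frozen=True)
class RoadSegment:
    """Straight road segment with a daily traffic count.

    Only roads with at least :data:`MIN_COUNTED_VEHICLES` vehicles/day exist in
    a scene; a segment is *high traffic* iff its count strictly exceeds
    :data:`HIGH_TRAFFIC_VEHICLES`.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    vehicles_per_day: float

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ConfigurationError("road segment endpoints must be distinct")
        if self.vehicles_per_day < MIN_COUNTED_VEHICLES:
            raise ConfigurationError(
                f"roads below {MIN_COUNTED_VEHICLES} vehicles/day carry no "
                f"count data and cannot be represented (got {self.vehicles_per_day})"
            )

    @property
    def is_high_traffic(self) -> bool:
        return self.vehicles_per_day > HIGH_TRAFFIC_VEHICLES

    @property
    def length(self) -> float:
        return float(np.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1]))

    def as_linestring(self) -> LineString:
        return LineString([self.start, self.end])


@dataclass(frozen=True)
class CensusBlock:
    """Smallest enumeration unit carrying population and terrain attributes."""

    id: int
    polygon: Polygon
    residents: int
    area: float
    altitude: float
    green_adjacent: bool

    def __post_init__(self) -> None:
        if self.residents < 0:
            raise ConfigurationError("block residents must be >= 0")
        if self.area <= 0:
            raise ConfigurationError("block area must be > 0")

    @property
    def inv_pop_density(self) -> float:
        """m^2 per person; defined only for inhabited blocks."""
        if self.residents <= 0:
            raise ValueError(f"inverse population density undefined for empty block {self.id}")
        return self.area / self.residents


@dataclass
class CityScene:
    """A square study area: roads, census blocks, terrain, and a city centre."""

    extent: float
    centre: tuple[float, float]
    roads: list[RoadSegment]
    blocks: list[CensusBlock]
    altitude_field: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if self.extent <= 0:
            raise ConfigurationError("extent must be positive")
        if not self._inside(*self.centre):
            raise ConfigurationError("city centre lies outside the extent")
        for r in self.roads:
            for x, y in (r.start, r.end):
                if not self._inside(x, y):
                    raise ConfigurationError(f"road endpoint ({x}, {y}) outside extent")

    def _inside(self, x: float, y: float) -> bool:
        return 0.0 <= x <= self.extent and 0.0 <= y <= self.extent

    def contains_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.extent) & (y >= 0) & (y <= self.extent)

    @property
    def high_traffic_roads(self) -> list[RoadSegment]:
        return [r for r in self.roads if r.is_high_traffic]


def segments_to_arrays(roads: Sequence[RoadSegment]):
    """(ax, ay, bx, by, vehicles) arrays for vectorised geometry."""
    if not roads:
        z = np.empty(0)
        return z, z, z, z, z
    a = np.array([r.start for r in roads], dtype=float)
    b = np.array([r.end for r in roads], dtype=float)
    v = np.array([r.vehicles_per_day for r in roads], dtype=float)
    return a[:, 0], a[:, 1], b[:, 0], b[:, 1], v
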