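"""Urban-scene geometry primitives shared by the generator, covariate and barrier code."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely.ops import unary_union

LayoutKind = Literal["orthogonal", "irregular"]


@dataclass
class Building:
    footprint: Polygon
    height: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"building height must be > 0, got {self.height}")


@dataclass
class UrbanScene:
    """A rectangular urban scene: building footprints with heights plus road polygons.

    Coordinates are projected meters with the origin at the scene's south-west
    corner. ``meta`` carries generator bookkeeping (street axis positions) used
    to derive walking routes; it is optional for externally loaded scenes.
    """

    extent: tuple[float, float]
    buildings: list[Building]
    roads: list[Polygon]
    layout_kind: LayoutKind = "orthogonal"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w, h = self.extent
        if not (w > 0 and h > 0):
            raise ValueError(f"extent must be positive, got {self.extent}")

    # -- cached unions -------------------------------------------------
    def building_union(self):
        if "_bu" not in self.meta:
            self.meta["_bu"] = unary_union([b.footprint for b in self.buildings])
        return self.meta["_bu"]

    def road_union(self):
        if "_ru" not in self.meta:
            self.meta["_ru"] = unary_union(list(self.roads))
        return self.meta["_ru"]

    def contains_building(self, x, y) -> np.ndarray:
        """Vectorized point-in-building test."""
        pts = shapely.points(np.asarray(x, float), np.asarray(y, float))
        return shapely.contains(self.building_union(), pts)

    def wall_segments(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exterior-ring wall segments as (start (S,2), end (S,2), height (S,)) arrays."""
        starts, ends, heights = [], [], []
        for b in self.buildings:
            xy = np.asarray(b.footprint.exterior.coords)
            starts.append(xy[:-1])
            ends.append(xy[1:])
            heights.append(np.full(len(xy) - 1, b.height))
        if not starts:
            z = np.zeros((0, 2))
            return z, z, np.zeros(0)
        return np.vstack(starts), np.vstack(ends), np.concatenate(heights)

    def translated(self, dx: float, dy: float) -> "UrbanScene":
        return UrbanScene(
            extent=self.extent,
            buildings=[
                Building(shapely.affinity.translate(b.footprint, dx, dy), b.height)
                for b in self.buildings
            ],
            roads=[shapely.affinity.translate(r, dx, dy) for r in self.roads],
            layout_kind=self.layout_kind,
        )

    def validate(self) -> None:
        """Check scene invariants; raises ValueError on violation."""
        w, h = self.extent
        box = shapely.box(0, 0, w, h).buffer(1e-6)
        for b in self.buildings:
            if not box.contains(b.footprint):
                raise ValueError("building outside extent")
        for r in self.roads:
            if not box.contains(r):
                raise ValueError("road outside extent")
        if self.buildings and self.roads:
            if self.building_union().intersection(self.road_union()).area > 1e-6:
                raise ValueError("buildings overlap roads")


@dataclass
class WalkRoute:
    """A walking route: polyline vertices (meters), speed and sampling interval."""

    vertices: np.ndarray
    speed: float = 0.8
    interval: float = 1.0
    directions: Literal["forward", "forward+backward"] = "forward"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("route vertices must be an (N, 2) array")
        if not self.speed > 0:
            raise ValueError("walking speed must be > 0")
        if not self.interval > 0:
            raise ValueError("sampling interval must be > 0")

    @property
    def length(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    def sample_positions(self) -> np.ndarray:
        """Positions at every sampling tick, in walk order.

        Forward pass yields ``floor(L / (speed * interval)) + 1`` points; the
        backward pass (if enabled) retraces the polyline end-to-start with the
        same count.
        """
        step = self.speed * self.interval
        n = int(np.floor(self.length / step)) + 1
        fwd = _points_along(self.vertices, np.arange(n) * step)
        if self.directions == "forward":
            return fwd
        bwd = _points_along(self.vertices[::-1], np.arange(n) * step)
        return np.vstack([fwd, bwd])

    def on_roads(self, scene: UrbanScene, tol: float = 1e-6) -> bool:
        line = LineString(self.vertices)
        return scene.road_union().buffer(tol).contains(line)


def _points_along(vertices: np.ndarray, dists: np.ndarray) -> np.ndarray:
    seg = np.diff(vertices, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    d = np.clip(dists, 0.0, cum[-1])
    idx = np.clip(np.searchsorted(cum, d, side="right") - 1, 0, len(seglen) - 1)
    frac = np.where(seglen[idx] > 0, (d - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0), 0.0)
    return vertices[idx] + seg[idx] * frac[:, None]
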