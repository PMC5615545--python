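"""Synthetic urban scenes, PM fields and walking transects.

Generates data with the statistical structure the downstream analysis
assumes: a street-grid scene (orthogonal or jittered-irregular), a PM2.5 /
PM10 truth field built from a mean level, an optional covariate-linked
trend, a Gaussian random field with a prescribed variogram and exponential
roadside hotspot kernels, and a 1 Hz walking transect with humidity
inflation, GPS position noise and multiplicative instrument noise. The walk
generator applies the *forward* model that the humidity correction inverts,
so a noiseless round trip is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import Polygon
import shapely

from .covariates import COVARIATE_NAMES, covariate_grids
from .geometry import Building, LayoutKind, UrbanScene, WalkRoute
from .grids import GridSpec
from .preprocess import TransectRecord, correction_factor
from .variogram import VariogramModel, unit_structure

log = logging.getLogger(__name__)

MAX_DENSE_CELLS = 8000

DEFAULT_TRUE_VARIOGRAM = VariogramModel(kind="stable", nugget=0.0,
                                        partial_sill=9.0, range_param=25.0,
                                        shape=1.0)


@dataclass(frozen=True)
class Hotspot:
    """Localized roadside source: amplitude * exp(-d / decay)."""

    x: float
    y: float
    amplitude: float
    decay: float

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError("hotspot decay length must be > 0")


@dataclass
class FieldTruth:
    """Ground-truth PM rasters plus the parameters that generated them."""

    grid: GridSpec
    pm25: np.ndarray
    pm10: np.ndarray
    true_variogram: VariogramModel
    hotspots: list[Hotspot] = field(default_factory=list)
    covariate_betas: dict = field(default_factory=dict)
    mean_level: float = 30.0

    def __post_init__(self) -> None:
        if np.any(self.pm25 < 0) or np.any(self.pm10 < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(self.pm10 < self.pm25):
            raise ValueError("pm10 must be >= pm25 cell-wise")


# ------------------------------------------------------------ scenes ------

def make_street_grid(layout_kind: LayoutKind = "orthogonal",
                     extent: tuple[float, float] = (500.0, 500.0),
                     block_size: float = 80.0, road_width: float = 20.0,
                     height_law: tuple[float, float] = (40.0, 15.0),
                     seed: int = 0, building_margin: float = 5.0) -> UrbanScene:
    """Street-grid scene: road strips on a lattice, one building per block.

    The orthogonal layout places ``floor(extent / (block + road))`` blocks per
    axis. The irregular layout starts from the same lattice and applies
    seeded jitter to street positions and building insets, plus random block
    splits into two buildings.
    """
    if road_width <= 0 or block_size <= road_width:
        raise ValueError("need block_size > road_width > 0")
    w, h = extent
    if w <= 0 or h <= 0:
        raise ValueError("extent must be positive")
    if layout_kind not in ("orthogonal", "irregular"):
        raise ValueError(f"unknown layout kind {layout_kind!r}")
    rng = np.random.default_rng(seed)
    period = block_size + road_width
    nbx = int(np.floor(w / period))
    nby = int(np.floor(h / period))
    if nbx < 1 or nby < 1:
        raise ValueError("extent too small for one block")

    xs = np.arange(nbx + 1) * period   # road strip left edges (last may overflow)
    ys = np.arange(nby + 1) * period
    if layout_kind == "irregular":
        jx = rng.uniform(-0.15, 0.15, nbx - 1) * block_size if nbx > 1 else np.zeros(0)
        jy = rng.uniform(-0.15, 0.15, nby - 1) * block_size if nby > 1 else np.zeros(0)
        xs = xs.astype(float)
        ys = ys.astype(float)
        xs[1:nbx] += jx
        ys[1:nby] += jy

    roads: list[Polygon] = []
    v_xs, h_ys = [], []
    for x0 in xs[:nbx]:
        roads.append(shapely.box(x0, 0.0, x0 + road_width, h))
        v_xs.append(x0 + road_width / 2.0)
    for y0 in ys[:nby]:
        roads.append(shapely.box(0.0, y0, w, y0 + road_width))
        h_ys.append(y0 + road_width / 2.0)

    mean_h, sd_h = height_law
    buildings: list[Building] = []
    for i in range(nbx):
        bx0 = xs[i] + road_width
        bx1 = xs[i + 1] if i + 1 < len(xs) else bx0 + block_size
        bx1 = min(bx1, w)
        for j in range(nby):
            by0 = ys[j] + road_width
            by1 = ys[j + 1] if j + 1 < len(ys) else by0 + block_size
            by1 = min(by1, h)
            if layout_kind == "orthogonal":
                insets = np.full(4, building_margin)
                split = False
            else:
                insets = rng.uniform(0.5 * building_margin, 1.8 * building_margin, 4)
                split = rng.random() < 0.35
            fx0, fy0 = bx0 + insets[0], by0 + insets[1]
            fx1, fy1 = bx1 - insets[2], by1 - insets[3]
            if fx1 - fx0 < 2 or fy1 - fy0 < 2:
                continue
            height = float(max(3.0, rng.normal(mean_h, sd_h)))
            if split and fx1 - fx0 > 12:
                cut = rng.uniform(0.35, 0.65) * (fx1 - fx0)
                gap = min(4.0, 0.2 * (fx1 - fx0))
                h2 = float(max(3.0, rng.normal(mean_h, sd_h)))
                buildings.append(Building(shapely.box(fx0, fy0, fx0 + cut - gap / 2, fy1), height))
                buildings.append(Building(shapely.box(fx0 + cut + gap / 2, fy0, fx1, fy1), h2))
            else:
                buildings.append(Building(shapely.box(fx0, fy0, fx1, fy1), height))

    scene = UrbanScene(extent=extent, buildings=buildings, roads=roads,
                       layout_kind=layout_kind,
                       meta={"v_road_xs": v_xs, "h_road_ys": h_ys,
                             "block_size": block_size, "road_width": road_width})
    return scene


def default_route(scene: UrbanScene, speed: float = 0.8, interval: float = 1.0,
                  directions: str = "forward+backward") -> WalkRoute:
    """Boustrophedon route along the scene's horizontal street centerlines."""
    v_xs = scene.meta.get("v_road_xs")
    h_ys = scene.meta.get("h_road_ys")
    if not v_xs or not h_ys:
        raise ValueError("scene carries no street metadata; supply a route explicitly")
    x_left, x_right = v_xs[0], v_xs[-1]
    verts = []
    for k, yc in enumerate(h_ys):
        if k % 2 == 0:
            verts += [(x_left, yc), (x_right, yc)]
        else:
            verts += [(x_right, yc), (x_left, yc)]
    return WalkRoute(vertices=np.asarray(verts, float), speed=speed,
                     interval=interval, directions=directions)


def roadside_hotspots(scene: UrbanScene, n: int = 6,
                      amplitude_range: tuple[float, float] = (25.0, 45.0),
                      decay_range: tuple[float, float] = (10.0, 20.0),
                      seed: int = 0) -> list[Hotspot]:
    """Random localized sources placed on the road network."""
    rng = np.random.default_rng(seed)
    roads = scene.road_union()
    w, h = scene.extent
    spots: list[Hotspot] = []
    while len(spots) < n:
        x, y = rng.uniform(0, w), rng.uniform(0, h)
        if roads.is_empty or shapely.contains(roads, shapely.points(x, y)):
            spots.append(Hotspot(x=float(x), y=float(y),
                                 amplitude=float(rng.uniform(*amplitude_range)),
                                 decay=float(rng.uniform(*decay_range))))
    return spots


# ------------------------------------------------------------- field ------

def _grf(dist: np.ndarray, model: VariogramModel, rng: np.random.Generator,
         jitter: float = 1e-8) -> np.ndarray:
    """One zero-mean GRF realization from a dense covariance factorization."""
    C = model.partial_sill * (1.0 - unit_structure(model, dist))
    C[np.diag_indices_from(C)] += model.partial_sill * jitter + 1e-12
    L = np.linalg.cholesky(C)
    z = L @ rng.standard_normal(len(C))
    if model.nugget > 0:
        z = z + np.sqrt(model.nugget) * rng.standard_normal(len(C))
    return z


def simulate_grf_points(points, model: VariogramModel, seed: int = 0,
                        mean: float = 0.0) -> np.ndarray:
    """GRF realization at arbitrary coordinates (dense Cholesky)."""
    pts = np.asarray(points, float)
    if len(pts) > MAX_DENSE_CELLS:
        raise ValueError(f"dense factorization capped at {MAX_DENSE_CELLS} points")
    rng = np.random.default_rng(seed)
    return mean + _grf(squareform(pdist(pts)), model, rng)


def hotspot_field(hotspots: list[Hotspot], x: np.ndarray, y: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(x, float))
    for hs in hotspots:
        d = np.hypot(x - hs.x, y - hs.y)
        out = out + hs.amplitude * np.exp(-d / hs.decay)
    return out


def simulate_pm_field(scene: UrbanScene,
                      true_variogram: VariogramModel = DEFAULT_TRUE_VARIOGRAM,
                      hotspots: list[Hotspot] | None = None,
                      covariate_betas: dict | None = None,
                      mean_level: float = 30.0, seed: int = 0,
                      cell_size: float | None = None,
                      pm10_ratio: float = 1.6,
                      pm10_extra_sill: float | None = None) -> FieldTruth:
    """Simulate the PM2.5/PM10 truth rasters on the scene's extent.

    pm25 = mean_level + covariate trend + GRF(true_variogram) + hotspots,
    clamped at 0. pm10 = pm25 * ratio + independent GRF component, then
    cell-wise max with pm25. Dense covariance factorization caps the raster
    at 8000 cells; choose a coarser ``cell_size`` if exceeded.
    """
    if mean_level <= 0:
        raise ValueError("mean_level must be > 0")
    w, h = scene.extent
    if cell_size is None:
        cell_size = max(w, h) / 70.0
    grid = GridSpec.from_extent(w, h, cellsize=cell_size)
    if grid.n_cells > MAX_DENSE_CELLS:
        raise ValueError(
            f"{grid.n_cells} cells exceeds the dense-factorization cap of "
            f"{MAX_DENSE_CELLS}; use a coarser grid (cell_size >= "
            f"{max(w, h) / np.floor(np.sqrt(MAX_DENSE_CELLS)):.2f} m)")
    rng = np.random.default_rng(seed)
    centers = grid.cell_centers()
    X, Y = centers[:, 0], centers[:, 1]

    mean_field = np.full(grid.n_cells, float(mean_level))
    betas = {k: v for k, v in (covariate_betas or {}).items() if v != 0.0}
    if betas:
        unknown = set(betas) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariate betas: {sorted(unknown)}")
        grids_cov = covariate_grids(scene, grid)
        for name, beta in betas.items():
            cov = grids_cov[name].ravel()
            mean_field = mean_field + beta * (cov - cov.mean())

    dist = squareform(pdist(centers))
    grf25 = _grf(dist, true_variogram, rng) if true_variogram.sill > 0 else np.zeros(grid.n_cells)
    pm25 = mean_field + grf25 + hotspot_field(hotspots or [], X, Y)
    pm25 = np.maximum(pm25, 0.0)

    if pm10_extra_sill is None:
        pm10_extra_sill = 0.5 * true_variogram.partial_sill
    if pm10_extra_sill > 0:
        extra_model = VariogramModel(kind=true_variogram.kind, nugget=0.0,
                                     partial_sill=pm10_extra_sill,
                                     range_param=true_variogram.range_param,
                                     shape=true_variogram.shape)
        grf10 = _grf(dist, extra_model, rng)
    else:
        grf10 = np.zeros(grid.n_cells)
    pm10 = np.maximum(pm25 * pm10_ratio + grf10, pm25)

    return FieldTruth(grid=grid, pm25=pm25.reshape(grid.shape),
                      pm10=pm10.reshape(grid.shape),
                      true_variogram=true_variogram,
                      hotspots=list(hotspots or []),
                      covariate_betas=dict(covariate_betas or {}),
                      mean_level=float(mean_level))


def default_dataset(seed: int = 1, cell_size: float | None = 500.0 / 60.0,
                    covariate_betas: dict | None = None) -> dict:
    """One canonical synthetic scene + truth + transect bundle.

    The same recipe backs the demo pipeline and the distribution-level
    checks: a 500 m orthogonal street grid, a stable range-25 m field with
    eight strong roadside hotspots and a weak covariate trend, and a
    forward+backward 1 Hz walk.
    """
    if covariate_betas is None:
        covariate_betas = {"svf50": -1.0, "fai50": 2.0, "rda50": 1.5}
    scene = make_street_grid("orthogonal", seed=seed)
    hotspots = roadside_hotspots(scene, n=8, amplitude_range=(30.0, 45.0),
                                 decay_range=(14.0, 20.0), seed=seed + 100)
    truth = simulate_pm_field(scene, DEFAULT_TRUE_VARIOGRAM, hotspots,
                              covariate_betas=covariate_betas,
                              mean_level=30.0, seed=seed + 200,
                              cell_size=cell_size)
    route = default_route(scene)
    records = simulate_walk(route, truth, seed=seed + 300)
    return {"scene": scene, "truth": truth, "route": route, "records": records}


# -------------------------------------------------------------- walk ------

START_TIME = datetime(2015, 6, 15, 14, 0, 0, tzinfo=timezone.utc)


def simulate_walk(route: WalkRoute, truth: FieldTruth,
                  rh_mean: float = 0.85, rh_ar1: tuple[float, float] = (0.95, 0.004),
                  gps_sigma: float = 2.0, instrument_noise_cv: float = 0.05,
                  seed: int = 0, temp_c: float = 30.0) -> list[TransectRecord]:
    """Walk the route over the truth field and emit raw transect records.

    One record per sampling tick. Raw PM is the bilinear field value at the
    *true* position, inflated by the humidity correction factor CF(RH) and by
    one shared multiplicative instrument-noise draw per tick (shared between
    the PM2.5 and PM10 channels, preserving pm10 >= pm25). Reported positions
    add isotropic Gaussian GPS noise. RH follows a clipped AR(1) around
    ``rh_mean``.
    """
    if not (0.0 < rh_mean < 1.0):
        raise ValueError("rh_mean must lie in (0, 1)")
    if route.length <= 0:
        raise ValueError("route length must be > 0")
    rng = np.random.default_rng(seed)
    pos = route.sample_positions()
    n = len(pos)

    rho, sigma = rh_ar1
    rh = np.empty(n)
    level = 0.0
    for t in range(n):
        level = rho * level + sigma * rng.standard_normal()
        rh[t] = rh_mean + level
    n_clip = int(np.sum(rh >= 1.0))
    if n_clip:
        log.warning("clipping %d RH excursions >= 1 to 0.99", n_clip)
    rh = np.clip(rh, 0.0, 0.99)

    true25 = truth.grid.bilinear(truth.pm25, pos[:, 0], pos[:, 1])
    true10 = truth.grid.bilinear(truth.pm10, pos[:, 0], pos[:, 1])
    cf = correction_factor(rh)
    noise = 1.0 + instrument_noise_cv * rng.standard_normal(n) if instrument_noise_cv > 0 \
        else np.ones(n)
    noise = np.maximum(noise, 0.0)
    raw25 = true25 * cf * noise
    raw10 = true10 * cf * noise
    gps = rng.normal(0.0, gps_sigma, size=(n, 2)) if gps_sigma > 0 else np.zeros((n, 2))
    xy = pos + gps

    records = []
    for t in range(n):
        records.append(TransectRecord(
            time=START_TIME + timedelta(seconds=t * route.interval),
            x=float(xy[t, 0]), y=float(xy[t, 1]),
            pm25_raw=float(raw25[t]), pm10_raw=float(raw10[t]),
            temp=float(temp_c + 0.5 * rng.standard_normal()), rh=float(rh[t]),
        ))
    return records
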