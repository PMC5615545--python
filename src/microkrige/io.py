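"""File formats: transect CSV, scene GeoJSON, ESRI ASCII grids, TIFF rasters.

Conventions (honored everywhere): coordinates are projected meters; rasters
are cell-registered with a north-west origin, row-major; ASCII NODATA is
-9999.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape
from shapely.ops import orient

from .geometry import Building, UrbanScene
from .grids import GridSpec
from .interpolate.surface import PredictionSurface
from .preprocess import TRANSECT_COLUMNS, CleanPoint, TransectRecord

log = logging.getLogger(__name__)

NODATA = -9999.0


# ------------------------------------------------------- transect CSV -----

def write_transect_csv(records: list[TransectRecord], path) -> None:
    df = pd.DataFrame({
        "time_iso": [r.time.isoformat() for r in records],
        "x": [r.x for r in records], "y": [r.y for r in records],
        "pm25_raw": [r.pm25_raw for r in records],
        "pm10_raw": [r.pm10_raw for r in records],
        "temp_c": [r.temp for r in records],
        "rh_frac": [r.rh for r in records],
    })
    df.to_csv(path, index=False, float_format="%.10g")


def read_transect_csv(path) -> list[TransectRecord]:
    """Schema-validated transect reader.

    RH given in percent (values > 1.5) is normalized to a fraction with a log
    line; rows with missing PM readings are dropped and counted.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRANSECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"transect CSV {path} is missing required columns: {missing}")
    n0 = len(df)
    df = df.dropna(subset=["pm25_raw", "pm10_raw"])
    if len(df) < n0:
        log.info("dropped %d rows with missing PM readings", n0 - len(df))
    rh = df["rh_frac"].to_numpy(float)
    if np.nanmax(rh, initial=0.0) > 1.5:
        log.info("rh_frac looks like percent; dividing by 100")
        rh = rh / 100.0
    return [
        TransectRecord(time=datetime.fromisoformat(str(t)), x=float(x), y=float(y),
                       pm25_raw=float(p25), pm10_raw=float(p10),
                       temp=float(tc), rh=float(r))
        for t, x, y, p25, p10, tc, r in zip(
            df["time_iso"], df["x"], df["y"], df["pm25_raw"], df["pm10_raw"],
            df["temp_c"], rh)
    ]


def write_clean_csv(points: list[CleanPoint], path) -> None:
    pd.DataFrame({
        "x": [p.x for p in points], "y": [p.y for p in points],
        "pm25": [p.pm25 for p in points], "pm10": [p.pm10 for p in points],
        "n_merged": [p.n_merged for p in points],
    }).to_csv(path, index=False, float_format="%.10g")


def read_clean_csv(path) -> list[CleanPoint]:
    df = pd.read_csv(path)
    return [CleanPoint(x=float(r.x), y=float(r.y), pm25=float(r.pm25),
                       pm10=float(r.pm10), n_merged=int(r.n_merged))
            for r in df.itertuples()]


# ------------------------------------------------------ scene GeoJSON -----

def write_scene_geojson(scene: UrbanScene, path) -> None:
    feats = []
    for b in scene.buildings:
        feats.append({"type": "Feature",
                      "properties": {"kind": "building", "height": b.height},
                      "geometry": mapping(orient(b.footprint))})
    for r in scene.roads:
        feats.append({"type": "Feature", "properties": {"kind": "road"},
                      "geometry": mapping(orient(r))})
    doc = {"type": "FeatureCollection",
           "properties": {"layout_kind": scene.layout_kind,
                          "extent": list(scene.extent),
                          "crs_note": "projected meters, local origin"},
           "features": feats}
    Path(path).write_text(json.dumps(doc))


def read_scene_geojson(path) -> UrbanScene:
    """Read a scene; validates heights, repairs ring orientation and rejects
    geographic (degree) coordinates."""
    doc = json.loads(Path(path).read_text())
    buildings, roads = [], []
    all_xy = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValueError("scene features must be polygons")
        geom = orient(shapely.make_valid(geom))
        props = feat.get("properties") or {}
        all_xy.append(np.asarray(geom.exterior.coords))
        if props.get("kind") == "road":
            roads.append(geom)
        else:
            if "height" not in props:
                raise ValueError("building feature without a 'height' property")
            buildings.append(Building(geom, float(props["height"])))
    xy = np.vstack(all_xy) if all_xy else np.zeros((0, 2))
    # degree coordinates: inside the lon/lat window with sub-degree spans
    if (len(xy) and np.all(np.abs(xy[:, 0]) <= 180) and np.all(np.abs(xy[:, 1]) <= 90)
            and np.ptp(xy[:, 0]) < 1.0 and np.ptp(xy[:, 1]) < 1.0):
        raise ValueError(
            "coordinates look geographic (degrees); a projected CRS in meters is required")
    props = doc.get("properties") or {}
    if "extent" in props:
        extent = tuple(float(v) for v in props["extent"])
    else:
        extent = (float(xy[:, 0].max()), float(xy[:, 1].max()))
    return UrbanScene(extent=extent, buildings=buildings, roads=roads,
                      layout_kind=props.get("layout_kind", "orthogonal"))


# ------------------------------------------------------------ rasters -----

def write_ascii_grid(grid: GridSpec, values: np.ndarray, path,
                     nodata: float = NODATA) -> None:
    """ESRI ASCII grid, row 0 = northernmost row, full float precision."""
    values = np.asarray(values, float)
    out = np.where(np.isfinite(values), values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
                 f"xllcorner {grid.xll:.10g}\nyllcorner {grid.yll:.10g}\n"
                 f"cellsize {grid.cellsize:.10g}\nNODATA_value {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        values = np.loadtxt(fh).reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    nodata = hdr.get("nodata_value", NODATA)
    values = np.where(values == nodata, np.nan, values)
    grid = GridSpec(xll=hdr["xllcorner"], yll=hdr["yllcorner"],
                    cellsize=hdr["cellsize"], nrows=int(hdr["nrows"]),
                    ncols=int(hdr["ncols"]))
    return grid, values


def write_surface(surface: PredictionSurface, path, format: str = "asc",
                  clamp: bool = True) -> None:
    """Write a prediction surface as ESRI ASCII ('asc') or TIFF ('tif').

    TIFF output is a plain float64 image (no geo-tags; grid registration
    travels in the sidecar manifest written by the pipeline).
    """
    values = surface.concentration if clamp else surface.values
    values = np.where(surface.mask, np.nan, values)
    if format == "asc":
        write_ascii_grid(surface.grid, values, path)
    elif format == "tif":
        import tifffile
        tifffile.imwrite(path, values.astype(np.float64))
    else:
        raise ValueError(f"unknown surface format {format!r}")


def read_surface_values(path, format: str = "asc") -> np.ndarray:
    if format == "asc":
        return read_ascii_grid(path)[1]
    if format == "tif":
        import tifffile
        return tifffile.imread(path)
    raise ValueError(f"unknown surface format {format!r}")
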