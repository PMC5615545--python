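"""Raw transect records -> clean, humidity-corrected, pass-merged points.

Optical PM readings inflate with relative humidity through hygroscopic
particle growth. The applied correction is

    CF(RH) = 1 + 0.25 * RH^2 / (1 - RH),        corrected = raw / CF

with RH as a fraction in [0, 1). Forward/backward walking passes are merged
by greedy spatial clustering within a small radius.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TRANSECT_COLUMNS = ["time_iso", "x", "y", "pm25_raw", "pm10_raw", "temp_c", "rh_frac"]


@dataclass(frozen=True)
class TransectRecord:
    """One timestamped, georeferenced raw PM/weather sample."""

    time: datetime
    x: float
    y: float
    pm25_raw: float
    pm10_raw: float
    temp: float
    rh: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rh < 1.0):
            raise ValueError(f"rh must lie in [0, 1), got {self.rh}")
        if self.pm25_raw < 0 or self.pm10_raw < 0:
            raise ValueError("PM readings must be >= 0")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")


@dataclass(frozen=True)
class CleanPoint:
    """RH-corrected, pass-averaged measurement point."""

    x: float
    y: float
    pm25: float
    pm10: float
    n_merged: int = 1


def correction_factor(rh) -> np.ndarray | float:
    """Humidity growth correction factor, >= 1 and increasing on [0, 1)."""
    rh_arr = np.asarray(rh, float)
    if np.any(rh_arr < 0) or np.any(rh_arr >= 1):
        raise ValueError("rh must lie in [0, 1)")
    cf = 1.0 + 0.25 * rh_arr**2 / (1.0 - rh_arr)
    return cf if cf.ndim else float(cf)


def rh_correction(records: list[TransectRecord]) -> list[TransectRecord]:
    """Divide both PM channels of each record by CF(rh); order preserved."""
    out = []
    for i, rec in enumerate(records):
        try:
            cf = correction_factor(rec.rh)
        except ValueError as exc:
            raise ValueError(f"record {i}: {exc}") from exc
        out.append(replace(rec, pm25_raw=rec.pm25_raw / cf, pm10_raw=rec.pm10_raw / cf))
    return out


def merge_passes(records: list[TransectRecord], merge_radius: float = 2.0) -> list[CleanPoint]:
    """Greedy spatial clustering of (corrected) records into clean points.

    Records are scanned in data order; each record joins the first existing
    cluster whose seed (the founding record's position) lies within
    ``merge_radius``, else founds a new cluster. Cluster members are averaged
    arithmetically (coordinates and both PM channels). Deterministic for a
    fixed input order.
    """
    if merge_radius < 0:
        raise ValueError("merge_radius must be >= 0")
    if not records:
        return []
    seeds = np.empty((len(records), 2))
    n_seeds = 0
    assign = np.empty(len(records), int)
    for i, rec in enumerate(records):
        if n_seeds:
            d2 = (seeds[:n_seeds, 0] - rec.x) ** 2 + (seeds[:n_seeds, 1] - rec.y) ** 2
            j = int(np.argmin(d2))
            if d2[j] <= merge_radius**2:
                assign[i] = j
                continue
        seeds[n_seeds] = (rec.x, rec.y)
        assign[i] = n_seeds
        n_seeds += 1
    x = np.array([r.x for r in records])
    y = np.array([r.y for r in records])
    p25 = np.array([r.pm25_raw for r in records])
    p10 = np.array([r.pm10_raw for r in records])
    counts = np.bincount(assign[: len(records)], minlength=n_seeds)
    out = []
    for j in range(n_seeds):
        m = assign == j
        out.append(CleanPoint(x=float(x[m].mean()), y=float(y[m].mean()),
                              pm25=float(p25[m].mean()), pm10=float(p10[m].mean()),
                              n_merged=int(counts[j])))
    return out


def clean_points_frame(points: list[CleanPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"x": [p.x for p in points], "y": [p.y for p in points],
         "pm25": [p.pm25 for p in points], "pm10": [p.pm10 for p in points],
         "n_merged": [p.n_merged for p in points]}
    )


def preprocess_records(records: list[TransectRecord],
                       merge_radius: float = 2.0) -> list[CleanPoint]:
    """Full preprocessing: RH correction followed by pass merging."""
    return merge_passes(rh_correction(records), merge_radius=merge_radius)
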