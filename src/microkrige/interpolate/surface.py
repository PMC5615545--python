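"""Prediction surface container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids import GridSpec


@dataclass
class PredictionSurface:
    """Regular raster of interpolated concentration.

    ``values`` keeps the raw predictor output (kriging may dip below 0);
    ``concentration`` is the floor-clamped view used for concentration maps.
    ``variance`` is present only where the algorithm defines one (OK/OCK).
    ``mask`` is True on cells without a valid prediction.
    """

    grid: GridSpec
    values: np.ndarray
    variance: np.ndarray | None = None
    mask: np.ndarray | None = None
    method_name: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        if self.variance is not None:
            self.variance = np.asarray(self.variance, float)
            if np.any(self.variance[~self.mask] < -1e-8):
                raise ValueError("negative prediction variance")
            self.variance = np.maximum(self.variance, 0.0)
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError("non-finite values on unmasked cells")

    @property
    def concentration(self) -> np.ndarray:
        return np.maximum(self.values, 0.0)
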