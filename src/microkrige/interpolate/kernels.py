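"""Distance kernels for LPI and barrier smoothing.

All kernels satisfy K(0) = 1 and are nonincreasing on [0, h]. The exponential
kernel is ``exp(-3 r / h)``; the gaussian uses the same e^-3-at-bandwidth
scaling. The remaining kernels are the conventional compact-support forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

KERNEL_KINDS = ("exponential", "polynomial5", "gaussian", "epanechnikov",
                "quartic", "constant")


@dataclass(frozen=True)
class KernelSpec:
    kind: str
    bandwidth: float

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")

    def __call__(self, r) -> np.ndarray:
        return kernel_value(self, r)

    @property
    def compact(self) -> bool:
        return self.kind in ("polynomial5", "epanechnikov", "quartic", "constant")


def kernel_value(spec: KernelSpec, r) -> np.ndarray | float:
    """Evaluate the kernel weight at radius ``r`` (meters)."""
    r_arr = np.asarray(r, float)
    if np.any(r_arr < 0):
        raise ValueError("radius must be >= 0")
    u = r_arr / spec.bandwidth
    kind = spec.kind
    if kind == "exponential":
        w = np.exp(-3.0 * u)
    elif kind == "gaussian":
        w = np.exp(-3.0 * u**2)
    elif kind == "polynomial5":
        w = np.where(u <= 1.0, 1.0 - u**5, 0.0)
    elif kind == "epanechnikov":
        w = np.where(u <= 1.0, 1.0 - u**2, 0.0)
    elif kind == "quartic":
        w = np.where(u <= 1.0, (1.0 - u**2) ** 2, 0.0)
    else:  # constant
        w = np.where(u <= 1.0, 1.0, 0.0)
    return w if w.ndim else float(w)


def scale_weight_factor(values, lo: float = 0.1, hi: float = 1.0) -> np.ndarray:
    """Min-max scale covariate values into [lo, hi] for use as weight factors.

    A constant covariate maps to all-ones (no reweighting).
    """
    v = np.asarray(values, float)
    vmin, vmax = v.min(), v.max()
    if vmax - vmin <= 1e-14:
        return np.ones_like(v)
    return lo + (hi - lo) * (v - vmin) / (vmax - vmin)
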