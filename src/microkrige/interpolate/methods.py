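"""The 13 interpolation configurations and their dispatcher.

Four base algorithms (LPI, OK, OCK, KIB) crossed with covariate choices:
LPI and KIB take an optional covariate *weight factor* (SVF/FAI/RDA, min-max
scaled into [0.1, 1]); OCK takes a covariate *set* ({SVF}, {FAI}, {RDA} or
all three); OK takes none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geometry import UrbanScene
from ..grids import GridSpec
from ..variogram import Coregionalization, VariogramModel
from .barriers import kib_predict
from .kernels import KernelSpec
from .kriging import ock_predict, ok_predict
from .lpi import lpi_predict
from .surface import PredictionSurface

ALGORITHMS = ("LPI", "OK", "OCK", "KIB")
WEIGHT_FACTORS = ("svf50", "fai50", "rda50")
_FACTOR_LABEL = {"svf50": "SVF", "fai50": "FAI", "rda50": "RDA", None: None}

METHOD_NAMES_13 = (
    "LPI", "LPI_SVF", "LPI_FAI", "LPI_RDA",
    "OK",
    "OCK_SVF", "OCK_FAI", "OCK_RDA", "OCK_ALL",
    "KIB", "KIB_SVF", "KIB_FAI", "KIB_RDA",
)


@dataclass(frozen=True)
class MethodConfig:
    """One interpolation configuration (a row of the 13-method comparison)."""

    name: str
    algorithm: str
    weight_factor: str | None = None          # LPI/KIB only
    covariate_set: tuple[str, ...] = ()       # OCK only
    kernel: KernelSpec | None = None          # LPI/KIB
    variogram: VariogramModel | None = None   # OK
    coreg: Coregionalization | None = None    # OCK
    order: int = 1                            # LPI

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.weight_factor is not None:
            if self.algorithm not in ("LPI", "KIB"):
                raise ValueError("weight factors apply to LPI/KIB only")
            if self.weight_factor not in WEIGHT_FACTORS:
                raise ValueError(f"unknown weight factor {self.weight_factor!r}")
        if self.covariate_set and self.algorithm != "OCK":
            raise ValueError("covariate sets apply to OCK only")
        for cv in self.covariate_set:
            if cv not in WEIGHT_FACTORS:
                raise ValueError(f"unknown covariate {cv!r}")


def table1_configs(kernel: KernelSpec | None = None,
                   variogram: VariogramModel | None = None,
                   coregs: dict[tuple[str, ...], Coregionalization] | None = None,
                   order: int = 1) -> list[MethodConfig]:
    """All 13 method configurations.

    ``coregs`` maps each OCK covariate set (sorted tuple) to its fitted
    coregionalization; any fitted ingredient may be None when only the
    structural configuration list is needed.
    """
    coregs = coregs or {}
    cfgs: list[MethodConfig] = []
    for wf in (None, "svf50", "fai50", "rda50"):
        suffix = f"_{_FACTOR_LABEL[wf]}" if wf else ""
        cfgs.append(MethodConfig(name=f"LPI{suffix}", algorithm="LPI",
                                 weight_factor=wf, kernel=kernel, order=order))
    cfgs.append(MethodConfig(name="OK", algorithm="OK", variogram=variogram))
    for cs in (("svf50",), ("fai50",), ("rda50",), ("fai50", "rda50", "svf50")):
        label = "ALL" if len(cs) == 3 else _FACTOR_LABEL[cs[0]]
        cfgs.append(MethodConfig(name=f"OCK_{label}", algorithm="OCK",
                                 covariate_set=tuple(sorted(cs)),
                                 coreg=coregs.get(tuple(sorted(cs)))))
    for wf in (None, "svf50", "fai50", "rda50"):
        suffix = f"_{_FACTOR_LABEL[wf]}" if wf else ""
        cfgs.append(MethodConfig(name=f"KIB{suffix}", algorithm="KIB",
                                 weight_factor=wf, kernel=kernel, order=order))
    assert tuple(c.name for c in cfgs) == METHOD_NAMES_13
    return cfgs


def run_method(config: MethodConfig, points, values, covariate_table=None,
               scene: UrbanScene | None = None, grid: GridSpec | None = None) -> PredictionSurface:
    """Route a MethodConfig to its algorithm and return the surface.

    ``covariate_table`` is a DataFrame (or dict of arrays) of covariate
    values at the sample points, required by any covariate-using method.
    """
    if grid is None:
        raise ValueError("a prediction grid is required")

    def factor_values(name):
        if covariate_table is None:
            raise ValueError(f"method {config.name} needs covariate values ({name})")
        return np.asarray(covariate_table[name], float)

    if config.algorithm == "LPI":
        wf = factor_values(config.weight_factor) if config.weight_factor else None
        return lpi_predict(points, values, config.kernel, grid, order=config.order,
                           weight_factor_values=wf, method_name=config.name)
    if config.algorithm == "OK":
        if config.variogram is None:
            raise ValueError("OK needs a fitted variogram model")
        return ok_predict(points, values, config.variogram, grid,
                          method_name=config.name)
    if config.algorithm == "OCK":
        if config.coreg is None:
            raise ValueError("OCK needs a fitted coregionalization")
        cov_vals = {nm: factor_values(nm) for nm in config.coreg.names[1:]}
        return ock_predict(points, values, cov_vals, config.coreg, grid,
                           method_name=config.name)
    if config.algorithm == "KIB":
        if scene is None:
            raise ValueError("KIB needs the urban scene (barrier layer)")
        wf = factor_values(config.weight_factor) if config.weight_factor else None
        return kib_predict(points, values, config.kernel, scene, grid,
                           weight_factor_values=wf, method_name=config.name)
    raise ValueError(f"unknown algorithm {config.algorithm!r}")  # pragma: no cover
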