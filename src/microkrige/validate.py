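"""Cross-validation of interpolation configurations and comparison tables.

LOOCV holds every sample out in turn and re-predicts it with the remaining
n - 1 samples; the variogram/coregionalization parameters are held fixed at
their full-data fit (local kernel fits are recomputed per fold). RMSE is
``sqrt(mean((pred - obs)^2))``. The 2-fold score is the squared Pearson
correlation of pooled out-of-fold predictions against observations (the
simple-linear-regression R^2), on a seeded random split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import UrbanScene
from .grids import GridSpec
from .interpolate.barriers import BarrierGrid, kib_predict_points
from .interpolate.kernels import KernelSpec, kernel_value, scale_weight_factor
from .interpolate.kriging import (
    kriging_loo_predictions,
    ock_predict_points,
    ock_system,
    ok_predict_points,
    ok_system,
    stack_values,
)
from .interpolate.lpi import lpi_predict_points
from .interpolate.methods import MethodConfig, table1_configs

log = logging.getLogger(__name__)


@dataclass
class CVReport:
    """Per-method cross-validation table plus the run's bookkeeping."""

    table: pd.DataFrame   # columns: method, variable, rmse, r2_kfold, ...
    n: int
    k: int
    seed: int

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "n", self.n)
        out.insert(1, "k", self.k)
        out.insert(2, "seed", self.seed)
        out.to_csv(path, index=False, float_format="%.10g")

    def __str__(self) -> str:
        return (f"CVReport(n={self.n}, k={self.k}, seed={self.seed})\n"
                + self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))


class _Context:
    """Shared per-dataset state (barrier grids, distance matrices)."""

    def __init__(self, points, scene: UrbanScene | None = None,
                 barrier_resolution: float | None = None):
        self.points = np.asarray(points, float)
        self.scene = scene
        self._bgrid = None
        self._bdist = None
        self.barrier_resolution = barrier_resolution

    def barrier_grid(self) -> BarrierGrid | None:
        if self.scene is None or not self.scene.buildings:
            return None
        if self._bgrid is None:
            res = self.barrier_resolution or max(self.scene.extent) / 100.0
            grid = GridSpec.from_extent(self.scene.extent[0], self.scene.extent[1],
                                        cellsize=res)
            self._bgrid = BarrierGrid(self.scene, grid)
        return self._bgrid

    def barrier_point_distances(self) -> np.ndarray:
        """(n, n) barrier distances between sample points (Euclidean if open)."""
        if self._bdist is None:
            bg = self.barrier_grid()
            if bg is None:
                self._bdist = cdist(self.points, self.points)
            else:
                d = bg.distances_from(self.points)
                idx = bg.grid.point_to_index(self.points[:, 0], self.points[:, 1])
                self._bdist = d[:, idx]
        return self._bdist


def _predict_heldout(config: MethodConfig, points, values, covariate_table,
                     ctx: _Context, train_idx, test_points, test_cov_dist=None):
    """Predict at arbitrary locations from a training subset (used by k-fold)."""
    pts = np.asarray(points, float)[train_idx]
    z = np.asarray(values, float)[train_idx]
    if config.algorithm == "LPI":
        wf = None
        if config.weight_factor:
            wf = np.asarray(covariate_table[config.weight_factor], float)[train_idx]
        return lpi_predict_points(pts, z, config.kernel, test_points,
                                  order=config.order, weight_factor_values=wf)
    if config.algorithm == "OK":
        return ok_predict_points(pts, z, config.variogram, test_points)
    if config.algorithm == "OCK":
        cov_vals = {nm: np.asarray(covariate_table[nm], float)[train_idx]
                    for nm in config.coreg.names[1:]}
        return ock_predict_points(pts, z, cov_vals, config.coreg, test_points)
    if config.algorithm == "KIB":
        wf = None
        if config.weight_factor:
            wf = np.asarray(covariate_table[config.weight_factor], float)[train_idx]
        if test_cov_dist is not None:
            # distances already known: direct Nadaraya-Watson
            c = np.ones(len(pts)) if wf is None else scale_weight_factor(wf)
            W = kernel_value(config.kernel, test_cov_dist[:, train_idx]) * c[None, :]
            wsum = W.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(wsum > 1e-12, (W @ z) / np.where(wsum > 0, wsum, 1.0), np.nan)
        return kib_predict_points(pts, z, config.kernel, ctx.scene, test_points,
                                  barrier_grid=ctx.barrier_grid(),
                                  weight_factor_values=wf)
    raise ValueError(f"unknown algorithm {config.algorithm!r}")


def loocv(points, values, config: MethodConfig, covariate_table=None,
          scene: UrbanScene | None = None, ctx: _Context | None = None):
    """Leave-one-out CV: per-point predictions and the RMSE.

    Returns ``(predictions, rmse, n_excluded)``; unpredictable points (empty
    kernel neighborhood) are NaN, excluded from the RMSE and counted.
    """
    pts = np.asarray(points, float)
    z = np.asarray(values, float)
    n = len(pts)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 points")
    ctx = ctx or _Context(pts, scene)

    if config.algorithm in ("LPI", "KIB"):
        if config.algorithm == "LPI":
            dist = cdist(pts, pts)
        else:
            dist = ctx.barrier_point_distances()
        wf = None
        if config.weight_factor:
            wf = np.asarray(covariate_table[config.weight_factor], float)
        preds = np.empty(n)
        keep = np.ones(n, bool)
        for i in range(n):
            keep_i = np.flatnonzero(np.arange(n) != i)
            if config.algorithm == "LPI":
                p = lpi_predict_points(pts[keep_i], z[keep_i], config.kernel,
                                       pts[i:i + 1], order=config.order,
                                       weight_factor_values=None if wf is None else wf[keep_i])
                preds[i] = p[0]
            else:
                c = np.ones(n - 1) if wf is None else scale_weight_factor(wf[keep_i])
                di = dist[i, keep_i]
                finite = np.isfinite(di)
                w = np.zeros(n - 1)
                w[finite] = kernel_value(config.kernel, di[finite]) * c[finite]
                s = w.sum()
                preds[i] = (w @ z[keep_i]) / s if s > 1e-12 else np.nan
        keep = np.isfinite(preds)
    elif config.algorithm == "OK":
        if config.variogram is None:
            raise ValueError("OK needs a fitted variogram")
        A = ok_system(pts, config.variogram)
        vals = np.concatenate([z, [0.0]])
        preds = kriging_loo_predictions(A, lambda i: A[:, i], vals,
                                        [np.array([i]) for i in range(n)])
        keep = np.isfinite(preds)
    elif config.algorithm == "OCK":
        if config.coreg is None:
            raise ValueError("OCK needs a fitted coregionalization")
        A = ock_system(pts, config.coreg)
        cov_vals = {nm: np.asarray(covariate_table[nm], float)
                    for nm in config.coreg.names[1:]}
        vals = stack_values(z, cov_vals, config.coreg.names)
        p1 = len(config.coreg.names)
        row_sets = [np.array([v * n + i for v in range(p1)]) for i in range(n)]
        preds = kriging_loo_predictions(A, lambda i: A[:, i], vals, row_sets)
        keep = np.isfinite(preds)
    else:
        raise ValueError(f"unknown algorithm {config.algorithm!r}")

    n_excluded = int(np.sum(~keep))
    if n_excluded:
        log.warning("%d points unpredictable in LOOCV for %s", n_excluded, config.name)
    rmse = float(np.sqrt(np.mean((preds[keep] - z[keep]) ** 2)))
    return preds, rmse, n_excluded


def kfold_r2(points, values, config: MethodConfig, k: int = 2, seed: int = 0,
             covariate_table=None, scene: UrbanScene | None = None,
             ctx: _Context | None = None, return_rmse: bool = False):
    """k-fold CV squared-Pearson score of pooled out-of-fold predictions."""
    pts = np.asarray(points, float)
    z = np.asarray(values, float)
    n = len(pts)
    if n < 2 * k:
        raise ValueError("need at least 2k points")
    ctx = ctx or _Context(pts, scene)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    preds = np.full(n, np.nan)
    bdist = ctx.barrier_point_distances() if config.algorithm == "KIB" else None
    for fold in folds:
        train = np.setdiff1d(np.arange(n), fold)
        preds[fold] = _predict_heldout(
            config, pts, z, covariate_table, ctx, train, pts[fold],
            test_cov_dist=None if bdist is None else bdist[fold],
        )
    keep = np.isfinite(preds)
    if np.std(z[keep]) <= 1e-14 or np.std(preds[keep]) <= 1e-14:
        warnings.warn("zero-variance data in k-fold CV; R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r = np.corrcoef(preds[keep], z[keep])[0, 1]
        r2 = float(r * r)
    if return_rmse:
        rmse = float(np.sqrt(np.mean((preds[keep] - z[keep]) ** 2)))
        return r2, rmse
    return r2


def compare_kernels(points, values_by_variable: dict, bandwidth: float = 50.0,
                    order: int = 1, k: int = 2, seed: int = 0,
                    kernel_kinds=("exponential", "polynomial5", "gaussian",
                                  "epanechnikov", "quartic", "constant")) -> CVReport:
    """LPI kernel-function comparison: one row per kernel x variable.

    Reports LOOCV RMSE, k-fold RMSE and k-fold R^2, and flags the per-variable
    winner (minimum LOOCV RMSE).
    """
    pts = np.asarray(points, float)
    rows = []
    for variable, vals in values_by_variable.items():
        for kind in kernel_kinds:
            cfg = MethodConfig(name=kind, algorithm="LPI",
                               kernel=KernelSpec(kind=kind, bandwidth=bandwidth),
                               order=order)
            _, rmse, n_excl = loocv(pts, vals, cfg)
            r2, rmse_kfold = kfold_r2(pts, vals, cfg, k=k, seed=seed, return_rmse=True)
            rows.append({"method": kind, "variable": variable, "rmse": rmse,
                         "rmse_kfold": rmse_kfold, "r2_kfold": r2,
                         "n_excluded": n_excl})
    table = pd.DataFrame(rows)
    table["winner"] = False
    for variable in values_by_variable:
        sub = table[table.variable == variable]
        table.loc[sub["rmse"].idxmin(), "winner"] = True
    n = len(pts)
    return CVReport(table=table, n=n, k=k, seed=seed)


def evaluate_methods(points, values_by_variable: dict, configs: list[MethodConfig],
                     covariate_table=None, scene: UrbanScene | None = None,
                     k: int = 2, seed: int = 0,
                     barrier_resolution: float | None = None) -> CVReport:
    """LOOCV RMSE and k-fold R^2 for every config x variable."""
    pts = np.asarray(points, float)
    ctx = _Context(pts, scene, barrier_resolution=barrier_resolution)
    rows = []
    for variable, vals in values_by_variable.items():
        for cfg in configs:
            _, rmse, n_excl = loocv(pts, vals, cfg, covariate_table=covariate_table,
                                    scene=scene, ctx=ctx)
            r2 = kfold_r2(pts, vals, cfg, k=k, seed=seed,
                          covariate_table=covariate_table, scene=scene, ctx=ctx)
            rows.append({"method": cfg.name, "variable": variable,
                         "algorithm": cfg.algorithm,
                         "covariate": _covariate_label(cfg),
                         "rmse": rmse, "r2_kfold": r2, "n_excluded": n_excl})
    return CVReport(table=pd.DataFrame(rows), n=len(pts), k=k, seed=seed)


def _covariate_label(cfg: MethodConfig) -> str:
    if cfg.algorithm == "OCK":
        if len(cfg.covariate_set) == 3:
            return "all"
        return cfg.covariate_set[0] if cfg.covariate_set else "none"
    return cfg.weight_factor or "none"


def compare_methods(points, values_by_variable: dict, configs: list[MethodConfig],
                    covariate_table=None, scene: UrbanScene | None = None,
                    k: int = 2, seed: int = 0,
                    barrier_resolution: float | None = None
                    ) -> tuple[CVReport, pd.DataFrame, pd.DataFrame]:
    """Evaluate all configs and emit the two grouped comparison tables.

    Returns the per-method report plus (a) mean scores grouped by base
    algorithm and (b) mean scores grouped by covariate/weight-factor choice
    (single-covariate choices only, mirroring the none/SVF/FAI/RDA grouping).
    """
    report = evaluate_methods(points, values_by_variable, configs,
                              covariate_table=covariate_table, scene=scene,
                              k=k, seed=seed, barrier_resolution=barrier_resolution)
    t = report.table
    by_algorithm = (t.groupby(["algorithm", "variable"], sort=False)[["rmse", "r2_kfold"]]
                    .mean().reset_index())
    single = t[t.covariate != "all"]
    by_covariate = (single.groupby(["covariate", "variable"], sort=False)[["rmse", "r2_kfold"]]
                    .mean().reset_index())
    return report, by_algorithm, by_covariate


def compare_all_13(points, values_by_variable, kernel: KernelSpec,
                   variogram_model, coregs: dict, covariate_table,
                   scene: UrbanScene | None = None, k: int = 2, seed: int = 0,
                   order: int = 1, barrier_resolution: float | None = None):
    """Convenience wrapper: build the 13 configs and run ``compare_methods``."""
    configs = table1_configs(kernel=kernel, variogram=variogram_model,
                             coregs=coregs, order=order)
    return compare_methods(points, values_by_variable, configs,
                           covariate_table=covariate_table, scene=scene, k=k,
                           seed=seed, barrier_resolution=barrier_resolution)
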