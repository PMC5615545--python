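"""Local polynomial interpolation (kernel-weighted moving polynomial fits)."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..grids import GridSpec
from .kernels import KernelSpec, kernel_value, scale_weight_factor
from .surface import PredictionSurface

_WEIGHT_EPS = 1e-12


def _n_terms(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def _design(dx: np.ndarray, dy: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(dx)]
    if order >= 1:
        cols += [dx, dy]
    if order >= 2:
        cols += [dx * dx, dx * dy, dy * dy]
    return np.stack(cols, axis=-1)


def lpi_predict_points(points, values, kernel: KernelSpec, targets,
                       order: int = 1, weight_factor_values=None,
                       return_diagnostics: bool = False):
    """Predict at arbitrary targets with a kernel-weighted polynomial fit.

    Per target, a polynomial of ``order`` in local coordinates is fitted by
    weighted least squares with weights ``K(r_i) * c_i``; the prediction is
    the fitted intercept. ``c_i`` is 1 unless covariate weight-factor values
    are given, in which case they are min-max scaled into [0.1, 1].

    Rank-deficient or under-populated local fits fall back to lower orders
    (eventually the local weighted mean); targets with no in-bandwidth weight
    are NaN. Returns predictions, plus a per-target fallback-order array when
    ``return_diagnostics`` is set.
    """
    if order not in (0, 1, 2):
        raise ValueError("polynomial order must be 0, 1 or 2")
    pts = np.asarray(points, float)
    z = np.asarray(values, float)
    tg = np.atleast_2d(np.asarray(targets, float))
    c = np.ones(len(pts)) if weight_factor_values is None else \
        scale_weight_factor(weight_factor_values)
    dist = cdist(tg, pts)
    W = kernel_value(kernel, dist) * c[None, :]

    preds = np.full(len(tg), np.nan)
    used_order = np.full(len(tg), -1)
    dx_all = tg[:, None, 0] - pts[None, :, 0]
    dy_all = tg[:, None, 1] - pts[None, :, 1]

    for ordr in range(order, -1, -1):
        todo = np.flatnonzero(used_order < 0)
        if len(todo) == 0:
            break
        m = _n_terms(ordr)
        enough = np.sum(W[todo] > _WEIGHT_EPS, axis=1) >= m
        cand = todo[enough]
        if len(cand) == 0:
            continue
        V = _design(dx_all[cand], dy_all[cand], ordr)      # (t, n, m)
        Wc = W[cand]                                       # (t, n)
        A = np.einsum("tnm,tn,tnk->tmk", V, Wc, V)
        b = np.einsum("tnm,tn,n->tm", V, Wc, z)
        # solve per target, rejecting ill-conditioned systems
        for row, (Ai, bi) in enumerate(zip(A, b)):
            scale = np.sqrt(np.maximum(np.diag(Ai), 1e-300))
            As = Ai / scale[:, None] / scale[None, :]
            try:
                if np.linalg.cond(As) > 1e10:
                    continue
                beta = np.linalg.solve(As, bi / scale) / scale
            except np.linalg.LinAlgError:
                continue
            preds[cand[row]] = beta[0]
            used_order[cand[row]] = ordr
    # pure weighted-mean fallback for anything left with some weight
    left = np.flatnonzero(used_order < 0)
    if len(left):
        wsum = W[left].sum(axis=1)
        ok = wsum > _WEIGHT_EPS
        preds[left[ok]] = (W[left[ok]] @ z) / wsum[ok]
        used_order[left[ok]] = 0
    if return_diagnostics:
        return preds, used_order
    return preds


def lpi_predict(points, values, kernel: KernelSpec, grid: GridSpec,
                order: int = 1, weight_factor_values=None,
                method_name: str = "LPI", chunk: int = 4096) -> PredictionSurface:
    """LPI over a grid; cells where the local fit degrades are flagged."""
    centers = grid.cell_centers()
    preds = np.empty(len(centers))
    orders = np.empty(len(centers), int)
    for lo in range(0, len(centers), chunk):
        p, o = lpi_predict_points(points, values, kernel, centers[lo:lo + chunk],
                                  order=order, weight_factor_values=weight_factor_values,
                                  return_diagnostics=True)
        preds[lo:lo + chunk] = p
        orders[lo:lo + chunk] = o
    values2d = preds.reshape(grid.shape)
    reduced = (orders < order).reshape(grid.shape)
    return PredictionSurface(grid=grid, values=values2d,
                             mask=~np.isfinite(values2d),
                             method_name=method_name,
                             diagnostics={"reduced_order": reduced})
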