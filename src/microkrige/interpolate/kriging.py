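"""Ordinary kriging and ordinary cokriging.

Both solve variogram-based linear systems with unbiasedness constraints:

* OK:  ``[Gamma 1; 1' 0] [lambda; mu] = [gamma0; 1]`` with ``gamma(0) = 0``
  on the diagonal; prediction ``sum lambda_i Z(S_i)``, variance
  ``lambda' gamma0 + mu``.
* OCK: one weight vector per variable and one Lagrange multiplier per
  unbiasedness constraint (primary weights sum to 1, each covariate's
  weights sum to 0), with direct and cross variograms supplied by a linear
  model of coregionalization.

Kriging is an exact interpolator: at a sample location the weight vector is
the corresponding unit vector, the prediction equals the observation and the
variance is zero.

Leave-one-out predictions reuse the inverse of the full system matrix and
downdate it per fold with a partitioned-inverse identity, which turns an
O(n * m^3) refit loop into O(n * m^2).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist, pdist, squareform

from ..grids import GridSpec
from ..variogram import Coregionalization, VariogramModel, model_gamma
from .surface import PredictionSurface


def _check_duplicates(points: np.ndarray) -> None:
    if len(points) < 2:
        return
    d = squareform(pdist(points))
    np.fill_diagonal(d, np.inf)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if d[i, j] < 1e-9:
        raise ValueError(
            f"duplicate sample coordinates at {tuple(points[i])} (indices {i}, {j}); "
            "merge duplicates before kriging"
        )


# ---------------------------------------------------------------- OK ------

def ok_system(points: np.ndarray, model: VariogramModel) -> np.ndarray:
    n = len(points)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = model_gamma(model, squareform(pdist(points)))
    A[n, :n] = A[:n, n] = 1.0
    A[n, n] = 0.0
    return A


def ok_predict_points(points, values, model: VariogramModel, targets,
                      return_var: bool = False, return_weights: bool = False):
    """Ordinary kriging at arbitrary target coordinates (global neighborhood)."""
    pts = np.asarray(points, float)
    z = np.asarray(values, float)
    tg = np.atleast_2d(np.asarray(targets, float))
    if len(pts) < 2:
        raise ValueError("ordinary kriging needs at least 2 points")
    _check_duplicates(pts)
    A = ok_system(pts, model)
    lu = lu_factor(A)
    n = len(pts)
    rhs = np.empty((n + 1, len(tg)))
    rhs[:n] = model_gamma(model, cdist(pts, tg))
    rhs[n] = 1.0
    sol = lu_solve(lu, rhs)
    lam, mu = sol[:n], sol[n]
    preds = lam.T @ z
    out = [preds]
    if return_var:
        var = np.einsum("it,it->t", lam, rhs[:n]) + mu
        out.append(np.maximum(var, 0.0))
    if return_weights:
        out.append(lam.T)
    return out[0] if len(out) == 1 else tuple(out)


def ok_predict(points, values, model: VariogramModel, grid: GridSpec,
               neighborhood: int | None = None,
               method_name: str = "OK") -> PredictionSurface:
    """OK prediction surface with kriging variance.

    ``neighborhood``: None solves one global system (all points); an integer
    k solves a local system on the k nearest samples per cell.
    """
    pts = np.asarray(points, float)
    z = np.asarray(values, float)
    centers = grid.cell_centers()
    if neighborhood is None or neighborhood >= len(pts):
        preds = np.empty(len(centers))
        var = np.empty(len(centers))
        for lo in range(0, len(centers), 16384):
            p, v = ok_predict_points(pts, z, model, centers[lo:lo + 16384],
                                     return_var=True)
            preds[lo:lo + 16384], var[lo:lo + 16384] = p, v
    else:
        _check_duplicates(pts)
        k = int(neighborhood)
        from scipy.spatial import cKDTree
        tree = cKDTree(pts)
        _, idx = tree.query(centers, k=k)
        preds = np.empty(len(centers))
        var = np.empty(len(centers))
        for t, nb in enumerate(idx):
            p, v = ok_predict_points(pts[nb], z[nb], model, centers[t:t + 1],
                                     return_var=True)
            preds[t], var[t] = p[0], v[0]
    return PredictionSurface(grid=grid, values=preds.reshape(grid.shape),
                             variance=var.reshape(grid.shape),
                             method_name=method_name)


# --------------------------------------------------------------- OCK ------

def ock_system(points: np.ndarray, coreg: Coregionalization) -> np.ndarray:
    """Full cokriging matrix for co-located samples of all variables."""
    n = len(points)
    p1 = len(coreg.names)
    D = squareform(pdist(points))
    m = p1 * n + p1
    A = np.zeros((m, m))
    for u in range(p1):
        for v in range(p1):
            A[u * n:(u + 1) * n, v * n:(v + 1) * n] = coreg.gamma(u, v, D)
    for v in range(p1):
        A[p1 * n + v, v * n:(v + 1) * n] = 1.0
        A[v * n:(v + 1) * n, p1 * n + v] = 1.0
    return A


def ock_rhs(points: np.ndarray, coreg: Coregionalization, targets: np.ndarray) -> np.ndarray:
    n, p1 = len(points), len(coreg.names)
    D = cdist(points, targets)
    rhs = np.zeros((p1 * n + p1, len(targets)))
    for u in range(p1):
        rhs[u * n:(u + 1) * n] = coreg.gamma(u, 0, D)
    rhs[p1 * n] = 1.0
    return rhs


def stack_values(values, covariate_values: dict, names) -> np.ndarray:
    """Stacked [z; covariates...; zeros-for-constraints] value vector."""
    z = np.asarray(values, float)
    cols = [z] + [np.asarray(covariate_values[nm], float) for nm in names[1:]]
    return np.concatenate(cols + [np.zeros(len(names))])


def ock_predict_points(points, values, covariate_values: dict,
                       coreg: Coregionalization, targets,
                       return_var: bool = False):
    """Ordinary cokriging at arbitrary targets.

    ``covariate_values`` maps each coregionalization covariate name to its
    values at the sample points.
    """
    pts = np.asarray(points, float)
    tg = np.atleast_2d(np.asarray(targets, float))
    missing = [nm for nm in coreg.names[1:] if nm not in covariate_values]
    if missing:
        raise ValueError(f"missing covariate values for {missing}")
    _check_duplicates(pts)
    n, p1 = len(pts), len(coreg.names)
    A = ock_system(pts, coreg)
    lu = lu_factor(A)
    rhs = ock_rhs(pts, coreg, tg)
    sol = lu_solve(lu, rhs)
    vals = stack_values(values, covariate_values, coreg.names)
    preds = sol.T @ vals
    if return_var:
        var = np.einsum("it,it->t", sol[:p1 * n], rhs[:p1 * n]) + sol[p1 * n]
        return preds, np.maximum(var, 0.0)
    return preds


def ock_predict(points, values, covariate_values: dict, coreg: Coregionalization,
                grid: GridSpec, covariate_grids: dict | None = None,
                method_name: str = "OCK") -> PredictionSurface:
    """OCK prediction surface.

    Note the cokriging predictor only needs covariates at the *sample*
    locations; ``covariate_grids`` is accepted for interface symmetry and
    ignored by the linear predictor.
    """
    centers = grid.cell_centers()
    preds = np.empty(len(centers))
    var = np.empty(len(centers))
    for lo in range(0, len(centers), 8192):
        p, v = ock_predict_points(points, values, covariate_values, coreg,
                                  centers[lo:lo + 8192], return_var=True)
        preds[lo:lo + 8192], var[lo:lo + 8192] = p, v
    return PredictionSurface(grid=grid, values=preds.reshape(grid.shape),
                             variance=var.reshape(grid.shape),
                             method_name=method_name)


# ----------------------------------------------------- LOO machinery ------

def kriging_loo_predictions(A: np.ndarray, rhs_builder, value_vector: np.ndarray,
                            row_sets: list[np.ndarray]) -> np.ndarray:
    """Leave-one-out predictions for an exact-interpolation kriging system.

    ``A`` is the full system matrix, ``value_vector`` the stacked values (0 on
    constraint rows), ``row_sets[i]`` the rows/cols to delete for fold i and
    ``rhs_builder(i)`` the full-size RHS for predicting at held-out point i
    (entries on deleted rows are ignored). Uses the partitioned-inverse
    identity ``(A_-S)^-1 = B_-S - B[-S,S] B[S,S]^-1 B[S,-S]`` with
    ``B = A^-1``.
    """
    B = np.linalg.inv(A)
    preds = np.empty(len(row_sets))
    for i, S in enumerate(row_sets):
        b = rhs_builder(i)
        b = b.copy()
        b[S] = 0.0
        t = B @ b
        corr = B[:, S] @ np.linalg.solve(B[np.ix_(S, S)], t[S])
        x = t - corr
        x[S] = 0.0
        preds[i] = x @ value_vector
    return preds
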