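"""Empirical semivariograms, parametric model fitting and coregionalization.

The semivariance estimator is the classical method-of-moments one: for each
distance bin, half the mean squared difference of all point pairs whose
separation falls in the bin. Parametric models are fitted by Cressie-weighted
least squares (weights ``n(d) / gamma_model(d)^2``) with multi-start over the
stable shape parameter.

Model families (``sill = nugget + partial_sill``, ``gamma(0) = 0``):

* ``stable``:      ``nugget + psill * (1 - exp(-(3 d / range)^omega))``
* ``exponential``: stable with ``omega = 1``
* ``gaussian``:    stable with ``omega = 2``
* ``spherical``:   ``nugget + psill * (1.5 (d/r) - 0.5 (d/r)^3)`` for ``d <= r``

The ``3d/range`` scaling makes ``range_param`` the distance at which the
stable family reaches ~95% of its sill, directly comparable to a reported
"major range".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

MODEL_KINDS = ("stable", "spherical", "exponential", "gaussian")


@dataclass(frozen=True)
class EmpiricalVariogram:
    lag_centers: np.ndarray
    gamma: np.ndarray
    pair_counts: np.ndarray
    max_lag: float
    bin_width: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_centers) <= 0):
            raise ValueError("lag centers must be strictly increasing")
        valid = self.pair_counts > 0
        if np.any(self.gamma[valid] < 0):
            raise ValueError("semivariance must be nonnegative")

    @property
    def n_valid_bins(self) -> int:
        return int(np.sum(self.pair_counts > 0))


@dataclass(frozen=True)
class VariogramModel:
    """Fitted (or prescribed) parametric semivariogram."""

    kind: str
    nugget: float
    partial_sill: float
    range_param: float
    shape: float = 1.0  # stable omega; ignored for spherical
    converged: bool = True

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown variogram kind {self.kind!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial sill must be >= 0")
        if self.range_param <= 0:
            raise ValueError("range parameter must be > 0")
        if self.kind == "stable" and not (0 < self.shape <= 2):
            raise ValueError("stable shape must lie in (0, 2]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def __call__(self, d) -> np.ndarray:
        return model_gamma(self, d)


def model_gamma(model: VariogramModel, d) -> np.ndarray:
    """Evaluate the model semivariance at distances ``d`` (gamma(0) = 0)."""
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    omega = {"exponential": 1.0, "gaussian": 2.0}.get(model.kind, model.shape)
    if model.kind == "spherical":
        u = np.minimum(d / model.range_param, 1.0)
        struct = 1.5 * u - 0.5 * u**3
    else:
        struct = 1.0 - np.exp(-((3.0 * d / model.range_param) ** omega))
    g = np.where(d > 0, model.nugget, 0.0) + model.partial_sill * struct
    return g if g.ndim else float(g)


def unit_structure(model: VariogramModel, d) -> np.ndarray:
    """The model's correlation structure with nugget 0 and partial sill 1."""
    return model_gamma(replace(model, nugget=0.0, partial_sill=1.0), d)


def empirical_semivariogram(points, values, bin_width: float | None = None,
                            max_lag: float | None = None) -> EmpiricalVariogram:
    """Method-of-moments semivariogram on half-open distance bins [lo, hi).

    Defaults: ``max_lag`` is half the maximum pairwise distance and
    ``bin_width = max_lag / 12``. Bins without pairs carry gamma = NaN.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if n < 2:
        raise ValueError("need at least 2 points")
    if len(values) != n:
        raise ValueError("points and values must be aligned")
    d = pdist(points)
    dv2 = pdist(values[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
        if max_lag <= 0:
            raise ValueError("all points are coincident")
    if bin_width is None:
        bin_width = max_lag / 12.0
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    nbins = int(np.ceil(max_lag / bin_width))
    idx = np.floor(d / bin_width).astype(int)
    keep = idx < nbins
    counts = np.bincount(idx[keep], minlength=nbins)
    sums = np.bincount(idx[keep], weights=dv2[keep], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    return EmpiricalVariogram(lag_centers=centers, gamma=gamma,
                              pair_counts=counts, max_lag=float(max_lag),
                              bin_width=float(bin_width))


def empirical_cross_variogram(points, values_a, values_b,
                              bin_width: float | None = None,
                              max_lag: float | None = None) -> EmpiricalVariogram:
    """Cross-semivariogram: half the mean product of increments of two variables."""
    points = np.asarray(points, float)
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    d = pdist(points)
    # pairwise increment products, matching pdist pair order
    i, j = np.triu_indices(len(points), 1)
    prod = (a[i] - a[j]) * (b[i] - b[j])
    if max_lag is None:
        max_lag = 0.5 * float(d.max())
    if bin_width is None:
        bin_width = max_lag / 12.0
    nbins = int(np.ceil(max_lag / bin_width))
    idx = np.floor(d / bin_width).astype(int)
    keep = idx < nbins
    counts = np.bincount(idx[keep], minlength=nbins)
    sums = np.bincount(idx[keep], weights=prod[keep], minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(counts > 0, sums / (2.0 * np.maximum(counts, 1)), np.nan)
    centers = (np.arange(nbins) + 0.5) * bin_width
    # cross gammas may be negative; bypass the direct-variogram invariant
    ev = object.__new__(EmpiricalVariogram)
    object.__setattr__(ev, "lag_centers", centers)
    object.__setattr__(ev, "gamma", gamma)
    object.__setattr__(ev, "pair_counts", counts)
    object.__setattr__(ev, "max_lag", float(max_lag))
    object.__setattr__(ev, "bin_width", float(bin_width))
    return ev


def _cressie_sse(emp: EmpiricalVariogram, model: VariogramModel) -> float:
    valid = (emp.pair_counts > 0) & np.isfinite(emp.gamma)
    g = model_gamma(model, emp.lag_centers[valid])
    g = np.maximum(g, 1e-12)
    return float(np.sum(emp.pair_counts[valid] * (emp.gamma[valid] - g) ** 2 / g**2))


def fit_variogram(emp: EmpiricalVariogram, kind: str = "stable") -> VariogramModel:
    """Fit one model family by Cressie-weighted least squares.

    Multi-start over the stable shape in {0.5, 1, 1.5, 2} (the shape is then
    refined within (0, 2]); nonnegativity is enforced through box bounds.
    Falls back to the best multi-start candidate (``converged=False``) if the
    optimizer reports failure everywhere.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown variogram kind {kind!r}")
    valid = (emp.pair_counts > 0) & np.isfinite(emp.gamma)
    if valid.sum() < 4:
        raise ValueError("need at least 4 non-empty lag bins to fit")
    lags = emp.lag_centers[valid]
    gam = emp.gamma[valid]
    cnt = emp.pair_counts[valid].astype(float)

    sill0 = max(float(np.mean(gam[-max(1, len(gam) // 3):])), 1e-9)
    nug0 = float(np.clip(gam[0], 0.0, sill0))
    above = lags[gam >= 0.95 * sill0]
    rng0 = float(above[0]) if len(above) else float(lags[-1] / 2)
    rng0 = max(rng0, emp.bin_width)

    fit_shape = kind == "stable"

    def residuals(theta):
        nug, psill, rng = theta[:3]
        omega = theta[3] if fit_shape else {"exponential": 1.0, "gaussian": 2.0}.get(kind, 1.0)
        if kind == "spherical":
            u = np.minimum(lags / rng, 1.0)
            g = nug + psill * (1.5 * u - 0.5 * u**3)
        else:
            g = nug + psill * (1.0 - np.exp(-((3.0 * lags / rng) ** omega)))
        g = np.maximum(g, 1e-12)
        return np.sqrt(cnt) * (gam - g) / g

    lo = [0.0, 0.0, emp.bin_width * 1e-3] + ([0.05] if fit_shape else [])
    hi = [sill0 * 4 + 1e-9, sill0 * 4 + 1e-9, emp.max_lag * 10] + ([2.0] if fit_shape else [])
    shape_starts = [0.5, 1.0, 1.5, 2.0] if fit_shape else [None]
    range_starts = sorted({rng0, emp.max_lag / 3, emp.max_lag})

    best, best_sse, any_ok = None, np.inf, False
    for om0 in shape_starts:
        for r0 in range_starts:
            x0 = [nug0, max(sill0 - nug0, 1e-9), r0] + ([om0] if fit_shape else [])
            x0 = np.clip(x0, lo, hi)
            try:
                res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                    max_nfev=400)
            except Exception:  # pragma: no cover - optimizer hiccups
                continue
            model = VariogramModel(
                kind=kind, nugget=float(res.x[0]), partial_sill=float(res.x[1]),
                range_param=float(res.x[2]),
                shape=float(res.x[3]) if fit_shape else {"exponential": 1.0, "gaussian": 2.0}.get(kind, 1.0),
            )
            sse = _cressie_sse(emp, model)
            if sse < best_sse:
                best, best_sse = model, sse
                any_ok = res.success
    if best is None:
        raise RuntimeError("variogram fit failed for every start")
    if not any_ok:
        log.warning("variogram fit did not formally converge; returning best candidate")
        best = replace(best, converged=False)
    return best


def select_model(emp: EmpiricalVariogram,
                 candidate_kinds=MODEL_KINDS) -> tuple[VariogramModel, pd.DataFrame]:
    """Fit every candidate family and pick the minimum weighted-SSE model.

    Ties are broken by the order {stable, spherical, exponential, gaussian}.
    """
    tie_order = {k: i for i, k in enumerate(MODEL_KINDS)}
    rows = []
    fits: dict[str, VariogramModel] = {}
    for kind in candidate_kinds:
        m = fit_variogram(emp, kind)
        fits[kind] = m
        rows.append({"kind": kind, "sse": _cressie_sse(emp, m),
                     "nugget": m.nugget, "partial_sill": m.partial_sill,
                     "range_param": m.range_param, "shape": m.shape})
    table = pd.DataFrame(rows)
    order = sorted(rows, key=lambda r: (r["sse"], tie_order.get(r["kind"], 99)))
    return fits[order[0]["kind"]], table


def major_range(model: VariogramModel) -> float:
    """Distance at which gamma reaches 95% of the sill.

    For the spherical family this is the range parameter itself; the 3d/range
    scaling of the stable family makes it ~= range_param there too.
    """
    if model.partial_sill <= 0:
        warnings.warn("partial sill is 0; major range is degenerate", stacklevel=2)
        return 0.0
    if model.kind == "spherical":
        return model.range_param
    target = 0.95 * model.sill

    def f(d):
        return model_gamma(model, d) - target

    if f(1e-9) >= 0:
        return 0.0
    hi = model.range_param
    while f(hi) < 0:
        hi *= 2
        if hi > model.range_param * 1e6:  # pragma: no cover
            return hi
    return float(brentq(f, 1e-9, hi))


@dataclass(frozen=True)
class Coregionalization:
    """Linear model of coregionalization with a single shared structure.

    All direct and cross variograms share the primary fit's family, range and
    shape; per-variable nuggets are diagonal. ``gamma_uv(d) =
    nugget_u * 1{u==v, d>0} + B[u, v] * g(d)`` with ``g`` the unit-sill
    structure. ``B`` is positive semidefinite, which implies the pairwise
    bound ``B_uv^2 <= B_uu * B_vv``.
    """

    names: tuple[str, ...]
    structure: VariogramModel  # range/shape/kind carrier (unit sill)
    nuggets: np.ndarray        # (p+1,)
    sills: np.ndarray          # B, (p+1, p+1)

    def __post_init__(self) -> None:
        B = np.asarray(self.sills, float)
        if B.shape != (len(self.names), len(self.names)):
            raise ValueError("sill matrix shape mismatch")
        eig = np.linalg.eigvalsh((B + B.T) / 2)
        if eig.min() < -1e-8 * max(eig.max(), 1.0):
            raise ValueError("coregionalization sill matrix is not PSD")

    def gamma(self, u: int, v: int, d) -> np.ndarray:
        d = np.asarray(d, float)
        g = self.sills[u, v] * unit_structure(self.structure, d)
        if u == v:
            g = g + np.where(d > 0, self.nuggets[u], 0.0)
        return g

    def direct_model(self, u: int) -> VariogramModel:
        return replace(self.structure, nugget=float(self.nuggets[u]),
                       partial_sill=float(self.sills[u, u]))


def fit_coregionalization(points, primary_values, covariates,
                          kind: str = "stable",
                          bin_width: float | None = None,
                          max_lag: float | None = None) -> Coregionalization:
    """Fit an LMC for the primary variable plus named covariates.

    The primary direct variogram is fitted first; every other direct and
    cross variogram then reuses its structure (family/range/shape) and only
    refits sill coefficients by weighted least squares. The sill matrix is
    eigenvalue-clipped into the PSD cone, which enforces
    ``|b_uv| <= sqrt(b_uu b_vv)`` for every pair.

    ``covariates`` maps name -> aligned value array. Zero-variance covariates
    are dropped with a warning.
    """
    points = np.asarray(points, float)
    z = np.asarray(primary_values, float)
    cov_items = []
    for name, vals in covariates.items():
        vals = np.asarray(vals, float)
        if np.std(vals) <= 1e-14:
            log.warning("dropping degenerate covariate %r (zero variance)", name)
            continue
        cov_items.append((name, vals))

    emp0 = empirical_semivariogram(points, z, bin_width=bin_width, max_lag=max_lag)
    if emp0.n_valid_bins < 4:
        raise ValueError("need at least 4 non-empty bins")
    primary = fit_variogram(emp0, kind)
    structure = replace(primary, nugget=0.0, partial_sill=1.0)

    names = ("pm",) + tuple(n for n, _ in cov_items)
    all_vals = [z] + [v for _, v in cov_items]
    p1 = len(names)

    valid = (emp0.pair_counts > 0) & np.isfinite(emp0.gamma)
    lags = emp0.lag_centers[valid]
    w = emp0.pair_counts[valid].astype(float)
    g = unit_structure(structure, lags)

    nuggets = np.zeros(p1)
    B = np.zeros((p1, p1))
    nuggets[0] = primary.nugget
    B[0, 0] = primary.partial_sill
    # direct sills/nuggets for covariates: nonneg linear WLS on [1, g(d)]
    for u in range(1, p1):
        emp_u = empirical_semivariogram(points, all_vals[u],
                                        bin_width=emp0.bin_width, max_lag=emp0.max_lag)
        gam_u = emp_u.gamma[valid]
        A = np.column_stack([np.ones_like(g), g]) * np.sqrt(w)[:, None]
        y = gam_u * np.sqrt(w)
        from scipy.optimize import nnls
        coef, _ = nnls(A, y)
        nuggets[u] = coef[0]
        B[u, u] = max(coef[1], 1e-12)
    # cross sills: single-coefficient WLS, no cross nugget
    for u in range(p1):
        for v in range(u + 1, p1):
            emp_uv = empirical_cross_variogram(points, all_vals[u], all_vals[v],
                                               bin_width=emp0.bin_width,
                                               max_lag=emp0.max_lag)
            gam_uv = emp_uv.gamma[valid]
            denom = np.sum(w * g * g)
            b = float(np.sum(w * g * gam_uv) / denom) if denom > 0 else 0.0
            bound = np.sqrt(B[u, u] * B[v, v])
            B[u, v] = B[v, u] = float(np.clip(b, -bound, bound))
    # project into the PSD cone (pairwise clipping is not sufficient for p > 2)
    eigval, eigvec = np.linalg.eigh(B)
    if eigval.min() < 0:
        B = (eigvec * np.maximum(eigval, 0.0)) @ eigvec.T
        B = (B + B.T) / 2
    return Coregionalization(names=names, structure=structure,
                             nuggets=nuggets, sills=B)
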