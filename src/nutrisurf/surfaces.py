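"""Smooth response surfaces of phenotypes over macronutrient-intake space.

Each outcome is fitted per treatment group as a generalized additive
model with a single three-dimensional thin-plate-spline smooth of
protein, carbohydrate and fat energy intake (kJ/day). A genuinely
multidimensional smooth matters here: effects such as an
ovulation-permissive carbohydrate-by-fat window are interactions that a
sum of univariate smooths cannot represent.

The smooth is the standard low-rank thin-plate construction: radial
basis functions phi(r) = -r / (8 pi) (the d=3, second-order Green's
function) centred on knots placed at the observed intake coordinates
(farthest-point subsampled when there are many), plus an unpenalized
linear polynomial; the side conditions are absorbed by projecting the
radial coefficients onto the null space of the polynomial constraints,
which turns the bending energy into an ordinary quadratic penalty.
Fitting is penalized IRLS for the chosen family; the smoothing
parameter minimizes generalized cross-validation, and the negative
binomial dispersion is estimated by outer profile likelihood.

Families: Gaussian-identity, Gaussian on the log outcome (latent scale
= log outcome), and negative binomial with log link for counts.
Predictions are made on the latent (linear predictor) scale with
pointwise standard errors from the penalized coefficient covariance,
then back-transformed for display. Surfaces are summarized as 2-D
slices with the third nutrient fixed at its median and cells outside
the convex hull of nearby observations masked out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.stats import shapiro

from .cohort import MouseRecord

__all__ = [
    "SurfaceFit",
    "SliceGrid",
    "fit_surface",
    "predict_slice",
    "ThinPlateBasis",
    "FitError",
    "AXES",
    "MIN_FIT_SIZE",
    "MAX_KNOTS",
]

#: Nutrient axis labels in canonical order (indices into intake coords).
AXES = ("P", "C", "F")

#: Minimum number of records for a surface fit.
MIN_FIT_SIZE = 30

#: Cap on thin-plate knots; beyond this the observed intake coordinates
#: are farthest-point subsampled (a deterministic, nested sequence).
MAX_KNOTS = 50

_FAMILIES = ("gaussian-identity", "gaussian-log", "negbin-log")


class FitError(RuntimeError):
    """Surface fitting failed (too few records or non-convergence)."""


# ---------------------------------------------------------------------------
# thin-plate basis


def farthest_point_order(points: np.ndarray) -> np.ndarray:
    """Deterministic farthest-point ordering of unique rows.

    Starts from the point nearest the centroid and greedily adds the
    point farthest from those already chosen, so any prefix is a
    space-filling knot set and knot sets of increasing size are nested.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    centroid = pts.mean(axis=0)
    start = int(np.argmin(np.sum((pts - centroid) ** 2, axis=1)))
    chosen = [start]
    dist = np.sqrt(np.sum((pts - pts[start]) ** 2, axis=1))
    for _ in range(n - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        d_new = np.sqrt(np.sum((pts - pts[nxt]) ** 2, axis=1))
        dist = np.minimum(dist, d_new)
    return np.asarray(chosen)


def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """phi(|a_i - b_j|) = -r / (8 pi), the 3-D second-order Green's fn."""
    diff = a[:, None, :] - b[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    return -r / (8.0 * math.pi)


class ThinPlateBasis:
    """Low-rank 3-D thin-plate-spline basis with absorbed constraints.

    Columns of the design matrix are [1, x1, x2, x3, (Phi Z)] where Phi
    holds the radial kernels at the knots and Z spans the null space of
    the polynomial side conditions; the penalty is Z' E Z on the radial
    block and zero on the polynomial block. Inputs are standardized
    axis-wise before the (scale-dependent) radial construction.
    """

    def __init__(self, xyz: np.ndarray, max_knots: int = MAX_KNOTS):
        xyz = np.asarray(xyz, dtype=float)
        self.center = xyz.mean(axis=0)
        scale = xyz.std(axis=0)
        self.scale = np.where(scale > 0, scale, 1.0)
        # axes with no variation carry no information; drop them from the
        # polynomial part so the unpenalized block stays full rank
        self.active = scale > 0
        z = self._standardize(xyz)
        uniq = np.unique(z, axis=0)
        order = farthest_point_order(uniq)
        self.knots = uniq[order[: min(max_knots, len(uniq))]]
        k = len(self.knots)
        n_poly = 1 + int(self.active.sum())
        if k < n_poly + 1:
            raise FitError(
                f"only {k} distinct intake points; need >= {n_poly + 1}"
            )

        E = _tps_kernel(self.knots, self.knots)
        T = np.column_stack([np.ones(k), self.knots[:, self.active]])
        # Z: orthonormal basis of the null space of T' (constraints T'delta=0)
        q, _ = np.linalg.qr(T, mode="complete")
        self.Z = q[:, n_poly:]                               # k x (k - n_poly)
        S_rad = self.Z.T @ E @ self.Z
        S_rad = (S_rad + S_rad.T) / 2.0
        # numerical floor: the projected bending energy is PSD in theory
        w, v = np.linalg.eigh(S_rad)
        S_rad = (v * np.maximum(w, 0.0)) @ v.T
        self.n_poly = n_poly
        p = n_poly + (k - n_poly)
        self.penalty = np.zeros((p, p))
        self.penalty[n_poly:, n_poly:] = S_rad
        self.n_param = p

    def _standardize(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - self.center) / self.scale

    def design(self, xyz: np.ndarray) -> np.ndarray:
        z = self._standardize(xyz)
        T = np.column_stack([np.ones(len(z)), z[:, self.active]])
        Phi = _tps_kernel(z, self.knots)
        return np.column_stack([T, Phi @ self.Z])

    def describe(self) -> str:
        return (
            f"3-D thin-plate spline, {len(self.knots)} knots "
            f"({self.n_param} coefficients incl. linear polynomial)"
        )


# ---------------------------------------------------------------------------
# penalized IRLS


def _pirls(y, X, S, family, lam, max_iter=100, tol=1e-9):
    """Penalized IRLS for one GLM family at fixed smoothing lam.

    Returns (beta, mu, eta, edf, XtWX, deviance, converged).
    """
    n = len(y)
    mu = family.starting_mu(y)
    eta = family.link(mu)
    dev = family.deviance(y, mu)
    beta = None
    converged = False
    for _ in range(max_iter):
        w = family.weights(mu)
        w = np.clip(w, 1e-12, 1e12)
        z = eta + (y - mu) * family.link.deriv(mu)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        A = XtWX + lam * S
        beta = np.linalg.solve(A, X.T @ (w * z))
        eta = X @ beta
        eta = np.clip(eta, -300, 300)
        mu = family.link.inverse(eta)
        dev_new = family.deviance(y, mu)
        if not np.isfinite(dev_new):
            break
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            dev = dev_new
            converged = True
            break
        dev = dev_new
    w = np.clip(family.weights(mu), 1e-12, 1e12)
    XtWX = X.T @ (X * w[:, None])
    A = XtWX + lam * S
    edf = float(np.trace(np.linalg.solve(A, XtWX)))
    return beta, mu, eta, edf, A, dev, converged


def _gcv(dev: float, n: int, edf: float) -> float:
    if n - edf < 1.0:
        return np.inf
    return n * dev / (n - edf) ** 2


def _select_lambda(y, X, S, family) -> float:
    """Smoothing selection: GCV for Gaussian fits (unknown scale),
    UBRE (deviance + 2 * edf, scale fixed at 1) for count families."""
    n = len(y)
    known_scale = not isinstance(family, sm.families.Gaussian)

    def crit(log10_lam):
        try:
            *_, edf, _, dev, _ = _pirls(y, X, S, family, 10.0 ** log10_lam)
        except np.linalg.LinAlgError:
            return np.inf
        if known_scale:
            return dev + 2.0 * edf
        return _gcv(dev, n, edf)

    opt = minimize_scalar(crit, bounds=(-5.0, 6.0), method="bounded",
                          options={"xatol": 0.15})
    return 10.0 ** float(opt.x)


def _null_deviance(y, family) -> float:
    # the intercept-only MLE mean is the sample mean for the canonical
    # and log links used here
    mu0 = np.full(len(y), max(float(np.mean(y)), 1e-9))
    return float(family.deviance(y, mu0))


# ---------------------------------------------------------------------------
# public fit surface


@dataclass
class SurfaceFit:
    """A fitted smooth response surface for one outcome and group."""

    outcome: str
    group: str
    family: str
    basis: str
    smoothing: float
    dispersion: float
    training_n: int
    support: np.ndarray            # training (P, C, F) intake coordinates
    params: np.ndarray = field(repr=False)
    cov_params: np.ndarray = field(repr=False)
    smoother: ThinPlateBasis = field(repr=False)
    deviance: float = 0.0
    null_deviance: float = 0.0
    edf: float = 0.0

    def predict_latent(self, xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Latent-scale mean and pointwise SE at (P, C, F) points."""
        X = self.smoother.design(np.asarray(xyz, dtype=float))
        eta = X @ self.params
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov_params, X), 0))
        return eta, se

    def inverse_link(self, eta: np.ndarray) -> np.ndarray:
        if self.family == "gaussian-identity":
            return np.asarray(eta)
        return np.exp(eta)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "outcome": self.outcome,
            "group": self.group,
            "family": self.family,
            "basis": self.basis,
            "smoothing": self.smoothing,
            "dispersion": self.dispersion,
            "training_n": self.training_n,
            "edf": self.edf,
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "coefficients": self.params.tolist(),
            "support_vertices": _hull_vertices(self.support).tolist(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc


def _hull_vertices(points: np.ndarray) -> np.ndarray:
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:
        return np.unique(points, axis=0)


def _extract(records: list[MouseRecord], outcome: str, group: str):
    xyz, y = [], []
    for r in records:
        if r.group != group:
            continue
        value = getattr(r, outcome)
        coords = (r.intake.p_kj, r.intake.c_kj, r.intake.f_kj)
        if np.isfinite(value) and all(np.isfinite(coords)):
            xyz.append(coords)
            y.append(float(value))
    return np.asarray(xyz, dtype=float), np.asarray(y, dtype=float)


def fit_surface(
    records: list[MouseRecord],
    outcome: str,
    group: str,
    family: str = "auto",
    min_fit_size: int = MIN_FIT_SIZE,
    max_knots: int = MAX_KNOTS,
) -> SurfaceFit:
    """Fit a penalized thin-plate surface of ``outcome`` over intake space.

    Parameters
    ----------
    records : list of MouseRecord
        The cohort; only rows of ``group`` with finite outcome and
        intakes are used. Intake coordinates are the cage averages
        carried by each mouse.
    outcome : str
        Name of a numeric MouseRecord field.
    group : str
        ``"control"`` or ``"PCOS"``.
    family : str
        ``"gaussian-identity"``, ``"gaussian-log"`` (Gaussian fit to the
        log outcome), ``"negbin-log"``, or ``"auto"``: Gaussian with a
        Shapiro-Wilk normality gate (alpha = 0.05) on the identity-link
        residuals that switches to the log transform.

    Raises
    ------
    FitError
        Fewer than ``min_fit_size`` usable records, or the penalized
        IRLS did not converge.
    ValueError
        Unknown family, or a non-integer outcome under ``negbin-log``.
    """
    xyz, y = _extract(records, outcome, group)
    if len(y) < min_fit_size:
        raise FitError(
            f"{outcome}/{group}: {len(y)} usable records < "
            f"minimum fit size {min_fit_size}"
        )

    if family == "auto":
        fit = fit_surface(records, outcome, group, "gaussian-identity",
                          min_fit_size=min_fit_size, max_knots=max_knots)
        eta, _ = fit.predict_latent(xyz)
        resid = y - eta
        if len(resid) >= 8 and np.ptp(resid) > 0 and shapiro(resid).pvalue < 0.05 \
                and np.all(y > 0):
            return fit_surface(records, outcome, group, "gaussian-log",
                               min_fit_size=min_fit_size, max_knots=max_knots)
        return fit

    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")

    y_work = y
    if family == "gaussian-log":
        if np.any(y <= 0):
            raise ValueError(
                f"{outcome}/{group}: gaussian-log requires positive outcomes"
            )
        y_work = np.log(y)
    if family == "negbin-log":
        if np.any(y < 0) or not np.allclose(y, np.rint(y)):
            raise ValueError(
                f"{outcome}/{group}: negbin-log requires non-negative "
                "integer counts"
            )

    basis = ThinPlateBasis(xyz, max_knots=max_knots)
    X = basis.design(xyz)
    S = basis.penalty
    n = len(y_work)

    if family.startswith("gaussian"):
        glm_family = sm.families.Gaussian()
        lam = _select_lambda(y_work, X, S, glm_family)
        beta, mu, eta, edf, A, dev, conv = _pirls(y_work, X, S, glm_family, lam)
        scale = dev / max(n - edf, 1.0)
        dispersion = float(scale)
    else:
        # moment start for the dispersion, then outer profile likelihood
        m, v = float(np.mean(y)), float(np.var(y))
        a0 = min(max((v - m) / max(m, 1e-6) ** 2, 1e-3), 10.0)
        lam = _select_lambda(y_work, X, S, sm.families.NegativeBinomial(alpha=a0))

        def neg_llf(log10_a):
            fam = sm.families.NegativeBinomial(alpha=10.0 ** log10_a)
            try:
                _, mu_a, *_ = _pirls(y_work, X, S, fam, lam)
            except np.linalg.LinAlgError:
                return np.inf
            ll = fam.loglike(y_work, mu_a)
            return -ll if np.isfinite(ll) else np.inf

        opt = minimize_scalar(neg_llf, bounds=(-3.0, 1.5), method="bounded",
                              options={"xatol": 0.05})
        nb_alpha = 10.0 ** float(opt.x)
        glm_family = sm.families.NegativeBinomial(alpha=nb_alpha)
        lam = _select_lambda(y_work, X, S, glm_family)
        beta, mu, eta, edf, A, dev, conv = _pirls(y_work, X, S, glm_family, lam)
        scale = 1.0
        dispersion = nb_alpha

    if not conv:
        raise FitError(
            f"{outcome}/{group}: penalized IRLS did not converge "
            f"(n={n}, family={family}, deviance={dev:.4g}, lambda={lam:.3g})"
        )
    if not np.all(np.isfinite(eta)):
        raise FitError(f"{outcome}/{group}: non-finite in-sample predictions")

    cov = scale * np.linalg.inv(A)

    return SurfaceFit(
        outcome=outcome,
        group=group,
        family=family,
        basis=basis.describe(),
        smoothing=float(lam),
        dispersion=dispersion,
        training_n=n,
        support=xyz,
        params=np.asarray(beta),
        cov_params=(cov + cov.T) / 2.0,
        smoother=basis,
        deviance=float(dev),
        null_deviance=_null_deviance(y_work, glm_family),
        edf=edf,
    )


# ---------------------------------------------------------------------------
# slices


@dataclass
class SliceGrid:
    """A 2-D cut through the 3-D surface at the median of the third axis."""

    free_axes: tuple[str, str]
    fixed_axis: str
    fixed_value: float
    axis1: np.ndarray              # grid values along free_axes[0]
    axis2: np.ndarray              # grid values along free_axes[1]
    latent_mean: np.ndarray        # shape (len(axis2), len(axis1))
    latent_se: np.ndarray
    raw_mean: np.ndarray
    mask: np.ndarray               # True where inside support

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.axis1, self.axis2)
        return pd.DataFrame(
            {
                self.free_axes[0]: a1.ravel(),
                self.free_axes[1]: a2.ravel(),
                "latent_mean": self.latent_mean.ravel(),
                "latent_se": self.latent_se.ravel(),
                "raw_mean": self.raw_mean.ravel(),
                "mask": self.mask.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


#: Half-width of the fixed-axis band used to collect the points whose
#: convex hull defines the in-support region of a slice, as a fraction
#: of the fixed axis's IQR.
SLICE_BAND_IQR_FRAC = 0.25


def _band_points(fit: SurfaceFit, fixed_idx: int, fixed_value: float) -> np.ndarray:
    free_cols = [i for i in range(3) if i != fixed_idx]
    col = fit.support[:, fixed_idx]
    iqr = float(np.subtract(*np.percentile(col, [75, 25])))
    half = SLICE_BAND_IQR_FRAC * iqr
    for widen in (1.0, 2.0, 4.0, np.inf):
        if np.isinf(widen):
            sel = np.ones(len(col), dtype=bool)
        else:
            sel = np.abs(col - fixed_value) <= max(half * widen, 1e-9)
        pts = fit.support[sel][:, free_cols]
        if len(np.unique(pts, axis=0)) >= 3:
            return pts
    return fit.support[:, free_cols]


def _inside_hull(points: np.ndarray, grid_xy: np.ndarray) -> np.ndarray:
    try:
        tri = Delaunay(points)
        return tri.find_simplex(grid_xy) >= 0
    except QhullError:
        # degenerate (collinear) support: fall back to the bounding box
        lo, hi = points.min(axis=0), points.max(axis=0)
        return np.all((grid_xy >= lo) & (grid_xy <= hi), axis=1)


def predict_slice(
    fit: SurfaceFit,
    free_axes: tuple[str, str] = ("C", "F"),
    resolution: int = 51,
    fixed_value: float | None = None,
    axis1: np.ndarray | None = None,
    axis2: np.ndarray | None = None,
) -> SliceGrid:
    """Predict a 2-D slice with the third nutrient fixed at its median.

    ``fixed_value``/``axis1``/``axis2`` can be supplied to evaluate on a
    caller-defined geometry (used when subtracting two surfaces, which
    must share a grid); by default the fixed axis sits at the median of
    the training intakes and the free axes span their observed ranges.
    Cells outside the convex hull of observations near the cut are
    masked and carry no predictions (NaN).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    a, b = free_axes
    if a == b or a not in AXES or b not in AXES:
        raise ValueError(f"free_axes must be two distinct of {AXES}")
    fixed_axis = next(ax for ax in AXES if ax not in free_axes)
    i1, i2, i_fix = AXES.index(a), AXES.index(b), AXES.index(fixed_axis)

    if fixed_value is None:
        fixed_value = float(np.median(fit.support[:, i_fix]))
    if axis1 is None:
        lo, hi = fit.support[:, i1].min(), fit.support[:, i1].max()
        axis1 = np.linspace(lo, hi, resolution)
    if axis2 is None:
        lo, hi = fit.support[:, i2].min(), fit.support[:, i2].max()
        axis2 = np.linspace(lo, hi, resolution)
    axis1 = np.asarray(axis1, dtype=float)
    axis2 = np.asarray(axis2, dtype=float)

    g1, g2 = np.meshgrid(axis1, axis2)
    xyz = np.zeros((g1.size, 3))
    xyz[:, i1] = g1.ravel()
    xyz[:, i2] = g2.ravel()
    xyz[:, i_fix] = fixed_value

    band = _band_points(fit, i_fix, fixed_value)
    free_cols = sorted([i1, i2])
    grid_free = xyz[:, free_cols]
    mask = _inside_hull(band, grid_free).reshape(g1.shape)

    eta, se = fit.predict_latent(xyz)
    latent = eta.reshape(g1.shape).copy()
    latent_se = se.reshape(g1.shape).copy()
    latent[~mask] = np.nan
    latent_se[~mask] = np.nan
    raw = fit.inverse_link(latent)

    return SliceGrid(
        free_axes=(a, b),
        fixed_axis=fixed_axis,
        fixed_value=float(fixed_value),
        axis1=axis1,
        axis2=axis2,
        latent_mean=latent,
        latent_se=latent_se,
        raw_mean=raw,
        mask=mask,
    )
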