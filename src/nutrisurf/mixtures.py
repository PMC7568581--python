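"""Scheffe canonical polynomial models on the diet-composition simplex.

Food and energy intake respond to the composition of the diet (the
proportions of energy from protein, carbohydrate and fat, which sum to
one), not to intake coordinates; the canonical mixture polynomials of
Scheffe model such responses without an intercept:

    linear        y = b1 x1 + b2 x2 + b3 x3
    quadratic     ... + b12 x1 x2 + b13 x1 x3 + b23 x2 x3
    special-cubic ... + b123 x1 x2 x3

The degree is chosen by the small-sample-corrected Akaike criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MixtureFit",
    "fit_scheffe",
    "predict_mixture",
    "select_degree",
    "scheffe_design",
    "DEGREES",
]

DEGREES = ("linear", "quadratic", "special-cubic")
_N_COEF = {"linear": 3, "quadratic": 6, "special-cubic": 7}
_COEF_NAMES = {
    "linear": ["b_p", "b_c", "b_f"],
    "quadratic": ["b_p", "b_c", "b_f", "b_pc", "b_pf", "b_cf"],
    "special-cubic": ["b_p", "b_c", "b_f", "b_pc", "b_pf", "b_cf", "b_pcf"],
}

SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class MixtureFit:
    """Least-squares Scheffe polynomial fit of one response."""

    degree: str
    coefficients: np.ndarray
    response: str
    n: int
    information_criterion: float

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "degree": self.degree,
            "coefficients": dict(
                zip(_COEF_NAMES[self.degree], self.coefficients.tolist())
            ),
            "response": self.response,
            "n": self.n,
            "information_criterion": self.information_criterion,
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2))
        return doc


def _check_simplex(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[None, :]
    if points.shape[1] != 3:
        raise ValueError("composition points must have 3 components")
    sums = points.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > SIMPLEX_TOL) or np.any(points < -SIMPLEX_TOL):
        raise ValueError("points must lie on the unit simplex")
    return points


def scheffe_design(points: np.ndarray, degree: str) -> np.ndarray:
    """Design matrix of the canonical polynomial at composition points."""
    if degree not in DEGREES:
        raise ValueError(f"unknown degree {degree!r}; expected one of {DEGREES}")
    x = _check_simplex(points)
    cols = [x[:, 0], x[:, 1], x[:, 2]]
    if degree in ("quadratic", "special-cubic"):
        cols += [x[:, 0] * x[:, 1], x[:, 0] * x[:, 2], x[:, 1] * x[:, 2]]
    if degree == "special-cubic":
        cols.append(x[:, 0] * x[:, 1] * x[:, 2])
    return np.column_stack(cols)


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian AIC with small-sample correction; +1 for the error variance
    rss = max(rss, 1e-300)
    aic = n * np.log(rss / n) + 2 * (k + 1)
    denom = n - k - 2
    if denom <= 0:
        return np.inf
    return aic + 2 * (k + 1) * (k + 2) / denom


def fit_scheffe(points, y, degree: str = "linear") -> MixtureFit:
    """Fit a Scheffe polynomial by ordinary least squares.

    Raises a ``ValueError`` naming the deficiency if the design matrix
    is rank deficient (fewer distinct compositions than coefficients).
    """
    y = np.asarray(y, dtype=float)
    X = scheffe_design(points, degree)
    if len(y) != len(X):
        raise ValueError("points and y must have the same length")
    k = _N_COEF[degree]
    if len(y) < k:
        raise ValueError(
            f"{degree} Scheffe model needs >= {k} points, got {len(y)}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError(
            f"rank-deficient mixture design: rank {rank} < {k} coefficients "
            f"for degree {degree!r} (too few distinct compositions)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return MixtureFit(
        degree=degree,
        coefficients=beta,
        response="",
        n=len(y),
        information_criterion=_aicc(rss, len(y), k),
    )


def select_degree(points, y, response: str = "") -> MixtureFit:
    """Fit all admissible degrees and keep the lowest-AICc model."""
    best = None
    for degree in DEGREES:
        try:
            fit = fit_scheffe(points, y, degree)
        except ValueError:
            continue
        if best is None or fit.information_criterion < best.information_criterion:
            best = fit
    if best is None:
        raise ValueError("no Scheffe degree is estimable on these points")
    return MixtureFit(
        degree=best.degree,
        coefficients=best.coefficients,
        response=response,
        n=best.n,
        information_criterion=best.information_criterion,
    )


def predict_mixture(fit: MixtureFit, point) -> float | np.ndarray:
    """Evaluate the fitted polynomial at composition points on the simplex."""
    X = scheffe_design(point, fit.degree)
    out = X @ fit.coefficients
    return float(out[0]) if out.shape == (1,) else out


def ternary_surface_frame(fit: MixtureFit, resolution: int = 40) -> pd.DataFrame:
    """Long-format fitted surface over a triangular lattice of the simplex."""
    rows = []
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            xp = i / resolution
            xc = j / resolution
            xf = 1.0 - xp - xc
            rows.append((xp, xc, xf))
    pts = np.asarray(rows)
    fitted = predict_mixture(fit, pts)
    return pd.DataFrame(
        {"x_p": pts[:, 0], "x_c": pts[:, 1], "x_f": pts[:, 2], "fitted": fitted}
    )
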