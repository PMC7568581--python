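"""Surface subtraction with pointwise confidence limits.

Two fitted surfaces of the same outcome (control and PCOS) are compared
cell by cell on a shared slice grid. On the latent (linear-predictor)
scale the difference is d = y1 - y2 with pooled standard error
SE_d = sqrt(SE1^2 + SE2^2); the confidence limit d +/- q * SE_d uses the
two-sided standard normal quantile q (1.96, 2.58 and 3.29 at 95, 99 and
99.9%), and a cell is significant where that interval excludes zero.
Back-transformation to the raw scale happens only after the interval
logic, for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .surfaces import AXES, SliceGrid, SurfaceFit, predict_slice

__all__ = ["DifferenceSurface", "q_constant", "subtract_surfaces"]

#: Confidence levels at which q is reported with the conventional
#: two-decimal presentation rounding.
_PRESENTATION_Q = {0.95: 1.96, 0.99: 2.58, 0.999: 3.29}


def q_constant(level: float) -> float:
    """Width constant of the pointwise confidence limit.

    The two-sided standard normal quantile for the given confidence
    level; at 95, 99 and 99.9% the conventional two-decimal roundings
    (1.96, 2.58, 3.29) are returned.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    for lv, q in _PRESENTATION_Q.items():
        if abs(level - lv) < 1e-12:
            return q
    return float(norm.ppf(0.5 + level / 2.0))


@dataclass
class DifferenceSurface:
    """Cellwise difference of two surfaces with confidence limits."""

    grid: SliceGrid                # shared geometry (axes, fixed value, mask)
    d: np.ndarray                  # latent-scale difference y1 - y2
    se_d: np.ndarray
    q: float
    level: float
    cfl_lo: np.ndarray
    cfl_hi: np.ndarray
    significant: np.ndarray
    raw_d: np.ndarray              # difference of back-transformed means

    def to_frame(self) -> pd.DataFrame:
        a1, a2 = np.meshgrid(self.grid.axis1, self.grid.axis2)
        return pd.DataFrame(
            {
                self.grid.free_axes[0]: a1.ravel(),
                self.grid.free_axes[1]: a2.ravel(),
                "d": self.d.ravel(),
                "se_d": self.se_d.ravel(),
                "cfl_lo": self.cfl_lo.ravel(),
                "cfl_hi": self.cfl_hi.ravel(),
                "significant": self.significant.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def subtract_surfaces(
    fit1: SurfaceFit,
    fit2: SurfaceFit,
    free_axes: tuple[str, str] = ("C", "F"),
    level: float = 0.95,
    resolution: int = 51,
) -> DifferenceSurface:
    """Subtract ``fit2`` from ``fit1`` on a shared slice grid.

    Both fits must model the same outcome with the same family/link.
    The grid spans the union of the two training ranges on the free
    axes, with the third nutrient fixed at the median of the pooled
    training intakes; cells outside either fit's support are dropped
    (intersection of the masks), never extrapolated.
    """
    if fit1.outcome != fit2.outcome:
        raise ValueError(
            f"cannot subtract different outcomes: "
            f"{fit1.outcome!r} vs {fit2.outcome!r}"
        )
    if fit1.family != fit2.family:
        raise ValueError(
            f"cannot subtract surfaces with mismatched links: "
            f"{fit1.family!r} vs {fit2.family!r}"
        )
    a, b = free_axes
    fixed_axis = next(ax for ax in AXES if ax not in free_axes)
    i1, i2, i_fix = AXES.index(a), AXES.index(b), AXES.index(fixed_axis)

    pooled = np.vstack([fit1.support, fit2.support])
    fixed_value = float(np.median(pooled[:, i_fix]))
    axis1 = np.linspace(pooled[:, i1].min(), pooled[:, i1].max(), resolution)
    axis2 = np.linspace(pooled[:, i2].min(), pooled[:, i2].max(), resolution)

    s1 = predict_slice(fit1, free_axes, resolution, fixed_value, axis1, axis2)
    s2 = predict_slice(fit2, free_axes, resolution, fixed_value, axis1, axis2)

    mask = s1.mask & s2.mask
    if not mask.any():
        raise ValueError(
            "supports of the two surfaces do not overlap on this slice"
        )

    nan = np.full(mask.shape, np.nan)
    d = np.where(mask, s1.latent_mean - s2.latent_mean, nan)
    se_d = np.where(mask, np.hypot(s1.latent_se, s2.latent_se), nan)
    q = q_constant(level)
    cfl_lo = d - q * se_d
    cfl_hi = d + q * se_d
    significant = np.zeros(mask.shape, dtype=bool)
    significant[mask] = (cfl_lo[mask] > 0) | (cfl_hi[mask] < 0)
    raw_d = np.where(mask, s1.raw_mean - s2.raw_mean, nan)

    grid = SliceGrid(
        free_axes=(a, b),
        fixed_axis=fixed_axis,
        fixed_value=fixed_value,
        axis1=axis1,
        axis2=axis2,
        latent_mean=d,
        latent_se=se_d,
        raw_mean=raw_d,
        mask=mask,
    )
    return DifferenceSurface(
        grid=grid, d=d, se_d=se_d, q=q, level=level,
        cfl_lo=cfl_lo, cfl_hi=cfl_hi, significant=significant, raw_d=raw_d,
    )
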