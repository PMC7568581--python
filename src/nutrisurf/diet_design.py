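"""Experimental diet mixture design and intake accounting.

Diets are described by the percentage of metabolizable energy contributed
by protein (P), carbohydrate (C) and fat (F), plus an energy density in
kJ per gram of food. Measured food intake (g/day, a cage average) is
converted to macronutrient energy intakes (kJ/day), the coordinates of
all response surfaces downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "DietSpec",
    "IntakeRecord",
    "load_diet_table",
    "macronutrient_intake",
    "to_simplex",
    "default_design",
    "DIET_TABLE_COLUMNS",
]

#: Required header of a diet-design CSV.
DIET_TABLE_COLUMNS = ("diet_id", "p_pct", "c_pct", "f_pct", "energy_density")

#: Tolerance (percentage points) on P+C+F energy sums, absorbing the
#: rounding typical of published diet sheets.
COMPOSITION_SUM_TOL = 0.5


class DietValidationError(ValueError):
    """A diet row violates the mixture-composition invariants."""


class DietSchemaError(ValueError):
    """A diet table is missing required columns."""


@dataclass(frozen=True)
class DietSpec:
    """One experimental diet: energy fractions and energy density.

    Parameters
    ----------
    diet_id : str
        Label of the diet (e.g. ``"d04"``).
    p_pct, c_pct, f_pct : float
        Percent of metabolizable energy from protein, carbohydrate and
        fat. Must be non-negative and sum to 100 within 0.5.
    energy_density : float
        kJ of metabolizable energy per gram of food; must be positive.
    """

    diet_id: str
    p_pct: float
    c_pct: float
    f_pct: float
    energy_density: float

    def __post_init__(self) -> None:
        for name in ("p_pct", "c_pct", "f_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DietValidationError(
                    f"diet {self.diet_id!r}: {name}={v} outside [0, 100]"
                )
        total = self.p_pct + self.c_pct + self.f_pct
        if abs(total - 100.0) > COMPOSITION_SUM_TOL:
            raise DietValidationError(
                f"diet {self.diet_id!r}: energy fractions sum to {total}, "
                f"expected 100 +/- {COMPOSITION_SUM_TOL}"
            )
        if not self.energy_density > 0:
            raise DietValidationError(
                f"diet {self.diet_id!r}: energy_density must be > 0, "
                f"got {self.energy_density}"
            )


@dataclass(frozen=True)
class IntakeRecord:
    """Daily macronutrient energy intakes of one cage/mouse (kJ/day)."""

    p_kj: float
    c_kj: float
    f_kj: float
    total_kj: float
    food_g: float

    def __post_init__(self) -> None:
        for name in ("p_kj", "c_kj", "f_kj", "total_kj", "food_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        parts = self.p_kj + self.c_kj + self.f_kj
        scale = max(abs(self.total_kj), 1.0)
        if abs(parts - self.total_kj) > 1e-6 * scale:
            raise ValueError(
                f"total_kj={self.total_kj} does not equal the sum of "
                f"macronutrient parts ({parts})"
            )


def load_diet_table(path: str | Path) -> list[DietSpec]:
    """Read a diet-design CSV into validated :class:`DietSpec` objects.

    The file must carry the header
    ``diet_id,p_pct,c_pct,f_pct,energy_density`` (UTF-8, decimal point).

    Raises
    ------
    DietSchemaError
        If a required column is missing.
    DietValidationError
        If any row violates the composition invariants; the message
        names the offending diet.
    """
    df = pd.read_csv(path)
    missing = [c for c in DIET_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise DietSchemaError(f"diet table {path} missing columns: {missing}")
    return [
        DietSpec(
            diet_id=str(row.diet_id),
            p_pct=float(row.p_pct),
            c_pct=float(row.c_pct),
            f_pct=float(row.f_pct),
            energy_density=float(row.energy_density),
        )
        for row in df.itertuples(index=False)
    ]


def macronutrient_intake(food_g: float, diet: DietSpec) -> IntakeRecord:
    """Convert food intake (g/day) to macronutrient energy intakes.

    Each macronutrient's kJ/day is food intake x energy density x its
    energy fraction; total energy is the sum of the three parts.
    """
    if food_g < 0:
        raise ValueError(f"food_g must be >= 0, got {food_g}")
    kj_per_g = diet.energy_density
    p = food_g * kj_per_g * diet.p_pct / 100.0
    c = food_g * kj_per_g * diet.c_pct / 100.0
    f = food_g * kj_per_g * diet.f_pct / 100.0
    return IntakeRecord(p_kj=p, c_kj=c, f_kj=f, total_kj=p + c + f, food_g=food_g)


def to_simplex(diet: DietSpec) -> tuple[float, float, float]:
    """Return the diet's composition as proportions summing to exactly 1.

    The renormalization removes the <=0.5-point rounding slack allowed in
    the percent representation, so mixture (Scheffe) models can assume an
    exact simplex.
    """
    total = diet.p_pct + diet.c_pct + diet.f_pct
    return (diet.p_pct / total, diet.c_pct / total, diet.f_pct / total)


#: Default synthetic 10-diet design: protein spans 5-60 % of energy with
#: the carbohydrate:fat ratio varied across protein levels, all at an
#: energy density of 16 kJ/g. It stands in for the (unpublished) study
#: design table and is deliberately dense around low-protein compositions,
#: where the ovulation-permissive intake window sits.
_DEFAULT_DESIGN = (
    ("d01", 5.0, 75.0, 20.0),
    ("d02", 5.0, 20.0, 75.0),
    ("d03", 8.0, 60.0, 32.0),
    ("d04", 12.0, 50.0, 38.0),
    ("d05", 15.0, 30.0, 55.0),
    ("d06", 20.0, 45.0, 35.0),
    ("d07", 25.0, 60.0, 15.0),
    ("d08", 30.0, 25.0, 45.0),
    ("d09", 45.0, 30.0, 25.0),
    ("d10", 60.0, 20.0, 20.0),
)


def default_design(energy_density: float = 16.0) -> list[DietSpec]:
    """The default synthetic 10-diet mixture design."""
    return [
        DietSpec(diet_id=d, p_pct=p, c_pct=c, f_pct=f, energy_density=energy_density)
        for d, p, c, f in _DEFAULT_DESIGN
    ]
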