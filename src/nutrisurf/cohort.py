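"""Synthetic control-vs-PCOS mouse cohort generator.

Emulates a 10-diet geometric-framework feeding study in hyperandrogenized
(DHT-induced PCOS) and control female mice. Each diet cohort is housed in
cages; food intake is a cage average, so every mouse in a cage shares the
same intake coordinates, matching the analysis unit used downstream.

The generator's mean structure encodes the qualitative biology the
analysis must recover:

* food intake follows a protein-leverage rule (declines with dietary
  protein), identically in both groups;
* corpora lutea counts are negative-binomial with a high control mean at
  all intakes, while the PCOS mean is near zero except on a smooth
  plateau over carbohydrate intake 20-30 kJ/day and fat 15-25 kJ/day
  (the ovulation-permissive window);
* body weight rises with energy intake in both groups with a PCOS excess
  that is largest at low carbohydrate and fat intakes;
* adiponectin rises with carbohydrate intake in controls only;
  cholesterol rises with fat intake in PCOS only; fasting glucose is
  elevated and diet-insensitive in PCOS;
* estrous-stage sequences come from a four-state Markov chain, cycling
  for controls and for PCOS mice inside the window, absorbed in
  diestrus otherwise.

Default calibration targets are the study-scale group summaries
(control CL 4.5 vs PCOS 0.5; body weight 21.7 vs 23.5 g; adiponectin
16806 vs 11221 ng/ml; cholesterol 53.1 vs 61.5 mg/dL; fasting glucose
8.8 vs 9.2 mmol/L).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diet_design import DietSpec, IntakeRecord, macronutrient_intake, to_simplex

__all__ = [
    "GeneratorConfig",
    "MouseRecord",
    "generate_cohort",
    "generate_choice_cohort",
    "cohort_to_frame",
    "frame_to_records",
    "write_cohort_csv",
    "read_cohort_csv",
    "outcome_means",
    "ovulation_window",
    "study_cohort_plan",
    "GTT_MINUTES",
    "ESTROUS_STAGES",
    "CHOICE_DIETS",
]

GTT_MINUTES = (0, 15, 30, 60, 90)
ESTROUS_STAGES = "PEMD"

#: The three ad-libitum choice diets offered in the diet-preference arm:
#: high protein (60% P), high carbohydrate (75% C) and high fat (75% F).
CHOICE_DIETS = (
    DietSpec("choice_hiP", 60.0, 20.0, 20.0, 16.0),
    DietSpec("choice_hiC", 5.0, 75.0, 20.0, 16.0),
    DietSpec("choice_hiF", 5.0, 20.0, 75.0, 16.0),
)

# Cycling kernel: ordered traversal P -> E -> M -> D -> P with realistic
# per-stage persistence (mean cycle length ~5 days, so an 11-day smear
# series usually contains at least one completed cycle).
_CYCLING_KERNEL = np.array(
    [
        [0.25, 0.75, 0.00, 0.00],  # P
        [0.00, 0.35, 0.65, 0.00],  # E
        [0.00, 0.00, 0.30, 0.70],  # M
        [0.60, 0.00, 0.00, 0.40],  # D
    ]
)

# Acyclic kernel: every stage decays into diestrus, which is absorbing,
# so a P -> E transition never occurs and no cycle can complete.
_ACYCLIC_KERNEL = np.array(
    [
        [0.20, 0.00, 0.00, 0.80],
        [0.00, 0.20, 0.00, 0.80],
        [0.00, 0.00, 0.20, 0.80],
        [0.00, 0.00, 0.00, 1.00],
    ]
)


class ConfigValidationError(ValueError):
    """Generator configuration violates an invariant."""


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort: design, effects, noise.

    Noise scales are standard deviations on the outcome's own scale;
    ``noise_scale`` multiplies all of them at once (set it to 0 for the
    deterministic limit in which continuous outcomes equal their mean
    functions). ``cl_size`` is the negative-binomial size (dispersion)
    parameter of the corpora-lutea counts; ``None`` selects the
    no-dispersion limit in which counts are the rounded mean.
    """

    # design
    n_per_diet: int = 10
    cage_size: int = 3
    seed: int = 0
    diet3_attrition: bool = False

    # protein-leverage intake rule: food_g = a - b*ln(x_p) + cage noise
    intake_a: float = 2.2
    intake_b: float = 0.35
    cage_sd: float = 0.12

    # ovulation-permissive intake window (kJ/day) with logistic edges
    c_window: tuple[float, float] = (20.0, 30.0)
    f_window: tuple[float, float] = (15.0, 25.0)
    window_scale: float = 1.5

    # corpora lutea (negative binomial, log-mean structure)
    cl_control_mean: float = 4.5
    cl_pcos_floor: float = 0.05
    cl_pcos_amp: float = 4.5
    cl_size: float | None = 3.0

    # body weight and composition
    bw_base: float = 17.3
    bw_slope: float = 0.10        # g per kJ/day of total energy intake
    bw_pcos_base: float = 0.8
    bw_pcos_amp: float = 2.0      # extra PCOS weight at low C and F
    bw_pcos_scale: float = 3.0    # kJ/day softness of the low-intake edge
    bw_sd: float = 1.0
    fat_frac: float = 0.18
    fat_pcos: float = 0.5
    fat_sd: float = 0.35
    lean_frac: float = 0.72
    lean_sd: float = 0.5

    # serum outcomes
    adipo_base: float = 13400.0
    adipo_c_slope: float = 180.0  # ng/ml per kJ/day C, controls only
    adipo_pcos: float = 11221.0
    adipo_sd: float = 2500.0
    chol_control: float = 53.1
    chol_pcos_base: float = 44.9
    chol_f_slope: float = 1.0     # mg/dL per kJ/day F, PCOS only
    chol_sd: float = 8.0
    trig_base: float = 58.0
    trig_p_slope: float = -0.5
    trig_sd: float = 8.0
    glu_control_base: float = 9.3
    glu_control_f_slope: float = -0.03
    glu_pcos: float = 9.2
    glu_sd: float = 0.55

    # glucose tolerance excursion above fasting baseline at GTT_MINUTES
    gtt_deltas: tuple[float, ...] = (0.0, 6.0, 4.8, 2.2, 0.8)
    gtt_sd: float = 0.4

    # adipose histology
    adipocyte_control: float = 1573.0
    adipocyte_pcos_base: float = 1630.0
    adipocyte_pcos_amp: float = 160.0
    adipocyte_sd: float = 230.0

    # steroids and gonadotropins (lognormal around group medians)
    dht_control: float = 0.27
    dht_pcos: float = 1.34
    dht_sdlog: float = 0.5
    dht_lod: float = 0.05
    tst_control: float = 0.07
    tst_pcos: float = 0.05
    tst_sdlog: float = 0.4
    tst_lod: float = 0.01
    lh_median: float = 0.4
    fsh_median: float = 2.0
    hormone_sdlog: float = 0.4
    below_lod_prob: float = 0.05

    # estrous smear series
    estrous_days: int = 11

    # diet-preference arm
    choice_n_control: int = 17
    choice_n_pcos: int = 16
    choice_total_kj: float = 45.0
    choice_total_sd: float = 4.0
    choice_alpha: tuple[float, float, float] = (2.0, 3.5, 4.5)

    # global noise multiplier
    noise_scale: float = 1.0

    def validate(self) -> None:
        if self.n_per_diet < 1:
            raise ConfigValidationError("n_per_diet must be >= 1")
        if self.cage_size < 1:
            raise ConfigValidationError("cage_size must be >= 1")
        if not self.c_window[0] < self.c_window[1]:
            raise ConfigValidationError("c_window bounds must be ordered")
        if not self.f_window[0] < self.f_window[1]:
            raise ConfigValidationError("f_window bounds must be ordered")
        if not 0.0 <= self.below_lod_prob <= 1.0:
            raise ConfigValidationError("below_lod_prob must lie in [0, 1]")
        for name in (
            "cage_sd", "bw_sd", "fat_sd", "lean_sd", "adipo_sd", "chol_sd",
            "trig_sd", "glu_sd", "gtt_sd", "adipocyte_sd", "dht_sdlog",
            "tst_sdlog", "hormone_sdlog", "choice_total_sd", "noise_scale",
        ):
            if getattr(self, name) < 0:
                raise ConfigValidationError(f"{name} must be >= 0")
        if self.cl_size is not None and not self.cl_size > 0:
            raise ConfigValidationError("cl_size must be > 0 or None")
        if self.estrous_days < 2:
            raise ConfigValidationError("estrous_days must be >= 2")
        if len(self.gtt_deltas) != len(GTT_MINUTES):
            raise ConfigValidationError("gtt_deltas must match GTT_MINUTES")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        # YAML round-trips tuples as lists; normalise on load instead
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ConfigValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("c_window", "f_window", "gtt_deltas", "choice_alpha"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def replace(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


@dataclass
class MouseRecord:
    """One animal with its cage-level intake and all phenotype outcomes.

    Hormone fields carry a companion ``*_nd`` flag marking below-LOD
    (nondetect) samples; the value is NaN when the flag is set.
    """

    mouse_id: str
    group: str
    diet_id: str
    cage_id: str
    food_g: float
    intake: IntakeRecord
    cl_count: int
    body_weight: float
    fat_mass: float
    lean_mass: float
    adiponectin: float
    cholesterol: float
    triglycerides: float
    fasting_glucose: float
    gtt: tuple[float, ...]
    estrous_seq: str
    adipocyte_area: float
    dht: float
    dht_nd: bool
    testosterone: float
    testosterone_nd: bool
    lh: float
    lh_nd: bool
    fsh: float
    fsh_nd: bool


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def ovulation_window(c_kj, f_kj, config: GeneratorConfig):
    """Smooth plateau over the ovulation-permissive intake window.

    Product of four logistic edges at the carbohydrate and fat window
    bounds; close to 1 well inside the window and to 0 well outside.
    A smooth (rather than boxcar) plateau keeps the generator's mean
    functions differentiable, which the spline surfaces can represent.
    """
    s = config.window_scale
    c_lo, c_hi = config.c_window
    f_lo, f_hi = config.f_window
    return (
        _logistic((np.asarray(c_kj) - c_lo) / s)
        * _logistic((c_hi - np.asarray(c_kj)) / s)
        * _logistic((np.asarray(f_kj) - f_lo) / s)
        * _logistic((f_hi - np.asarray(f_kj)) / s)
    )


def _pcos_lowcf_sensitivity(c_kj, f_kj, config: GeneratorConfig):
    """Soft indicator of jointly low carbohydrate and fat intake."""
    s = config.bw_pcos_scale
    return _logistic((25.0 - np.asarray(c_kj)) / s) * _logistic(
        (25.0 - np.asarray(f_kj)) / s
    )


def outcome_means(
    p_kj, c_kj, f_kj, group: str, config: GeneratorConfig
) -> dict[str, float | np.ndarray]:
    """Closed-form mean functions of every continuous outcome plus the
    corpora-lutea mean, given intake coordinates and treatment group.

    This is the generator's ground truth; tests and surface-recovery
    checks compare fitted surfaces against it.
    """
    p = np.asarray(p_kj, dtype=float)
    c = np.asarray(c_kj, dtype=float)
    f = np.asarray(f_kj, dtype=float)
    total = p + c + f
    pcos = group == "PCOS"

    if pcos:
        cl_mean = config.cl_pcos_floor + config.cl_pcos_amp * ovulation_window(
            c, f, config
        )
    else:
        cl_mean = np.full_like(c, config.cl_control_mean)

    bw = config.bw_base + config.bw_slope * total
    if pcos:
        bw = bw + config.bw_pcos_base + config.bw_pcos_amp * _pcos_lowcf_sensitivity(
            c, f, config
        )

    adipo = (
        np.full_like(c, config.adipo_pcos)
        if pcos
        else config.adipo_base + config.adipo_c_slope * c
    )
    chol = (
        config.chol_pcos_base + config.chol_f_slope * f
        if pcos
        else np.full_like(f, config.chol_control)
    )
    trig = config.trig_base + config.trig_p_slope * p
    glu = (
        np.full_like(f, config.glu_pcos)
        if pcos
        else config.glu_control_base + config.glu_control_f_slope * f
    )
    adipocyte = (
        config.adipocyte_pcos_base
        + config.adipocyte_pcos_amp * _pcos_lowcf_sensitivity(c, f, config)
        if pcos
        else np.full_like(c, config.adipocyte_control)
    )
    return {
        "cl_count": cl_mean,
        "body_weight": bw,
        "fat_mass": config.fat_frac * bw + (config.fat_pcos if pcos else 0.0),
        "lean_mass": config.lean_frac * bw,
        "adiponectin": adipo,
        "cholesterol": chol,
        "triglycerides": trig,
        "fasting_glucose": glu,
        "adipocyte_area": adipocyte,
    }


def _sample_counts(rng, mean, config: GeneratorConfig):
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if config.cl_size is None:
        return np.rint(mean).astype(int)
    k = config.cl_size
    return np.asarray(rng.negative_binomial(k, k / (k + mean)))


def _markov_sequence(rng, kernel: np.ndarray, days: int, start: int) -> str:
    states = [start]
    for _ in range(days - 1):
        states.append(rng.choice(4, p=kernel[states[-1]]))
    return "".join(ESTROUS_STAGES[s] for s in states)


def _lognormal(rng, median: float, sdlog: float, size: int) -> np.ndarray:
    return np.exp(np.log(median) + sdlog * rng.standard_normal(size))


def _hormone(rng, median, sdlog, lod, nd_prob, n, noise):
    values = _lognormal(rng, median, sdlog * noise if noise > 0 else 0.0, n)
    if noise == 0:
        values = np.full(n, median)
    nd = (values < lod) | (rng.uniform(size=n) < nd_prob)
    out = values.copy()
    out[nd] = np.nan
    return out, nd


def generate_cohort(
    diets: list[DietSpec], config: GeneratorConfig
) -> list[MouseRecord]:
    """Draw a full two-group cohort over the given diets.

    Reproducible for a fixed ``config.seed``; both groups share the same
    protein-leverage intake law and all mice in a cage share intake.
    """
    if not diets:
        raise ValueError("diets must be non-empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    noise = config.noise_scale

    records: list[MouseRecord] = []
    for group in ("control", "PCOS"):
        for d_idx, diet in enumerate(diets):
            n_mice = config.n_per_diet
            if config.diet3_attrition and d_idx == 2:
                n_mice = min(n_mice, 3)
            n_cages = math.ceil(n_mice / config.cage_size)
            x_p, _, _ = to_simplex(diet)
            cage_food = (
                config.intake_a
                - config.intake_b * math.log(x_p)
                + config.cage_sd * noise * rng.standard_normal(n_cages)
            )
            cage_food = np.maximum(cage_food, 0.1)
            for m in range(n_mice):
                cage = m // config.cage_size
                food = float(cage_food[cage])
                intake = macronutrient_intake(food, diet)
                mu = outcome_means(
                    intake.p_kj, intake.c_kj, intake.f_kj, group, config
                )
                nrm = lambda sd: float(sd * noise * rng.standard_normal())

                cl = int(_sample_counts(rng, mu["cl_count"], config)[()])
                bw = float(mu["body_weight"]) + nrm(config.bw_sd)
                fg = max(0.1, float(mu["fasting_glucose"]) + nrm(config.glu_sd))
                gtt = tuple(
                    max(0.1, fg + d + nrm(config.gtt_sd)) for d in config.gtt_deltas
                )

                window = float(
                    ovulation_window(intake.c_kj, intake.f_kj, config)
                )
                cycling = group == "control" or rng.uniform() < window
                kernel = _CYCLING_KERNEL if cycling else _ACYCLIC_KERNEL
                start = int(rng.integers(4)) if cycling else 3
                seq = _markov_sequence(rng, kernel, config.estrous_days, start)

                pcos = group == "PCOS"
                dht, dht_nd = _hormone(
                    rng, config.dht_pcos if pcos else config.dht_control,
                    config.dht_sdlog, config.dht_lod, config.below_lod_prob,
                    1, noise,
                )
                tst, tst_nd = _hormone(
                    rng, config.tst_pcos if pcos else config.tst_control,
                    config.tst_sdlog, config.tst_lod, config.below_lod_prob,
                    1, noise,
                )
                lh, lh_nd = _hormone(
                    rng, config.lh_median, config.hormone_sdlog, 0.0,
                    config.below_lod_prob, 1, noise,
                )
                fsh, fsh_nd = _hormone(
                    rng, config.fsh_median, config.hormone_sdlog, 0.0,
                    config.below_lod_prob, 1, noise,
                )

                records.append(
                    MouseRecord(
                        mouse_id=f"{group[:3]}_{diet.diet_id}_{m:03d}",
                        group=group,
                        diet_id=diet.diet_id,
                        cage_id=f"{group[:3]}_{diet.diet_id}_c{cage}",
                        food_g=food,
                        intake=intake,
                        cl_count=max(0, cl),
                        body_weight=bw,
                        fat_mass=max(
                            0.0, float(mu["fat_mass"]) + nrm(config.fat_sd)
                        ),
                        lean_mass=max(
                            0.0, float(mu["lean_mass"]) + nrm(config.lean_sd)
                        ),
                        adiponectin=max(
                            0.0, float(mu["adiponectin"]) + nrm(config.adipo_sd)
                        ),
                        cholesterol=max(
                            0.0, float(mu["cholesterol"]) + nrm(config.chol_sd)
                        ),
                        triglycerides=max(
                            0.0, float(mu["triglycerides"]) + nrm(config.trig_sd)
                        ),
                        fasting_glucose=fg,
                        gtt=gtt,
                        estrous_seq=seq,
                        adipocyte_area=max(
                            0.0,
                            float(mu["adipocyte_area"]) + nrm(config.adipocyte_sd),
                        ),
                        dht=float(dht[0]),
                        dht_nd=bool(dht_nd[0]),
                        testosterone=float(tst[0]),
                        testosterone_nd=bool(tst_nd[0]),
                        lh=float(lh[0]),
                        lh_nd=bool(lh_nd[0]),
                        fsh=float(fsh[0]),
                        fsh_nd=bool(fsh_nd[0]),
                    )
                )
    return records


def generate_choice_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the three-diet preference arm.

    Each mouse allocates its daily energy across the high-protein,
    high-carbohydrate and high-fat choice diets with Dirichlet-distributed
    preference weights drawn from the same law in both groups (no group
    effect by default). Returns per-mouse P/C/F energy intakes (kJ/day).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    noise = config.noise_scale
    alpha = np.asarray(config.choice_alpha, dtype=float)
    rows = []
    for group, n in (
        ("control", config.choice_n_control),
        ("PCOS", config.choice_n_pcos),
    ):
        for i in range(n):
            total = config.choice_total_kj + config.choice_total_sd * noise * (
                rng.standard_normal()
            )
            total = max(total, 1.0)
            if noise == 0:
                weights = alpha / alpha.sum()
            else:
                weights = rng.dirichlet(alpha)
            p = c = f = 0.0
            for w, diet in zip(weights, CHOICE_DIETS):
                p += w * total * diet.p_pct / 100.0
                c += w * total * diet.c_pct / 100.0
                f += w * total * diet.f_pct / 100.0
            rows.append(
                {
                    "mouse_id": f"{group[:3]}_choice_{i:02d}",
                    "group": group,
                    "p_kj": p,
                    "c_kj": c,
                    "f_kj": f,
                    "total_kj": p + c + f,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study bookkeeping and CSV round trip

def study_cohort_plan() -> pd.DataFrame:
    """Per-diet completer counts of the original feeding study design.

    Ten mice per diet in each group, except: the third diet was
    discontinued for welfare reasons and contributes only 3 completers
    per group, and the PCOS arm of diet 10 enrolled 11 mice. Summing the
    table gives the analyzed cohort sizes (93 control, 94 PCOS).
    """
    rows = []
    for i in range(1, 11):
        control = 3 if i == 3 else 10
        pcos = 3 if i == 3 else (11 if i == 10 else 10)
        rows.append({"diet": i, "control": control, "PCOS": pcos})
    return pd.DataFrame(rows)


_SCALAR_COLS = [
    "mouse_id", "group", "diet_id", "cage_id", "food_g",
    "p_kj", "c_kj", "f_kj", "total_kj",
    "cl_count", "body_weight", "fat_mass", "lean_mass", "adiponectin",
    "cholesterol", "triglycerides", "fasting_glucose", "estrous_seq",
    "adipocyte_area", "dht", "dht_nd", "testosterone", "testosterone_nd",
    "lh", "lh_nd", "fsh", "fsh_nd",
]


def cohort_to_frame(records: list[MouseRecord]) -> pd.DataFrame:
    """Flatten records to one row per mouse; the GTT series is a
    ';'-joined subfield."""
    rows = []
    for r in records:
        row = {
            "mouse_id": r.mouse_id, "group": r.group, "diet_id": r.diet_id,
            "cage_id": r.cage_id, "food_g": r.food_g,
            "p_kj": r.intake.p_kj, "c_kj": r.intake.c_kj,
            "f_kj": r.intake.f_kj, "total_kj": r.intake.total_kj,
            "cl_count": r.cl_count, "body_weight": r.body_weight,
            "fat_mass": r.fat_mass, "lean_mass": r.lean_mass,
            "adiponectin": r.adiponectin, "cholesterol": r.cholesterol,
            "triglycerides": r.triglycerides,
            "fasting_glucose": r.fasting_glucose,
            "estrous_seq": r.estrous_seq,
            "adipocyte_area": r.adipocyte_area,
            "dht": r.dht, "dht_nd": r.dht_nd,
            "testosterone": r.testosterone,
            "testosterone_nd": r.testosterone_nd,
            "lh": r.lh, "lh_nd": r.lh_nd, "fsh": r.fsh, "fsh_nd": r.fsh_nd,
            "gtt": ";".join(f"{g:.6g}" for g in r.gtt),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=_SCALAR_COLS + ["gtt"])


def frame_to_records(df: pd.DataFrame) -> list[MouseRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    records = []
    for row in df.itertuples(index=False):
        intake = IntakeRecord(
            p_kj=float(row.p_kj), c_kj=float(row.c_kj), f_kj=float(row.f_kj),
            total_kj=float(row.total_kj), food_g=float(row.food_g),
        )
        records.append(
            MouseRecord(
                mouse_id=str(row.mouse_id), group=str(row.group),
                diet_id=str(row.diet_id), cage_id=str(row.cage_id),
                food_g=float(row.food_g), intake=intake,
                cl_count=int(row.cl_count),
                body_weight=float(row.body_weight),
                fat_mass=float(row.fat_mass), lean_mass=float(row.lean_mass),
                adiponectin=float(row.adiponectin),
                cholesterol=float(row.cholesterol),
                triglycerides=float(row.triglycerides),
                fasting_glucose=float(row.fasting_glucose),
                gtt=tuple(float(x) for x in str(row.gtt).split(";")),
                estrous_seq=str(row.estrous_seq),
                adipocyte_area=float(row.adipocyte_area),
                dht=float(row.dht), dht_nd=bool(row.dht_nd),
                testosterone=float(row.testosterone),
                testosterone_nd=bool(row.testosterone_nd),
                lh=float(row.lh), lh_nd=bool(row.lh_nd),
                fsh=float(row.fsh), fsh_nd=bool(row.fsh_nd),
            )
        )
    return records


def write_cohort_csv(records: list[MouseRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[MouseRecord]:
    return frame_to_records(pd.read_csv(path))
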