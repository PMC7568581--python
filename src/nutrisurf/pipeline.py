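"""End-to-end pipeline: simulate -> fit -> diff -> stats -> report.

A single YAML configuration drives every stage; all randomness flows
from one root seed (the generator consumes it directly, and figure
hashing is salted with it), so re-running a configuration reproduces
every numeric output byte for byte. A manifest records the
configuration hash, seed, package versions and every artifact written;
a failed stage leaves the manifest marked incomplete.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    GeneratorConfig,
    MouseRecord,
    cohort_to_frame,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from .diet_design import DietSpec, default_design, load_diet_table, to_simplex
from .differences import subtract_surfaces
from .mixtures import select_degree, ternary_surface_frame
from .plots import RenderSpec, render_difference_panel, render_surface_panel
from .stats import compare_groups, estrous_metrics, gtt_auc
from .surfaces import MIN_FIT_SIZE, fit_surface, predict_slice

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

ALL_STAGES = ("simulate", "fit", "diff", "stats", "report")

#: Default outcome panel with per-outcome family choices; "auto" applies
#: the normality gate between identity and log-Gaussian fits.
DEFAULT_OUTCOMES: dict[str, str] = {
    "cl_count": "negbin-log",
    "body_weight": "auto",
    "adiponectin": "auto",
    "cholesterol": "auto",
    "fasting_glucose": "auto",
}

DEFAULT_SLICE_PAIRS = (("P", "C"), ("P", "F"), ("C", "F"))

_NUMERIC_OUTCOMES = {
    "cl_count", "body_weight", "fat_mass", "lean_mass", "adiponectin",
    "cholesterol", "triglycerides", "fasting_glucose", "adipocyte_area",
    "food_g",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    seed: int = 0
    outdir: str = "results/run"
    level: float = 0.95
    resolution: int = 51
    diet_table: str | None = None
    cohort_csv: str | None = None
    generator: dict = field(default_factory=dict)
    outcomes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES)
    )
    slice_pairs: tuple = DEFAULT_SLICE_PAIRS
    difference_axes: tuple[str, str] = ("C", "F")
    min_fit_size: int = MIN_FIT_SIZE
    output_format: str = "svg"

    def validate(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("confidence level must lie in (0, 1)")
        if not self.outcomes:
            raise ValueError("outcome list must be non-empty")
        unknown = set(self.outcomes) - _NUMERIC_OUTCOMES
        if unknown:
            raise ValueError(f"unknown outcomes: {sorted(unknown)}")
        if self.resolution < 2:
            raise ValueError("resolution must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "slice_pairs" in data:
            data["slice_pairs"] = tuple(tuple(p) for p in data["slice_pairs"])
        if "difference_axes" in data:
            data["difference_axes"] = tuple(data["difference_axes"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_diets(config: PipelineConfig) -> list[DietSpec]:
    if config.diet_table:
        return load_diet_table(config.diet_table)
    return default_design()


def _get_cohort(config: PipelineConfig, diets) -> list[MouseRecord]:
    if config.cohort_csv:
        return read_cohort_csv(config.cohort_csv)
    gen = GeneratorConfig(**config.generator)
    gen.seed = config.seed
    return generate_cohort(diets, gen)


def _outcome_values(records, outcome, group):
    vals = [
        getattr(r, outcome) for r in records
        if r.group == group and np.isfinite(getattr(r, outcome))
    ]
    return np.asarray(vals, dtype=float)


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES
) -> dict:
    """Run the requested stages and return the manifest dictionary.

    Stage order is fixed (simulate -> fit -> diff -> stats -> report);
    later stages reuse in-memory results of earlier ones, so requesting
    e.g. only ``diff`` still runs the fits it needs but writes only the
    artifacts of the requested stages.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": list(stages),
        "status": "incomplete",
        "outputs": [],
        "counts": {},
    }
    manifest_path = outdir / "manifest.json"

    def emit(path: Path):
        manifest["outputs"].append(str(path.relative_to(outdir)))

    stage = "setup"
    try:
        diets = _load_diets(config)
        stage = "simulate"
        records = _get_cohort(config, diets)
        manifest["counts"]["mice"] = len(records)
        manifest["counts"]["diets"] = len(diets)
        if "simulate" in stages:
            path = outdir / "cohort.csv"
            write_cohort_csv(records, path)
            emit(path)

        fits: dict[tuple[str, str], object] = {}
        need_fit = any(s in stages for s in ("fit", "diff", "report"))
        if need_fit:
            stage = "fit"
            for outcome, family in config.outcomes.items():
                for group in ("control", "PCOS"):
                    fit = fit_surface(
                        records, outcome, group, family,
                        min_fit_size=config.min_fit_size,
                    )
                    fits[(outcome, group)] = fit
                    if "fit" in stages:
                        jpath = outdir / f"fit_{outcome}_{group}.json"
                        fit.to_json(jpath)
                        emit(jpath)
                        for pair in config.slice_pairs:
                            grid = predict_slice(
                                fit, tuple(pair), config.resolution
                            )
                            cpath = (
                                outdir
                                / f"slice_{outcome}_{group}_{pair[0]}{pair[1]}.csv"
                            )
                            grid.to_csv(cpath)
                            emit(cpath)
            if "fit" in stages:
                _mixture_stage(records, diets, outdir, emit)

        diffs = {}
        if any(s in stages for s in ("diff", "report")):
            stage = "diff"
            for outcome in config.outcomes:
                diff = subtract_surfaces(
                    fits[(outcome, "control")], fits[(outcome, "PCOS")],
                    config.difference_axes, config.level, config.resolution,
                )
                diffs[outcome] = diff
                if "diff" in stages:
                    dpath = outdir / f"diff_{outcome}.csv"
                    diff.to_csv(dpath)
                    emit(dpath)

        if "stats" in stages:
            stage = "stats"
            table = _stats_stage(records, config)
            spath = outdir / "group_comparisons.csv"
            table.to_csv(spath, index=False)
            emit(spath)

        if "report" in stages:
            stage = "report"
            import matplotlib.pyplot as plt

            plt.rcParams["svg.hashsalt"] = f"nutrisurf-{config.seed}"
            spec = RenderSpec(output_format=config.output_format)
            for outcome in config.outcomes:
                pair = tuple(config.difference_axes)
                diff = diffs[outcome]
                g1 = predict_slice(
                    fits[(outcome, "control")], pair, config.resolution,
                    fixed_value=diff.grid.fixed_value,
                    axis1=diff.grid.axis1, axis2=diff.grid.axis2,
                )
                g2 = predict_slice(
                    fits[(outcome, "PCOS")], pair, config.resolution,
                    fixed_value=diff.grid.fixed_value,
                    axis1=diff.grid.axis1, axis2=diff.grid.axis2,
                )
                fpath = outdir / f"surfaces_{outcome}.{config.output_format}"
                render_surface_panel((g1, g2), spec, fpath)
                emit(fpath)
                emit(Path(str(fpath) + ".json"))
                dpath = outdir / f"difference_{outcome}.{config.output_format}"
                render_difference_panel(diff, spec, dpath, title=outcome)
                emit(dpath)
                emit(Path(str(dpath) + ".json"))

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["error"] = f"stage {stage!r} failed: {exc}"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise PipelineError(manifest["error"]) from exc

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _mixture_stage(records, diets, outdir: Path, emit) -> None:
    """Scheffe fits of cage food and energy intake on diet composition."""
    diet_map = {d.diet_id: d for d in diets}
    for group in ("control", "PCOS"):
        cages: dict[str, tuple] = {}
        for r in records:
            if r.group == group:
                cages[r.cage_id] = (r.diet_id, r.food_g, r.intake.total_kj)
        pts = np.array([to_simplex(diet_map[d]) for d, _, _ in cages.values()])
        for response, idx in (("food_g", 1), ("total_kj", 2)):
            y = np.array([v[idx] for v in cages.values()])
            fit = select_degree(pts, y, response=response)
            jpath = outdir / f"mixture_{response}_{group}.json"
            fit.to_json(jpath)
            emit(jpath)
            tpath = outdir / f"ternary_{response}_{group}.csv"
            ternary_surface_frame(fit).to_csv(tpath, index=False)
            emit(tpath)


def _stats_stage(records, config: PipelineConfig) -> pd.DataFrame:
    """Pooled-across-diet group contrasts plus derived metrics."""
    rows = []
    for outcome in config.outcomes:
        x = _outcome_values(records, outcome, "control")
        y = _outcome_values(records, outcome, "PCOS")
        cmp = compare_groups(x, y, "continuous", outcome=outcome)
        rows.append(_comparison_row(cmp))

    # GTT AUC contrast
    from .cohort import GTT_MINUTES

    auc = {
        g: np.array([
            gtt_auc(GTT_MINUTES, r.gtt) for r in records if r.group == g
        ])
        for g in ("control", "PCOS")
    }
    rows.append(
        _comparison_row(
            compare_groups(auc["control"], auc["PCOS"], "continuous",
                           outcome="gtt_auc")
        )
    )

    # cycling proportion contrast (Fisher)
    cyc = {}
    for g in ("control", "PCOS"):
        flags = [
            estrous_metrics(r.estrous_seq).is_cycling
            for r in records if r.group == g
        ]
        cyc[g] = (int(sum(flags)), int(len(flags) - sum(flags)))
    rows.append(
        _comparison_row(
            compare_groups(cyc["control"], cyc["PCOS"], "proportion",
                           outcome="is_cycling")
        )
    )
    return pd.DataFrame(rows)


def _comparison_row(cmp) -> dict:
    (m1, s1), (m2, s2) = cmp.mean_sem
    return {
        "outcome": cmp.outcome,
        "test": cmp.test,
        "statistic": cmp.statistic,
        "p_value": cmp.p_value,
        "control_mean": m1,
        "control_sem": s1,
        "pcos_mean": m2,
        "pcos_sem": s2,
        "n_control": cmp.n[0],
        "n_pcos": cmp.n[1],
    }


def _versions() -> dict[str, str]:
    import matplotlib
    import scipy
    import statsmodels

    return {
        "nutrisurf": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }
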