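"""Figure-style rendering of paired response surfaces and differences.

Paired heatmaps share one color scale spanning the pooled unmasked
range of both groups (red = highest response, blue = lowest), with
labeled contours and the fixed-axis median printed in parentheses under
the x-axis label. Difference panels color significant cells by the
signed difference on a diverging map and render non-significant cells
neutral gray. A JSON sidecar records color limits and contour levels so
rendering decisions are testable without parsing image files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .differences import DifferenceSurface
from .surfaces import SliceGrid

__all__ = ["RenderSpec", "render_surface_panel", "render_difference_panel"]


@dataclass
class RenderSpec:
    """Rendering options for surface and difference panels."""

    color_map: str = "turbo"          # sequential blue -> red
    diverging_map: str = "PuOr_r"     # for signed differences
    shared_limits: bool = True
    contour_levels: int | tuple[float, ...] = 7
    annotate_median: bool = True
    output_format: str = "svg"        # svg is the bit-stable surface

    def __post_init__(self):
        if self.output_format not in ("png", "svg"):
            raise ValueError("output_format must be 'png' or 'svg'")


def _pooled_limits(grids: tuple[SliceGrid, ...]) -> tuple[float, float]:
    values = np.concatenate(
        [g.raw_mean[g.mask] for g in grids if g.mask.any()]
    )
    if values.size == 0:
        raise ValueError("no unmasked cells to render")
    return float(np.nanmin(values)), float(np.nanmax(values))


def _axis_label(grid: SliceGrid, axis: str, spec: RenderSpec,
                with_median: bool) -> str:
    label = f"{axis} intake (kJ/day)"
    if with_median and spec.annotate_median:
        label += f"\n({grid.fixed_axis} = {grid.fixed_value:.1f} kJ/day)"
    return label


def _contour_levels(spec: RenderSpec, vmin: float, vmax: float) -> np.ndarray:
    if isinstance(spec.contour_levels, int):
        if vmax <= vmin:
            return np.array([vmin])
        return np.linspace(vmin, vmax, spec.contour_levels + 2)[1:-1]
    return np.asarray(spec.contour_levels, dtype=float)


def _save(fig, path: Path, spec: RenderSpec) -> None:
    fig.savefig(path, format=spec.output_format,
                metadata={"Date": None} if spec.output_format == "svg" else None)
    plt.close(fig)


def render_surface_panel(
    grids: tuple[SliceGrid, SliceGrid],
    spec: RenderSpec,
    path: str | Path,
    titles: tuple[str, str] = ("control", "PCOS"),
) -> dict:
    """Render a pair of slice heatmaps with one pooled color scale.

    Returns the sidecar dictionary (also written to ``<path>.json``)
    with the color limits and contour levels used.
    """
    g1, g2 = grids
    if g1.free_axes != g2.free_axes or g1.axis1.shape != g2.axis1.shape:
        raise ValueError("paired grids must share axes and resolution")
    if spec.shared_limits:
        vmin, vmax = _pooled_limits((g1, g2))
        limits = [(vmin, vmax), (vmin, vmax)]
    else:
        limits = [_pooled_limits((g,)) for g in (g1, g2)]

    path = Path(path)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), constrained_layout=True)
    sidecar_panels = []
    for ax, grid, title, (vmin, vmax) in zip(axes, grids, titles, limits):
        masked = np.ma.masked_where(~grid.mask, grid.raw_mean)
        mesh = ax.pcolormesh(
            grid.axis1, grid.axis2, masked, cmap=spec.color_map,
            vmin=vmin, vmax=vmax, shading="nearest",
        )
        levels = _contour_levels(spec, vmin, vmax)
        if len(levels) > 1:
            cs = ax.contour(grid.axis1, grid.axis2, masked, levels=levels,
                            colors="black", linewidths=0.6)
            ax.clabel(cs, fontsize=6, fmt="%.3g")
        ax.set_title(title)
        ax.set_xlabel(_axis_label(grid, grid.free_axes[0], spec, True))
        ax.set_ylabel(_axis_label(grid, grid.free_axes[1], spec, False))
        fig.colorbar(mesh, ax=ax, shrink=0.85)
        sidecar_panels.append(
            {"title": title, "vmin": vmin, "vmax": vmax,
             "contour_levels": np.asarray(levels).tolist()}
        )
    _save(fig, path, spec)

    sidecar = {
        "kind": "surface_pair",
        "free_axes": list(g1.free_axes),
        "fixed_axis": g1.fixed_axis,
        "fixed_value": g1.fixed_value,
        "shared_limits": spec.shared_limits,
        "panels": sidecar_panels,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return sidecar


def render_difference_panel(
    diff: DifferenceSurface,
    spec: RenderSpec,
    path: str | Path,
    title: str = "response difference",
) -> dict:
    """Render a difference slice: gray where not significant, signed
    color elsewhere; returns (and writes) the sidecar dictionary."""
    grid = diff.grid
    path = Path(path)
    display = diff.raw_d

    sig = diff.significant & grid.mask
    vmax = float(np.nanmax(np.abs(display[sig]))) if sig.any() else 1.0
    if vmax == 0:
        vmax = 1.0

    fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
    # background: neutral gray on every in-support, non-significant cell
    gray = np.ma.masked_where(~(grid.mask & ~sig), np.zeros_like(display))
    ax.pcolormesh(grid.axis1, grid.axis2, gray, cmap="Greys",
                  vmin=-1, vmax=3, shading="nearest")
    colored = np.ma.masked_where(~sig, display)
    mesh = ax.pcolormesh(grid.axis1, grid.axis2, colored,
                         cmap=spec.diverging_map, vmin=-vmax, vmax=vmax,
                         shading="nearest")
    ax.set_title(f"{title} ({diff.level * 100:g}% CFL)")
    ax.set_xlabel(_axis_label(grid, grid.free_axes[0], spec, True))
    ax.set_ylabel(_axis_label(grid, grid.free_axes[1], spec, False))
    fig.colorbar(mesh, ax=ax, shrink=0.85)
    _save(fig, path, spec)

    sidecar = {
        "kind": "difference",
        "free_axes": list(grid.free_axes),
        "fixed_axis": grid.fixed_axis,
        "fixed_value": grid.fixed_value,
        "level": diff.level,
        "q": diff.q,
        "vlim": vmax,
        "n_significant": int(sig.sum()),
        "n_cells": int(grid.mask.sum()),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
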