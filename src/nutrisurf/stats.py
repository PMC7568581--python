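"""Group-level comparisons and derived phenotype metrics.

Continuous outcomes are compared between control and PCOS mice with a
Student's t-test when both groups pass a Shapiro-Wilk normality check
(alpha = 0.05) and a Mann-Whitney test otherwise; proportions use
Fisher's exact test. The Mann-Whitney p-value is computed by exhaustive
mid-rank permutation enumeration for small samples (total n <= 20) and
by the tie-corrected normal approximation beyond that.

Also here: estrous-cycle metrics from daily smear sequences, the
trapezoidal glucose-tolerance AUC, and substitution rules for
below-detection-limit (left-censored) hormone values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import fisher_exact, norm, rankdata, shapiro, ttest_ind

__all__ = [
    "GroupComparison",
    "EstrousMetrics",
    "compare_groups",
    "mannwhitney_exact",
    "estrous_metrics",
    "gtt_auc",
    "censor_substitute",
]

EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class GroupComparison:
    """Result of one control-vs-PCOS contrast."""

    outcome: str
    test: str                      # "t", "mann-whitney" or "fisher"
    statistic: float
    p_value: float
    mean_sem: tuple[tuple[float, float], tuple[float, float]]
    n: tuple[int, int]

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


@dataclass(frozen=True)
class EstrousMetrics:
    """Summary of one 11-day estrous smear sequence."""

    pct_time: dict[str, float]
    cycles_completed: int
    is_cycling: bool


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    sem = float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(np.mean(x)), sem


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test by exhaustive permutation.

    Mid-ranks handle ties; the p-value is the fraction of all
    C(n1+n2, n1) group assignments whose U statistic is at least as far
    from its null mean n1*n2/2 as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    center = n1 * n2 / 2.0
    dev_obs = abs(u_obs - center) - 1e-9
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = float(np.sum(ranks[list(idx)])) - n1 * (n1 + 1) / 2.0
        if abs(u - center) >= dev_obs:
            count += 1
        total += 1
    return u_obs, count / total


def _mannwhitney_normal(x, y) -> tuple[float, float]:
    """Tie-corrected normal approximation (mid-ranks, no continuity)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    u = float(np.sum(ranks[:n1])) - n1 * (n1 + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return u, 1.0
    z = (u - n1 * n2 / 2.0) / math.sqrt(var_u)
    return u, float(2 * norm.sf(abs(z)))


def compare_groups(x, y, kind: str = "continuous",
                   outcome: str = "") -> GroupComparison:
    """Compare two groups the way the study's violin/bar panels do.

    ``kind="continuous"``: Shapiro-Wilk on each group (alpha = 0.05)
    gates between Student's t-test (both normal) and Mann-Whitney
    (either non-normal); requires >= 3 observations per group.
    ``kind="proportion"``: ``x`` and ``y`` are the (successes, failures)
    rows of a 2x2 table, tested with Fisher's exact test.
    """
    if kind == "proportion":
        table = np.asarray([x, y])
        if table.shape != (2, 2):
            raise ValueError("proportion comparison needs a 2x2 table")
        if not np.allclose(table, np.rint(table)) or np.any(table < 0):
            raise ValueError("proportion counts must be non-negative integers")
        table = table.astype(int)
        stat, p = fisher_exact(table, alternative="two-sided")
        n1, n2 = int(table[0].sum()), int(table[1].sum())
        prop = lambda row: (row[0] / row.sum() if row.sum() else 0.0, 0.0)
        return GroupComparison(
            outcome=outcome, test="fisher", statistic=float(stat),
            p_value=float(p), mean_sem=(prop(table[0]), prop(table[1])),
            n=(n1, n2),
        )

    if kind != "continuous":
        raise ValueError(f"unknown comparison kind {kind!r}")

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 observations per group")

    def _normal(v):
        if np.ptp(v) == 0:
            return False
        return shapiro(v).pvalue >= 0.05

    if _normal(x) and _normal(y):
        stat, p = ttest_ind(x, y)
        test = "t"
        stat, p = float(stat), float(p)
    else:
        test = "mann-whitney"
        if len(x) + len(y) <= EXACT_MW_MAX_N:
            stat, p = mannwhitney_exact(x, y)
        else:
            stat, p = _mannwhitney_normal(x, y)
    return GroupComparison(
        outcome=outcome, test=test, statistic=stat, p_value=min(p, 1.0),
        mean_sem=(_mean_sem(x), _mean_sem(y)), n=(len(x), len(y)),
    )


# ---------------------------------------------------------------------------
# estrous metrics

_STAGES = "PEMD"


def estrous_metrics(seq: str) -> EstrousMetrics:
    """Percent time per stage and completed-cycle count of a smear series.

    A completed cycle is an ordered traversal proestrus -> estrus ->
    diestrus, with metestrus optional between estrus and diestrus and
    arbitrary repetition within each visited stage (metestrus is brief
    and often missed in daily smears). A mouse is cycling if it
    completed at least one cycle.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    bad = set(seq) - set(_STAGES)
    if bad:
        raise ValueError(f"unknown estrous stage symbols: {sorted(bad)}")

    pct = {s: 100.0 * seq.count(s) / len(seq) for s in _STAGES}

    # compress runs, then walk a P -> E -> (M) -> D state machine
    runs = [seq[0]]
    for ch in seq[1:]:
        if ch != runs[-1]:
            runs.append(ch)
    cycles = 0
    state = "idle"
    for stage in runs:
        if state == "idle":
            if stage == "P":
                state = "sawP"
        elif state == "sawP":
            if stage == "E":
                state = "sawE"
            elif stage in ("M", "D"):
                state = "idle"
        elif state == "sawE":
            if stage == "D":
                cycles += 1
                state = "idle"
            elif stage == "P":
                state = "sawP"
            # E or M: still progressing through the cycle
    return EstrousMetrics(
        pct_time=pct, cycles_completed=cycles, is_cycling=cycles >= 1
    )


def gtt_auc(times, glucose) -> float:
    """Trapezoidal area under the glucose-tolerance curve (mmol/L x min)."""
    times = np.asarray(times, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if times.shape != glucose.shape:
        raise ValueError("times and glucose must have the same length")
    if times.ndim != 1 or len(times) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(glucose, times))


def censor_substitute(values, nondetect, lod: float | None = None,
                      method: str = "lod_scaled") -> np.ndarray:
    """Replace below-LOD (nondetect) values for analysis.

    ``lod_scaled`` substitutes LOD/sqrt(2), the standard single-value
    replacement for left-censored assay data; ``min_observed``
    substitutes the smallest detected value. Detected values are never
    altered.
    """
    values = np.asarray(values, dtype=float).copy()
    nondetect = np.asarray(nondetect, dtype=bool)
    if values.shape != nondetect.shape:
        raise ValueError("values and nondetect flags must align")
    if not nondetect.any():
        return values
    if method == "lod_scaled":
        if lod is None or lod <= 0:
            raise ValueError("lod_scaled substitution requires lod > 0")
        values[nondetect] = lod / math.sqrt(2.0)
    elif method == "min_observed":
        detected = values[~nondetect]
        detected = detected[np.isfinite(detected)]
        if len(detected) == 0:
            raise ValueError(
                "min_observed substitution requires >= 1 detected value"
            )
        values[nondetect] = float(detected.min())
    else:
        raise ValueError(f"unknown substitution method {method!r}")
    return values
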