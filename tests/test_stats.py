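import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from nutrisurf import (
    censor_substitute,
    compare_groups,
    estrous_metrics,
    gtt_auc,
)
from nutrisurf.stats import mannwhitney_exact


# ---------------------------------------------------------------------------
# independent oracles

def _mw_oracle(x, y):
    """Brute-force Mann-Whitney: U by pair counting, p by enumerating
    every assignment of the pooled values to the two groups."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = 0.0
        for xi in a:
            for yj in b:
                u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        return u

    center = n1 * len(y) / 2.0
    obs = abs(u_stat(range(n1)) - center)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(set(idx)) - center) >= obs - 1e-9:
            hits += 1
    return hits / total


def _fisher_oracle(table):
    """Two-sided Fisher p by summing hypergeometric point masses no
    larger than the observed one."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, row1, col1)
    p_obs = dist.pmf(a)
    total = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p_k = dist.pmf(k)
        if p_k <= p_obs * (1 + 1e-9):
            total += p_k
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# Mann-Whitney

class TestMannWhitney:
    def test_identical_samples_give_p_one(self):
        x = [3.0, 1.0, 2.0, 5.0]
        _, p = mannwhitney_exact(x, list(x))  # mid-ranks, U at its center
        assert p == 1.0
        assert compare_groups(x, list(x)).p_value == 1.0

    def test_separated_groups_match_enumeration(self):
        _, p = mannwhitney_exact([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(_mw_oracle([1, 2, 3], [4, 5, 6]))
        assert p == pytest.approx(0.1)  # 2 of the 20 assignments

    @pytest.mark.parametrize("n1,n2", [(3, 3), (3, 4), (4, 4), (5, 5), (3, 7), (2, 8)])
    def test_exact_p_equals_permutation_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(5):
            x = rng.integers(0, 6, n1).astype(float)  # ties likely
            y = rng.integers(0, 6, n2).astype(float)
            _, p = mannwhitney_exact(x, y)
            assert p == pytest.approx(_mw_oracle(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        data=st.lists(st.integers(0, 8), min_size=6, max_size=10),
        n1=st.integers(3, 5),
    )
    def test_property_sweep_small_samples(self, data, n1):
        if n1 >= len(data) - 2:
            n1 = len(data) - 3
        x = [float(v) for v in data[:n1]]
        y = [float(v) for v in data[n1:]]
        _, p = mannwhitney_exact(x, y)
        assert p == pytest.approx(_mw_oracle(x, y), abs=1e-12)

    def test_large_sample_normal_approximation_reasonable(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1.5, 1, 30)
        res = compare_groups(np.exp(x), np.exp(y))  # lognormal: MW branch
        assert res.test == "mann-whitney"
        assert res.p_value < 0.001

    def test_gate_selects_t_for_normal_data(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0, 1, 40), rng.normal(0.2, 1, 40))
        assert res.test == "t"


# ---------------------------------------------------------------------------
# Fisher

class TestFisher:
    def test_study_anovulation_table_matches_hypergeometric(self):
        """8/35 PCOS ovaries with corpora lutea vs 36/36 control."""
        table = ((8, 27), (36, 0))
        res = compare_groups(table[0], table[1], kind="proportion")
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(_fisher_oracle(table), rel=1e-9)
        assert res.p_value < 1e-9

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_random_tables_match_hypergeometric(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        table = ((a, b), (c, d))
        res = compare_groups(table[0], table[1], kind="proportion")
        assert res.p_value == pytest.approx(_fisher_oracle(table), rel=1e-7)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            compare_groups((1.5, 2), (3, 4), kind="proportion")


class TestCompareGroupsValidation:
    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_mean_sem_reported(self):
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        (m1, s1), (m2, s2) = res.mean_sem
        assert m1 == pytest.approx(2.0)
        assert m2 == pytest.approx(5.0)
        assert s1 == pytest.approx(1.0 / math.sqrt(3))
        assert res.n == (3, 3)


# ---------------------------------------------------------------------------
# estrous metrics

class TestEstrousMetrics:
    def test_all_diestrus_is_acyclic(self):
        m = estrous_metrics("DDDDDDDDDDD")
        assert m.pct_time["D"] == 100.0
        assert m.cycles_completed == 0
        assert not m.is_cycling

    def test_single_full_cycle(self):
        m = estrous_metrics("PPEEMMDDPPE")
        assert m.cycles_completed == 1
        assert m.is_cycling

    def test_metestrus_optional(self):
        assert estrous_metrics("PED").cycles_completed == 1
        assert estrous_metrics("PEMD").cycles_completed == 1
        assert estrous_metrics("PD").cycles_completed == 0  # no estrus

    def test_two_cycles(self):
        assert estrous_metrics("PEDPEMD").cycles_completed == 2

    def test_pct_time_sums_to_100_and_ignores_order(self):
        a = estrous_metrics("PPEEMMDDDDD")
        b = estrous_metrics("DPDPDEMEDDM")
        assert sum(a.pct_time.values()) == pytest.approx(100.0, abs=1e-9)
        assert a.pct_time == b.pct_time

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            estrous_metrics("PEXD")

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estrous_metrics("P")

    def test_window_mice_cycle_more(self, diets):
        """PCOS mice inside the permissive intake window cycle more often
        than those outside (one-sided Fisher)."""
        from nutrisurf import GeneratorConfig, generate_cohort
        from scipy.stats import fisher_exact

        cfg = GeneratorConfig(seed=21, n_per_diet=20)
        records = generate_cohort(diets, cfg)
        inside = [0, 0]
        outside = [0, 0]
        for r in records:
            if r.group != "PCOS":
                continue
            cyc = estrous_metrics(r.estrous_seq).is_cycling
            c, f = r.intake.c_kj, r.intake.f_kj
            box = (cfg.c_window[0] <= c <= cfg.c_window[1]
                   and cfg.f_window[0] <= f <= cfg.f_window[1])
            tgt = inside if box else outside
            tgt[0] += cyc
            tgt[1] += not cyc
        _, p = fisher_exact([inside, outside], alternative="greater")
        assert p < 0.05


# ---------------------------------------------------------------------------
# GTT AUC

class TestGttAuc:
    def test_constant_series_rectangle(self):
        assert gtt_auc((0, 15, 30, 60, 90), [9] * 5) == pytest.approx(810.0)

    def test_hand_computed_trapezoid(self):
        # segments: 150 + 180 + 330 + 270
        auc = gtt_auc((0, 15, 30, 60, 90), (8, 12, 12, 10, 8))
        assert auc == pytest.approx(930.0)

    def test_two_point_series(self):
        assert gtt_auc((0, 90), (10, 10)) == pytest.approx(900.0)

    def test_collinear_midpoint_invariance(self):
        base = gtt_auc((0, 30, 90), (8.0, 10.0, 14.0))
        refined = gtt_auc((0, 15, 30, 90), (8.0, 9.0, 10.0, 14.0))
        assert refined == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize(
        "times,glucose",
        [((0, 15, 30), (1.0, 2.0)), ((0, 15, 15), (1.0, 2.0, 3.0))],
    )
    def test_invalid_series_rejected(self, times, glucose):
        with pytest.raises(ValueError):
            gtt_auc(times, glucose)


# ---------------------------------------------------------------------------
# censoring substitution

class TestCensorSubstitute:
    def test_lod_scaled_uses_lod_over_sqrt2(self):
        out = censor_substitute([np.nan], [True], lod=0.05)
        assert out[0] == pytest.approx(0.035355, abs=1e-6)

    def test_min_observed_uses_lowest_detected(self):
        out = censor_substitute(
            [np.nan, 0.12, 0.30], [True, False, False], method="min_observed"
        )
        assert np.allclose(out, [0.12, 0.12, 0.30])

    def test_no_nondetects_identity(self):
        values = [0.2, 0.4, 0.9]
        out = censor_substitute(values, [False] * 3, lod=0.05)
        assert np.array_equal(out, values)

    def test_detected_values_untouched(self):
        out = censor_substitute(
            [np.nan, 0.7], [True, False], lod=0.1, method="lod_scaled"
        )
        assert out[1] == 0.7

    def test_all_nondetect_min_observed_rejected(self):
        with pytest.raises(ValueError):
            censor_substitute([np.nan, np.nan], [True, True],
                              method="min_observed")

    def test_lod_required_for_lod_scaled(self):
        with pytest.raises(ValueError):
            censor_substitute([np.nan], [True], lod=None, method="lod_scaled")
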