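import numpy as np
import pytest

from nutrisurf import (
    GeneratorConfig,
    fit_surface,
    generate_cohort,
    outcome_means,
    predict_slice,
)
from nutrisurf.surfaces import (
    FitError,
    ThinPlateBasis,
    _pirls,
    farthest_point_order,
)

from conftest import make_records

import statsmodels.api as sm


def _grid_xyz(n_side=5, lo=5.0, hi=30.0):
    axes = np.linspace(lo, hi, n_side)
    g = np.meshgrid(axes, axes, axes)
    return np.column_stack([a.ravel() for a in g])


class TestFitSurface:
    def test_constant_outcome_recovered_everywhere(self):
        xyz = _grid_xyz(4)
        records = make_records(xyz, np.full(len(xyz), 7.0))
        fit = fit_surface(records, "body_weight", "control",
                          "gaussian-identity")
        eta, se = fit.predict_latent(xyz)
        assert np.max(np.abs(eta - 7.0)) < 1e-6
        assert np.all(se >= 0)

    def test_linear_plane_matches_least_squares(self):
        """Noiseless planar data: GAM predictions equal the OLS plane."""
        rng = np.random.default_rng(0)
        xyz = rng.uniform(3, 40, size=(80, 3))
        y = 2.0 + 0.3 * xyz[:, 0]
        records = make_records(xyz, y)
        fit = fit_surface(records, "body_weight", "control",
                          "gaussian-identity")
        # independent oracle: ordinary least squares on [1, P, C, F]
        X = np.column_stack([np.ones(len(xyz)), xyz])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        eta, _ = fit.predict_latent(xyz)
        assert np.max(np.abs(eta - X @ beta)) < 1e-3

    def test_negbin_recovers_known_log_mean(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(3, 40, size=(300, 3))
        true_mu = np.exp(1.0 + 0.05 * xyz[:, 1])
        k = 4.0
        counts = rng.negative_binomial(k, k / (k + true_mu))
        records = make_records(xyz, counts, outcome="cl_count")
        fit = fit_surface(records, "cl_count", "control", "negbin-log")
        eta, _ = fit.predict_latent(xyz)
        fitted_mu = np.exp(eta)
        corr = np.corrcoef(fitted_mu, true_mu)[0, 1]
        assert corr > 0.95
        assert np.all(fitted_mu > 0)
        assert fit.deviance <= fit.null_deviance + 1e-8

    def test_zero_noise_surface_rmse_below_one_percent(self, diets):
        """Parameter recovery: noiseless generator means are reproduced."""
        cfg = GeneratorConfig(seed=0, n_per_diet=10, noise_scale=0.0,
                              cl_size=None)
        records = generate_cohort(diets, cfg)
        fit = fit_surface(records, "body_weight", "PCOS",
                          "gaussian-identity")
        xyz = fit.support
        truth = outcome_means(xyz[:, 0], xyz[:, 1], xyz[:, 2], "PCOS", cfg)[
            "body_weight"
        ]
        eta, _ = fit.predict_latent(xyz)
        rmse = float(np.sqrt(np.mean((eta - truth) ** 2)))
        assert rmse < 0.01 * np.ptp(truth)

    def test_too_few_records_raises(self):
        xyz = _grid_xyz(2)  # 8 points
        records = make_records(xyz, np.arange(len(xyz), dtype=float))
        with pytest.raises(FitError, match="minimum fit size"):
            fit_surface(records, "body_weight", "control",
                        "gaussian-identity")

    def test_non_integer_counts_rejected_under_negbin(self):
        xyz = _grid_xyz(4)
        records = make_records(xyz, np.full(len(xyz), 2.0) + 0.5)
        with pytest.raises(ValueError, match="integer"):
            fit_surface(records, "body_weight", "control", "negbin-log")

    def test_unknown_family_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="family"):
            fit_surface(default_cohort, "cl_count", "control", "poisson")

    def test_auto_family_gates_on_normality(self):
        rng = np.random.default_rng(5)
        xyz = rng.uniform(3, 40, size=(120, 3))
        normal_y = 20 + 0.1 * xyz.sum(axis=1) + rng.normal(0, 1, 120)
        skewed_y = np.exp(rng.normal(0, 1.2, 120))
        fit_n = fit_surface(make_records(xyz, normal_y), "body_weight",
                            "control", "auto")
        fit_s = fit_surface(make_records(xyz, skewed_y), "body_weight",
                            "control", "auto")
        assert fit_n.family == "gaussian-identity"
        assert fit_s.family == "gaussian-log"


class TestBasis:
    def test_farthest_point_prefixes_are_nested(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(30, 3))
        order = farthest_point_order(pts)
        assert sorted(order) == list(range(30))
        # prefix property: the ordering is a single fixed sequence
        assert list(order[:10]) == list(farthest_point_order(pts)[:10])

    def test_more_knots_never_increase_deviance(self):
        """Nested-model sanity at (numerically) zero penalty."""
        rng = np.random.default_rng(3)
        xyz = rng.uniform(0, 30, size=(120, 3))
        y = np.sin(xyz[:, 0] / 6) + 0.1 * xyz[:, 1] + rng.normal(0, 0.2, 120)
        fam = sm.families.Gaussian()
        devs = []
        for k in (10, 20, 40):
            basis = ThinPlateBasis(xyz, max_knots=k)
            X = basis.design(xyz)
            *_, dev, _ = _pirls(y, X, basis.penalty, fam, 1e-8)
            devs.append(dev)
        assert devs[1] <= devs[0] * (1 + 1e-6)
        assert devs[2] <= devs[1] * (1 + 1e-6)

    def test_penalty_is_positive_semidefinite(self):
        rng = np.random.default_rng(4)
        basis = ThinPlateBasis(rng.uniform(0, 30, size=(60, 3)))
        w = np.linalg.eigvalsh(basis.penalty)
        assert w.min() >= -1e-10
        # the linear polynomial block is unpenalized
        assert np.allclose(basis.penalty[:4, :4], 0)


class TestPredictSlice:
    def test_constant_fit_constant_slice(self):
        xyz = _grid_xyz(4)
        records = make_records(xyz, np.full(len(xyz), 7.0))
        fit = fit_surface(records, "body_weight", "control",
                          "gaussian-identity")
        grid = predict_slice(fit, ("P", "C"), 21)
        assert np.nanmax(np.abs(grid.raw_mean[grid.mask] - 7.0)) < 1e-6

    def test_back_transform_consistency(self, cl_fits):
        grid = predict_slice(cl_fits["PCOS"], ("C", "F"), 31)
        inside = grid.mask
        assert np.array_equal(
            grid.raw_mean[inside], np.exp(grid.latent_mean[inside])
        )
        # zero latent mean back-transforms to exactly 1 under the log link
        assert cl_fits["PCOS"].inverse_link(np.array([0.0]))[0] == 1.0

    def test_fixed_value_is_training_median(self, bw_fits):
        fit = bw_fits["control"]
        grid = predict_slice(fit, ("C", "F"), 11)
        assert grid.fixed_axis == "P"
        assert grid.fixed_value == pytest.approx(
            float(np.median(fit.support[:, 0]))
        )

    def test_masked_cells_carry_no_predictions(self, bw_fits):
        grid = predict_slice(bw_fits["control"], ("C", "F"), 31)
        assert np.isnan(grid.latent_mean[~grid.mask]).all()
        assert np.isnan(grid.latent_se[~grid.mask]).all()
        assert np.all(grid.latent_se[grid.mask] >= 0)

    def test_support_masking_excludes_outside_hull(self):
        """Points outside the convex hull of observed intakes are masked."""
        # L-shaped support in the C x F plane at fixed P
        pts = []
        for c in np.linspace(5, 30, 8):
            for f in np.linspace(5, 30, 8):
                if c <= 15 or f <= 15:  # exclude the high-C, high-F corner
                    pts.append((10.0, c, f))
        xyz = np.array(pts)
        records = make_records(xyz, 20 + 0.1 * xyz[:, 1])
        fit = fit_surface(records, "body_weight", "control",
                          "gaussian-identity")
        grid = predict_slice(fit, ("C", "F"), 41)
        ic = np.argmin(np.abs(grid.axis1 - 28.0))
        jf = np.argmin(np.abs(grid.axis2 - 28.0))
        assert not grid.mask[jf, ic]          # outside the L
        ic0 = np.argmin(np.abs(grid.axis1 - 10.0))
        assert grid.mask[jf, ic0]             # inside the L

    def test_resolution_validation(self, bw_fits):
        with pytest.raises(ValueError):
            predict_slice(bw_fits["control"], ("C", "F"), 1)
        with pytest.raises(ValueError):
            predict_slice(bw_fits["control"], ("C", "C"), 11)

    def test_pcos_cl_argmax_inside_window(self, cl_fits, diets):
        """The fitted PCOS corpora-lutea peak sits in the permissive
        window (C 20-30, F 15-25 kJ/day)."""
        grid = predict_slice(cl_fits["PCOS"], ("C", "F"), 51)
        masked = np.where(grid.mask, grid.raw_mean, -np.inf)
        j, i = np.unravel_index(np.argmax(masked), masked.shape)
        assert 20 <= grid.axis1[i] <= 30
        assert 15 <= grid.axis2[j] <= 25

    def test_slice_export_long_format(self, bw_fits, tmp_path):
        grid = predict_slice(bw_fits["control"], ("P", "F"), 11)
        path = tmp_path / "slice.csv"
        grid.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["P", "F", "latent_mean", "latent_se",
                                    "raw_mean", "mask"]
        assert len(df) == 121


def test_surface_fit_json_export(bw_fits, tmp_path):
    import json

    path = tmp_path / "fit.json"
    doc = bw_fits["control"].to_json(path)
    loaded = json.loads(path.read_text())
    assert loaded["family"] == "gaussian-identity"
    assert loaded["training_n"] == doc["training_n"]
    assert len(loaded["coefficients"]) > 4
    assert np.asarray(loaded["support_vertices"]).shape[1] == 3
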