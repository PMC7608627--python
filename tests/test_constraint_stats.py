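import numpy as np
import pytest

from soiltau.constraint_stats import (EmergentRegression, ObsEstimate,
                                      constrain_at_level, constrained_pdf,
                                      fit_emergent_regression,
                                      observational_x_distribution,
                                      pseudo_obs_temperatures)
from soiltau.grids_io import Field
from soiltau.reconstruction import DeltaCsTauPoint
from soiltau.spatial_fit import QuadFit


def _points(x, y):
    return [DeltaCsTauPoint("m%d" % i, "s", "2C", float(yi), float(xi), 1500.0)
            for i, (xi, yi) in enumerate(zip(x, y))]


class TestObservationalX:
    def test_two_model_mean_and_sample_sd(self, small_grid):
        """Two pseudo-obs x values {-200, -240}: mean -220, sd 28.28."""
        from soiltau.warming_levels import PseudoObsTemperature

        # engineered so a linear fit gives exactly -200 and -240 PgC
        fit = QuadFit(0.0, -0.1, 4.0, 10, 0.0, (0.0, 30.0))
        rh0 = Field(small_grid, np.full(small_grid.shape, 1.0), "kg m-2 yr-1")
        th = Field(small_grid, np.full(small_grid.shape, 15.0), "degC")
        from soiltau.grids_io import global_total_pgc
        cs0 = global_total_pgc(
            Field(small_grid, np.full(small_grid.shape, np.exp(4.0 - 1.5)),
                  "kg m-2"))
        dts = [np.log(1.0 - 200.0 / cs0) / -0.1, np.log(1.0 - 240.0 / cs0) / -0.1]
        pseudo = [
            PseudoObsTemperature("m%d" % i, "s", th,
                                 th.copy_with(th.values + dt))
            for i, dt in enumerate(dts)
        ]
        est = observational_x_distribution(fit, rh0, pseudo)
        assert est.x_obs_mean == pytest.approx(-220.0, rel=1e-9)
        assert est.x_obs_sd == pytest.approx(np.std([-200, -240], ddof=1), rel=1e-9)
        assert est.x_obs_sd == pytest.approx(28.2843, rel=1e-4)

    def test_identical_anomalies_zero_sd(self, small_grid):
        from soiltau.warming_levels import PseudoObsTemperature

        fit = QuadFit(0.0, -0.1, 4.0, 10, 0.0, (0.0, 30.0))
        rh0 = Field(small_grid, np.full(small_grid.shape, 1.0), "kg m-2 yr-1")
        th = Field(small_grid, np.full(small_grid.shape, 15.0), "degC")
        pseudo = [PseudoObsTemperature("a", "s", th, th.copy_with(th.values + 2)),
                  PseudoObsTemperature("b", "s", th, th.copy_with(th.values + 2))]
        est = observational_x_distribution(fit, rh0, pseudo)
        assert est.x_obs_sd == pytest.approx(0.0, abs=1e-9)
        assert est.per_model_values[0] == pytest.approx(est.x_obs_mean)

    def test_zero_warming_zero_mean(self, small_grid):
        from soiltau.warming_levels import PseudoObsTemperature

        fit = QuadFit(0.0, -0.1, 4.0, 10, 0.0, (0.0, 30.0))
        rh0 = Field(small_grid, np.full(small_grid.shape, 1.0), "kg m-2 yr-1")
        th = Field(small_grid, np.full(small_grid.shape, 15.0), "degC")
        pseudo = [PseudoObsTemperature("a", "s", th, th),
                  PseudoObsTemperature("b", "s", th, th)]
        est = observational_x_distribution(fit, rh0, pseudo)
        assert est.x_obs_mean == pytest.approx(0.0, abs=1e-12)

    def test_single_model_fails(self, small_grid):
        from soiltau.warming_levels import PseudoObsTemperature

        fit = QuadFit(0.0, -0.1, 4.0, 10, 0.0, (0.0, 30.0))
        rh0 = Field(small_grid, np.ones(small_grid.shape), "kg m-2 yr-1")
        th = Field(small_grid, np.full(small_grid.shape, 15.0), "degC")
        with pytest.raises(ValueError):
            observational_x_distribution(
                fit, rh0, [PseudoObsTemperature("a", "s", th, th)])


class TestRegression:
    def test_exact_line(self):
        reg = fit_emergent_regression(_points([0, 1, 2, 3], [1, 3, 5, 7]))
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(1.0)
        assert reg.s2 == pytest.approx(0.0, abs=1e-20)

    def test_identity_line(self):
        reg = fit_emergent_regression(_points([0, 1, 2], [0, 1, 2]))
        assert reg.slope == pytest.approx(1.0)
        assert reg.s2 == pytest.approx(0.0, abs=1e-20)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(14)
        x = rng.normal(-200, 60, 30)
        y = 1.1 * x - 20 + rng.normal(0, 15, 30)
        reg = fit_emergent_regression(_points(x, y))
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.slope == pytest.approx(beta[0], rel=1e-10)
        assert reg.intercept == pytest.approx(beta[1], rel=1e-8)
        resid = y - X @ beta
        assert reg.s2 == pytest.approx(resid @ resid / (30 - 2), rel=1e-10)

    def test_prediction_variance_formula(self):
        rng = np.random.default_rng(15)
        x = rng.normal(0, 1, 20)
        y = 2 * x + rng.normal(0, 0.5, 20)
        reg = fit_emergent_regression(_points(x, y))
        xq = 0.7
        expected = reg.s2 * (1 + 1 / 20 + (xq - x.mean()) ** 2 / (20 * x.var()))
        assert reg.prediction_variance(xq) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_x_fails(self):
        with pytest.raises(ValueError):
            fit_emergent_regression(_points([1, 1, 1], [0, 1, 2]))

    def test_too_few_points_fails(self):
        with pytest.raises(ValueError):
            fit_emergent_regression(_points([0, 1], [0, 1]))


class TestConstrainedPDF:
    def test_exact_linear_map_of_gaussian(self):
        """s2 = 0 and y = 2x: x ~ N(-100, 25^2) maps to y ~ N(-200, 50^2)."""
        pts = _points([-150, -100, -50, 0], [-300, -200, -100, 0])
        reg = fit_emergent_regression(pts)
        obs = ObsEstimate(-100.0, 25.0, [-100.0, -100.0])
        pdf = constrained_pdf(reg, obs, pts)
        assert pdf.constrained_mean == pytest.approx(-200.0, abs=0.1)
        assert pdf.constrained_sd == pytest.approx(50.0, rel=1e-3)

    def test_point_mass_limit(self):
        pts = _points([-150, -100, -50, 0], [-300, -200, -100, 0])
        reg = fit_emergent_regression(pts)
        obs = ObsEstimate(-100.0, 0.0, [-100.0, -100.0])
        pdf = constrained_pdf(reg, obs, pts)
        assert pdf.constrained_mean == pytest.approx(-200.0, abs=1e-6)
        assert pdf.constrained_sd == pytest.approx(0.0, abs=1e-6)

    def test_densities_normalised(self):
        rng = np.random.default_rng(16)
        x = rng.normal(-200, 60, 20)
        y = 1.05 * x - 10 + rng.normal(0, 20, 20)
        pts = _points(x, y)
        reg = fit_emergent_regression(pts)
        obs = ObsEstimate(-220.0, 30.0, [-200.0, -240.0])
        pdf = constrained_pdf(reg, obs, pts)
        assert np.trapezoid(pdf.constrained_pdf, pdf.y_grid) == \
            pytest.approx(1.0, abs=1e-6)
        assert np.trapezoid(pdf.prior_pdf, pdf.y_grid) == \
            pytest.approx(1.0, abs=1e-3)

    def test_moments_match_monte_carlo_oracle(self):
        """Quadrature moments within 1 % of a 10^6-draw simulation of
        x ~ N then y | x ~ N(a + b x, sigma_f^2(x))."""
        rng = np.random.default_rng(17)
        x = rng.normal(-200, 60, 16)
        y = 1.1 * x - 15 + rng.normal(0, 25, 16)
        pts = _points(x, y)
        reg = fit_emergent_regression(pts)
        obs = ObsEstimate(-210.0, 35.0, list(x[:4]))
        pdf = constrained_pdf(reg, obs, pts)

        draws_x = rng.normal(obs.x_obs_mean, obs.x_obs_sd, 1_000_000)
        draws_y = rng.normal(reg.predict(draws_x),
                             np.sqrt(reg.prediction_variance(draws_x)))
        assert pdf.constrained_mean == pytest.approx(
            draws_y.mean(), abs=0.01 * abs(draws_y.mean()))
        assert pdf.constrained_sd == pytest.approx(draws_y.std(), rel=0.01)

    def test_stable_under_grid_refinement(self):
        rng = np.random.default_rng(18)
        x = rng.normal(-200, 60, 20)
        y = x + rng.normal(0, 30, 20)
        pts = _points(x, y)
        reg = fit_emergent_regression(pts)
        obs = ObsEstimate(-190.0, 40.0, [-150.0, -230.0])
        a = constrained_pdf(reg, obs, pts)
        b = constrained_pdf(reg, obs, pts, n_y=4001, n_x=2401)
        assert abs(b.constrained_mean - a.constrained_mean) \
            <= 0.005 * max(abs(a.constrained_mean), a.constrained_sd)
        assert abs(b.constrained_sd - a.constrained_sd) <= 0.005 * a.constrained_sd

    def test_uncertainty_halving_mechanism(self):
        """With a tight emergent correlation and obs spread below the
        ensemble x spread, the constrained sd shrinks below the prior sd."""
        rng = np.random.default_rng(19)
        x = rng.normal(-200, 90, 20)
        y = x + rng.normal(0, 20, 20)      # |r| > 0.9
        pts = _points(x, y)
        reg = fit_emergent_regression(pts)
        obs = ObsEstimate(-220.0, 30.0, [-200.0, -240.0])
        pdf = constrained_pdf(reg, obs, pts)
        assert pdf.constrained_sd < pdf.prior_sd


class TestFullLevelConstraint:
    def test_level_pipeline(self, small_ensemble, obs_bundle):
        res = constrain_at_level(small_ensemble, obs_bundle, 2.0)
        assert res.pdf.constrained_sd < res.pdf.prior_sd
        assert res.pdf.constrained_mean < 0
        assert 0.8 <= res.scatter.r2 <= 1.0
        assert len(res.obs_estimate.per_model_values) == len(res.scatter.points)

    def test_constrained_mean_grows_with_level(self, default_report):
        """|constrained mean| is non-decreasing across 1, 2, 3 degC."""
        means = [abs(default_report["levels"][k]["constrained_mean_pgc"])
                 for k in ("1", "2", "3")]
        assert means == sorted(means)

    def test_pseudo_obs_skip_unreached(self, small_ensemble, obs_bundle):
        pseudo = pseudo_obs_temperatures(small_ensemble, obs_bundle.t_ref, 3.5)
        assert 0 < len(pseudo) < len(small_ensemble)
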