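"""Emergent-constraint statistics for ensemble projections.

Given an ensemble scatter of (x = relationship-derived, y = actual) global
dC_s,tau values and an observation-derived estimate of x, the constrained
posterior of y is the Gaussian integral

    P(y) = int N(y; a + b x, sigma_f^2(x)) N(x; x_obs, s_obs^2) dx

with the ordinary-least-squares line y = a + b x and the standard
prediction variance

    sigma_f^2(x) = s2 * (1 + 1/n + (x - x_mean)^2 / (n * x_var)),

where s2 is the residual variance with n-2 degrees of freedom and x_var the
ensemble (population) variance of x. The prior is a Gaussian fit to the raw
ensemble y values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .grids_io import Field
from .reconstruction import (DeltaCsTauPoint, ScatterResult, build_scatter,
                             estimated_delta_cs_tau)
from .spatial_fit import QuadFit, fit_log_tau_vs_t
from .turnover import TurnoverDiagnostics, reference_mean
from .warming_levels import (LevelNotReachedError, PseudoObsTemperature,
                             anomaly_to_obs, slice_at_level)


@dataclass
class EmergentRegression:
    """OLS fit of actual (y) on estimated (x) dC_s,tau across an ensemble."""

    slope: float
    intercept: float
    n: int
    s2: float                  # residual variance, PgC^2, dof = n - 2
    x_mean: float
    x_var: float               # population variance of x

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def prediction_variance(self, x):
        x = np.asarray(x, dtype=float)
        return self.s2 * (1.0 + 1.0 / self.n
                          + (x - self.x_mean) ** 2 / (self.n * self.x_var))


@dataclass
class ObsEstimate:
    """Observation-derived x estimate: one value per model warming pattern."""

    x_obs_mean: float
    x_obs_sd: float            # sample sd over models
    per_model_values: list[float]


@dataclass
class ConstraintPDF:
    """Prior and constrained probability densities of dC_s,tau (PgC)."""

    y_grid: np.ndarray
    prior_pdf: np.ndarray
    constrained_pdf: np.ndarray
    prior_mean: float
    prior_sd: float
    constrained_mean: float
    constrained_sd: float


@dataclass
class LevelConstraint:
    """Full constraint result at one global warming level."""

    delta_t: float
    scatter: ScatterResult
    regression: EmergentRegression
    obs_estimate: ObsEstimate
    pdf: ConstraintPDF


def observational_x_distribution(
    obs_fit: QuadFit, obs_rh0: Field,
    pseudo_obs: Sequence[PseudoObsTemperature],
) -> ObsEstimate:
    """Observation-derived dC_s,tau for each model's warming pattern.

    Each model's pseudo-observational (historical, future) temperature pair
    is pushed through the observational fit and R_h0; the mean and sample
    standard deviation over models form the constraint's x distribution.
    """
    if len(pseudo_obs) < 2:
        raise ValueError("observational_x_distribution: need >= 2 pseudo-obs pairs")
    xs = [
        estimated_delta_cs_tau(obs_fit, obs_rh0, p.t_obs_hist, p.t_obs_future).pgc
        for p in pseudo_obs
    ]
    arr = np.asarray(xs)
    return ObsEstimate(
        x_obs_mean=float(arr.mean()),
        x_obs_sd=float(arr.std(ddof=1)),
        per_model_values=list(map(float, xs)),
    )


def fit_emergent_regression(points: Sequence[DeltaCsTauPoint]) -> EmergentRegression:
    """Ordinary least squares of actual on estimated dC_s,tau."""
    n = len(points)
    if n < 3:
        raise ValueError(f"fit_emergent_regression: need >= 3 points, have {n}")
    x = np.array([p.estimated_pgc for p in points])
    y = np.array([p.actual_pgc for p in points])
    x_var = float(x.var())          # population variance, matches n * x_var = SSx
    if x_var == 0:
        raise ValueError("fit_emergent_regression: degenerate x spread")
    slope, intercept = np.polyfit(x, y, deg=1)
    resid = y - (intercept + slope * x)
    s2 = float(np.sum(resid**2) / (n - 2))
    return EmergentRegression(slope=float(slope), intercept=float(intercept),
                              n=n, s2=s2, x_mean=float(x.mean()), x_var=x_var)


def _moments(grid: np.ndarray, pdf: np.ndarray) -> tuple[float, float]:
    mass = np.trapezoid(pdf, grid)
    mean = np.trapezoid(grid * pdf, grid) / mass
    var = np.trapezoid((grid - mean) ** 2 * pdf, grid) / mass
    return float(mean), float(np.sqrt(var))


def constrained_pdf(reg: EmergentRegression, obs: ObsEstimate,
                    points: Sequence[DeltaCsTauPoint],
                    n_y: int = 2001, n_x: int = 1201,
                    span_sd: float = 6.0) -> ConstraintPDF:
    """Constrained posterior of dC_s,tau by numerical Gaussian quadrature.

    The y grid spans both the prior and the constrained density by at least
    ``span_sd`` combined standard deviations; a normalisation loss above
    1e-3 raises with advice to widen the grid.
    """
    y_ens = np.array([p.actual_pgc for p in points])
    prior_mean, prior_sd = float(y_ens.mean()), float(y_ens.std(ddof=1))

    center = reg.predict(obs.x_obs_mean)
    spread2 = (reg.slope**2 * obs.x_obs_sd**2
               + reg.prediction_variance(obs.x_obs_mean))
    spread = float(np.sqrt(spread2))
    if spread <= 1e-9 * max(abs(center), prior_sd, 1.0):
        # degenerate limit: point mass at the regression prediction
        y_grid = np.linspace(center - max(5 * prior_sd, 1.0),
                             center + max(5 * prior_sd, 1.0), n_y)
        cpdf = np.zeros_like(y_grid)
        i = int(np.argmin(np.abs(y_grid - center)))
        cpdf[i] = 1.0 / np.diff(y_grid).mean()
        prior = _gauss(y_grid, prior_mean, prior_sd)
        return ConstraintPDF(y_grid, prior, cpdf, prior_mean, prior_sd,
                             float(center), 0.0)

    lo = min(center - span_sd * spread, prior_mean - span_sd * prior_sd)
    hi = max(center + span_sd * spread, prior_mean + span_sd * prior_sd)
    y_grid = np.linspace(lo, hi, n_y)

    if reg.s2 == 0.0:
        # exact emergent relation: y is a linear map of the Gaussian x
        cpdf = _gauss(y_grid, float(center), abs(reg.slope) * obs.x_obs_sd)
    elif obs.x_obs_sd > 0:
        x_grid = np.linspace(obs.x_obs_mean - 8 * obs.x_obs_sd,
                             obs.x_obs_mean + 8 * obs.x_obs_sd, n_x)
        px = _gauss(x_grid, obs.x_obs_mean, obs.x_obs_sd)
        dy = (hi - lo) / (n_y - 1)
        mu_y = reg.predict(x_grid)                       # (n_x,)
        # floor the conditional sd at twice the y spacing so near-degenerate
        # residual variance stays resolvable on the quadrature grid
        sig_y = np.maximum(np.sqrt(reg.prediction_variance(x_grid)), 2 * dy)
        cond = _gauss(y_grid[:, None], mu_y[None, :], sig_y[None, :])
        cpdf = np.trapezoid(cond * px[None, :], x_grid, axis=1)
    else:
        dy = (hi - lo) / (n_y - 1)
        sd = max(float(np.sqrt(reg.prediction_variance(obs.x_obs_mean))), 2 * dy)
        cpdf = _gauss(y_grid, float(center), sd)

    mass = float(np.trapezoid(cpdf, y_grid))
    if abs(mass - 1.0) > 1e-3:
        raise ValueError(
            f"constrained_pdf: normalisation loss {abs(mass - 1.0):.2e} > 1e-3; "
            "widen the y grid (increase span_sd) or refine it (n_y, n_x)"
        )
    cpdf = cpdf / mass
    c_mean, c_sd = _moments(y_grid, cpdf)
    prior = _gauss(y_grid, prior_mean, prior_sd)
    return ConstraintPDF(y_grid, prior, cpdf, prior_mean, prior_sd, c_mean, c_sd)


def _gauss(x, mu, sd):
    sd = np.asarray(sd, dtype=float)
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def pseudo_obs_temperatures(ensemble, obs_t_ref: Field, delta_t: float,
                            regrid_method: str = "bilinear",
                            ) -> list[PseudoObsTemperature]:
    """Model warming anomalies at one level mapped onto the observational
    temperature field; runs that never reach the level are skipped."""
    out = []
    for run in ensemble:
        try:
            slc = slice_at_level(run, delta_t)
        except LevelNotReachedError:
            continue
        ref_t = reference_mean(run.tas, run.reference_period)
        out.append(anomaly_to_obs(slc, ref_t, obs_t_ref,
                                  model_id=run.model_id,
                                  scenario_id=run.scenario_id,
                                  method=regrid_method))
    return out


def constrain_at_level(ensemble, obs: TurnoverDiagnostics, delta_t: float,
                       rh_units: str = "per_year",
                       regrid_method: str = "bilinear") -> LevelConstraint:
    """Run the full constraint pipeline at one warming level."""
    scatter = build_scatter(ensemble, delta_t, rh_units=rh_units)
    if len(scatter.points) < 3:
        raise ValueError(
            f"constrain_at_level: only {len(scatter.points)} runs reach "
            f"{delta_t:g} degC; need >= 3"
        )
    obs_fit = fit_log_tau_vs_t(obs.tau, obs.t_ref)
    pseudo = pseudo_obs_temperatures(ensemble, obs.t_ref, delta_t,
                                     regrid_method=regrid_method)
    obs_est = observational_x_distribution(obs_fit, obs.rh0, pseudo)
    reg = fit_emergent_regression(scatter.points)
    pdf = constrained_pdf(reg, obs_est, scatter.points)
    return LevelConstraint(delta_t=delta_t, scatter=scatter, regression=reg,
                           obs_estimate=obs_est, pdf=pdf)


def constrain_at_levels(ensemble, obs: TurnoverDiagnostics,
                        levels: Sequence[float],
                        rh_units: str = "per_year",
                        regrid_method: str = "bilinear",
                        ) -> dict[float, LevelConstraint]:
    """Per-level constraint results (e.g. levels = [1.0, 2.0, 3.0])."""
    return {
        float(lvl): constrain_at_level(ensemble, obs, float(lvl),
                                       rh_units=rh_units,
                                       regrid_method=regrid_method)
        for lvl in levels
    }
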