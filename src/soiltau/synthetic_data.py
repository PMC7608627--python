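"""Synthetic pseudo-ESM ensemble and pseudo-observations with known truth.

Each pseudo-model owns a quadratic ln(tau_s)-temperature relation p_true and
obeys it by construction: per cell, ln tau_s = p_true(T) + eta with a frozen
cell-level residual eta (soil properties, not weather), R_h rises
exponentially with temperature, and C_s = tau_s * R_h. Warming follows a
scenario ramp with polar amplification and interannual variability of the
global mean. Both the cell residual and the multiplicative R_h noise are
mean-one in linear space (lognormal with mu = -sigma^2/2), so the expected
stock at a given temperature is exactly exp(p_true(T)) * R_h and the
analytic per-model truth needs no noise correction.

The default ensemble has sixteen pseudo-models spanning slope, intercept,
respiration scale, climate sensitivity and polar amplification, run under
three scenario ramps; an out-of-ensemble truth relation generates the
pseudo-observations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np

from .grids_io import (AnnualSeries, Field, Grid, ModelRun, area_weighted_mean,
                       cell_areas)
from .turnover import RH_FLOOR, TurnoverDiagnostics, compute_tau

#: Central spatial relation: tau ~ 7 yr at 25 degC, ~150 yr at -10 degC.
CENTRAL_COEFFS = (2.62e-5, -0.0879, 4.128)


@dataclass(frozen=True)
class Scenario:
    """Linear warming ramp from start_year to end_year (degC at end, before
    per-model climate-sensitivity scaling)."""

    scenario_id: str
    end_anomaly: float
    start_year: int = 2005
    end_year: int = 2100

    def ramp(self, years: np.ndarray) -> np.ndarray:
        frac = np.clip((np.asarray(years, dtype=float) - self.start_year)
                       / (self.end_year - self.start_year), 0.0, 1.0)
        return self.end_anomaly * frac


DEFAULT_SCENARIOS = (
    Scenario("low", 1.4),
    Scenario("mid", 2.8),
    Scenario("high", 5.0),
)


@dataclass(frozen=True)
class PseudoModelConfig:
    """Generating parameters of one pseudo-model (reproducible per seed)."""

    model_id: str
    true_coeffs: tuple[float, float, float] = CENTRAL_COEFFS
    scatter_sd: float = 0.6        # ln-year cell scatter at fixed T
    rh_scale: float = 0.25         # kg C m-2 yr-1 at 0 degC
    polar_amp: float = 1.0         # extra warming fraction poleward of 40 deg
    climate_sens_scale: float = 1.0
    seed: int = 0
    t_noise_sd: float = 0.15       # interannual sd of global-mean T, degC
    rh_noise_sd: float = 0.3       # lognormal sigma of frozen R_h noise

    def p_true(self, t):
        c2, c1, c0 = self.true_coeffs
        t = np.asarray(t, dtype=float)
        return c2 * t**2 + c1 * t + c0


@dataclass
class PseudoEnsembleTruth:
    """Analytic per-model dC_s,tau truth (PgC) at each warming level."""

    levels: tuple[float, ...]
    per_model: dict[str, dict[float, float]]
    obs_truth_model_id: str = "truth"
    obs_truth: dict[float, float] = dc_field(default_factory=dict)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, stream)])


def make_baseline_climate(grid: Grid, seed: int) -> Field:
    """Present-day temperature climatology: T = 28 - 0.6|lat| + N(0, 2),
    clipped to [-25, 32] degC; deterministic per seed.

    The 0.6 degC per degree latitude gradient reproduces the real
    equator-to-pole contrast (~28 degC tropics to ~-25 degC poles), so cold
    regions with century-scale turnover exist as they do in observations.
    """
    lat = grid.lat_centers[:, None] * np.ones((1, grid.lon_centers.size))
    base = 28.0 - 0.6 * np.abs(lat)
    noise = _rng(seed, 0).normal(0.0, 2.0, size=grid.shape)
    return Field(grid, np.clip(base + noise, -25.0, 32.0), "degC")


def land_mask(grid: Grid, seed: int = 7, land_fraction: float = 0.3) -> np.ndarray:
    """Smooth continental blob mask with ~land_fraction of cells valid.

    The blob pattern is a continuous function of (lat, lon), so masks drawn
    on different grids describe the same pseudo-continents.
    """
    rng = np.random.default_rng([int(seed), 99])
    n_blobs = 8
    lat0 = np.rad2deg(np.arcsin(rng.uniform(-1, 1, n_blobs)))
    lon0 = rng.uniform(0, 360, n_blobs)
    width = rng.uniform(15.0, 40.0, n_blobs)
    amp = rng.uniform(0.5, 1.5, n_blobs)
    glat = grid.lat_centers[:, None]
    glon = np.mod(grid.lon_centers[None, :], 360.0)
    fieldv = np.zeros(grid.shape)
    for k in range(n_blobs):
        dlon = np.abs(glon - lon0[k])
        dlon = np.minimum(dlon, 360.0 - dlon)
        d2 = ((glat - lat0[k]) / width[k]) ** 2 + (dlon / width[k]) ** 2
        fieldv += amp[k] * np.exp(-d2)
    thresh = np.quantile(fieldv, 1.0 - land_fraction)
    return fieldv >= thresh


def warming_pattern(grid: Grid, polar_amp: float) -> np.ndarray:
    """Unnormalised polar-amplification pattern
    1 + polar_amp * max(0, (|lat| - 40)/50)."""
    lat = np.abs(grid.lat_centers)[:, None] * np.ones((1, grid.lon_centers.size))
    return 1.0 + polar_amp * np.maximum(0.0, (lat - 40.0) / 50.0)


def _pattern_global_mean(grid: Grid, polar_amp: float) -> float:
    pat = warming_pattern(grid, polar_amp)
    w = cell_areas(grid)
    return float(np.sum(pat * w) / w.sum())


def _frozen_noises(config: PseudoModelConfig, grid: Grid
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Cell-level residual exp(eta) and R_h noise factor, both mean-one."""
    eta = _rng(config.seed, 1).normal(
        -0.5 * config.scatter_sd**2, config.scatter_sd, size=grid.shape)
    delta = np.exp(_rng(config.seed, 2).normal(
        -0.5 * config.rh_noise_sd**2, config.rh_noise_sd, size=grid.shape))
    return np.exp(eta), delta


def make_pseudo_model(config: PseudoModelConfig, grid: Grid,
                      scenario: Scenario,
                      years: tuple[int, int] = (1995, 2100),
                      land_seed: int = 7,
                      rh_floor: float = RH_FLOOR) -> ModelRun:
    """Generate one pseudo-model run obeying its own spatial relation.

    Per year, T = climatology + sensitivity * ramp * pattern + global noise;
    tau tracks exp(p_true(T) + eta) with the frozen cell residual, R_h =
    rh_scale * exp(0.05 T) * delta (floored), and C_s = tau * R_h.
    """
    yr = np.arange(years[0], years[1] + 1)
    t0 = make_baseline_climate(grid, config.seed).values
    pat = warming_pattern(grid, config.polar_amp)
    ramp = config.climate_sens_scale * scenario.ramp(yr)
    scen_stream = zlib.crc32(scenario.scenario_id.encode()) % 1_000_000
    gnoise = _rng(config.seed, 3, scen_stream).normal(
        0.0, config.t_noise_sd, size=yr.size)
    exp_eta, delta = _frozen_noises(config, grid)

    tas = t0[None, :, :] + ramp[:, None, None] * pat[None, :, :] \
        + gnoise[:, None, None]
    tau = np.exp(config.p_true(tas)) * exp_eta[None, :, :]
    rh = np.maximum(config.rh_scale * np.exp(0.05 * tas) * delta[None, :, :],
                    rh_floor)
    cs = tau * rh

    land = land_mask(grid, seed=land_seed)
    land3 = np.broadcast_to(land, cs.shape)
    return ModelRun(
        model_id=config.model_id,
        scenario_id=scenario.scenario_id,
        cs=AnnualSeries(grid, yr, cs, "kg m-2", land3.copy()),
        rh=AnnualSeries(grid, yr, rh, "kg m-2 yr-1", land3.copy()),
        tas=AnnualSeries(grid, yr, tas, "degC"),
        reference_period=(1995, 2005),
    )


def make_pseudo_obs(truth_config: PseudoModelConfig, grid: Grid,
                    seed: int | None = None,
                    obs_noise_sd: float = 0.10,
                    land_seed: int = 7,
                    rh_floor: float = RH_FLOOR) -> TurnoverDiagnostics:
    """Pseudo-observational bundle from an out-of-ensemble truth relation.

    The same generative recipe as the pseudo-models at zero warming, with
    multiplicative observational noise (default sd 10 %) on C_s and R_h and
    an ocean/ice mask (~30 % of cells land). Returned as reference-decade
    turnover diagnostics (the observational period, 2001-2010).
    """
    if seed is None:
        seed = truth_config.seed
    t0 = make_baseline_climate(grid, truth_config.seed)
    exp_eta, delta = _frozen_noises(truth_config, grid)
    tau_true = np.exp(truth_config.p_true(t0.values)) * exp_eta
    rh_true = np.maximum(truth_config.rh_scale * np.exp(0.05 * t0.values) * delta,
                         rh_floor)
    cs_true = tau_true * rh_true

    rng = _rng(seed, 4)
    cs_obs = cs_true * (1.0 + rng.normal(0.0, obs_noise_sd, size=grid.shape))
    rh_obs = rh_true * (1.0 + rng.normal(0.0, obs_noise_sd, size=grid.shape))

    land = land_mask(grid, seed=land_seed)
    cs0 = Field(grid, cs_obs, "kg m-2", land)
    rh0 = Field(grid, rh_obs, "kg m-2 yr-1", land)
    tau = compute_tau(cs0, rh0, rh_units="per_year", rh_floor=rh_floor)
    return TurnoverDiagnostics(tau=tau, cs0=cs0, rh0=rh0,
                               t_ref=t0.copy_with(t0.values),
                               reference_period=(2001, 2010))


def analytic_truth(config: PseudoModelConfig, grid: Grid, level: float,
                   land_seed: int = 7) -> float:
    """Exact expected dC_s,tau (PgC) of a pseudo-model at a warming level.

    Evaluates R_h0 * (exp(p_true(T + dT_pattern)) - exp(p_true(T))) cell-wise
    with the noise-free generating fields (both noises are mean-one, so this
    is the exact expectation) and integrates over land. The local warming is
    the polar-amplified pattern scaled so its area-weighted global mean
    equals ``level``. Independent of the pipeline code path.
    """
    t0 = make_baseline_climate(grid, config.seed).values
    pat = warming_pattern(grid, config.polar_amp)
    dt = level * pat / _pattern_global_mean(grid, config.polar_amp)
    rh0 = config.rh_scale * np.exp(0.05 * t0)
    dtau = np.exp(config.p_true(t0 + dt)) - np.exp(config.p_true(t0))
    land = land_mask(grid, seed=land_seed)
    areas = cell_areas(grid)
    return float(np.sum(np.where(land, rh0 * dtau * areas, 0.0)) / 1e12)


# ---------------------------------------------------------------------------
# default ensemble


def default_ensemble_configs(seed: int = 0, n_models: int = 16
                             ) -> list[PseudoModelConfig]:
    """Sixteen pseudo-models (the CMIP5+CMIP6 ensemble size) spanning
    coefficient, respiration and climate-pattern diversity."""
    rng = np.random.default_rng([int(seed), 10])
    c2_0, c1_0, c0_0 = CENTRAL_COEFFS
    configs = []
    for i in range(n_models):
        configs.append(PseudoModelConfig(
            model_id=f"pseudo-{i:02d}",
            true_coeffs=(
                float(c2_0 + rng.normal(0.0, 8e-6)),
                float(c1_0 + rng.normal(0.0, 0.015)),
                float(c0_0 + rng.normal(0.0, 0.25)),
            ),
            rh_scale=float(rng.uniform(0.15, 0.35)),
            polar_amp=float(rng.uniform(0.5, 1.5)),
            climate_sens_scale=float(rng.uniform(0.8, 1.3)),
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return configs


def default_truth_config(seed: int = 0) -> PseudoModelConfig:
    """Truth relation behind the pseudo-observations.

    Uses the central coefficients — the observed-world turnover structure
    (~7 yr warm tropics, century-scale cold regions) — which no ensemble
    member matches exactly, so the observations stay out of ensemble while
    looking like the real maps the analysis ingests.
    """
    rng = np.random.default_rng([int(seed), 11])
    return PseudoModelConfig(
        model_id="truth",
        true_coeffs=CENTRAL_COEFFS,
        rh_scale=float(rng.uniform(0.15, 0.35)),
        polar_amp=float(rng.uniform(0.5, 1.5)),
        climate_sens_scale=float(rng.uniform(0.8, 1.3)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_ensemble(configs: list[PseudoModelConfig], grid: Grid,
                  scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS,
                  years: tuple[int, int] = (1995, 2100),
                  land_seed: int = 7) -> list[ModelRun]:
    """One run per model x scenario."""
    return [
        make_pseudo_model(cfg, grid, scen, years=years, land_seed=land_seed)
        for cfg in configs for scen in scenarios
    ]


def ensemble_truth(configs: list[PseudoModelConfig],
                   truth_config: PseudoModelConfig, grid: Grid,
                   levels: tuple[float, ...] = (1.0, 2.0, 3.0),
                   land_seed: int = 7) -> PseudoEnsembleTruth:
    """Analytic truths for every model and the observational truth relation."""
    per_model = {
        cfg.model_id: {lvl: analytic_truth(cfg, grid, lvl, land_seed=land_seed)
                       for lvl in levels}
        for cfg in configs
    }
    obs_truth = {lvl: analytic_truth(truth_config, grid, lvl, land_seed=land_seed)
                 for lvl in levels}
    return PseudoEnsembleTruth(levels=tuple(levels), per_model=per_model,
                               obs_truth_model_id=truth_config.model_id,
                               obs_truth=obs_truth)
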