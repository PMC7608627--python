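"""Global-warming-level extraction and anomaly mapping onto observations.

A warming level (e.g. 2 degC) is reached in the first year whose 5-year
rolling mean of global-mean temperature exceeds the baseline-decade mean by
that amount. The spatial temperature field is then averaged over an 11-year
window centred on that year, and the model's warming anomaly (future minus
reference-decade field) is added to the observational temperature
climatology to give a bias-free pseudo-observational future temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_io import Field, Grid, ModelRun, area_weighted_mean, regrid


class LevelNotReachedError(RuntimeError):
    """The requested global warming level is never reached within the run."""


@dataclass
class WarmingSlice:
    """Decadal-mean temperature field of a run at a prescribed warming level."""

    delta_t_target: float      # degC of global-mean warming
    central_year: int
    t_future: Field            # window-mean temperature, degC
    window: tuple[int, int]    # inclusive (first, last) year actually used
    truncated: bool = False    # True if the window hit the end of the run


@dataclass
class PseudoObsTemperature:
    """Observational climatology plus one model's warming anomaly."""

    model_id: str
    scenario_id: str
    t_obs_hist: Field
    t_obs_future: Field


def global_mean_t_series(run: ModelRun) -> tuple[np.ndarray, np.ndarray]:
    """(years, area-weighted global-mean temperature per year, degC)."""
    tas = run.tas
    out = np.empty(tas.years.size)
    for i in range(tas.years.size):
        out[i] = area_weighted_mean(Field(tas.grid, tas.values[i], tas.units,
                                          tas.mask[i]))
    return tas.years.copy(), out


def rolling_mean(series: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered rolling mean; endpoints average the available truncated window."""
    if width % 2 == 0:
        raise ValueError("rolling_mean width must be odd")
    s = np.asarray(series, dtype=float)
    if width > s.size:
        raise ValueError("rolling_mean width exceeds series length")
    half = width // 2
    out = np.empty_like(s)
    for i in range(s.size):
        lo, hi = max(0, i - half), min(s.size, i + half + 1)
        out[i] = s[lo:hi].mean()
    return out


def find_warming_year(run: ModelRun, delta_t: float,
                      baseline: tuple[int, int] | None = None,
                      smooth_width: int = 5) -> int:
    """First year whose smoothed global-mean warming anomaly reaches delta_t.

    The anomaly is the 5-year rolling mean of global-mean temperature minus
    the baseline-period mean of the unsmoothed series. Raises
    :class:`LevelNotReachedError` if the level is never reached, so callers
    can skip that model x scenario.
    """
    if baseline is None:
        baseline = run.reference_period
    years, gmt = global_mean_t_series(run)
    in_base = (years >= baseline[0]) & (years <= baseline[1])
    if not in_base.any():
        raise ValueError(f"baseline {baseline} outside run coverage")
    anomaly = rolling_mean(gmt, smooth_width) - gmt[in_base].mean()
    # 1e-9 degC slack absorbs floating-point dust in exact-crossing cases
    hits = np.nonzero(anomaly >= delta_t - 1e-9)[0]
    if hits.size == 0:
        raise LevelNotReachedError(
            f"{run.model_id}/{run.scenario_id}: {delta_t:+.2f} degC never reached "
            f"(max anomaly {anomaly.max():+.2f} degC)"
        )
    return int(years[hits[0]])


def extract_slice(run: ModelRun, year: int, delta_t: float,
                  half_window: int = 5) -> WarmingSlice:
    """11-year (central year -5..+5, inclusive) mean temperature field.

    The window is truncated, and flagged, where it runs past the end of the
    run's coverage.
    """
    tas = run.tas
    first = max(int(tas.years[0]), year - half_window)
    last = min(int(tas.years[-1]), year + half_window)
    truncated = (first, last) != (year - half_window, year + half_window)
    sel = (tas.years >= first) & (tas.years <= last)
    mask = tas.mask[sel].all(axis=0)
    vals = np.where(mask, tas.values[sel].mean(axis=0), np.nan)
    return WarmingSlice(
        delta_t_target=delta_t, central_year=year,
        t_future=Field(tas.grid, vals, tas.units, mask),
        window=(first, last), truncated=truncated,
    )


def slice_at_level(run: ModelRun, delta_t: float,
                   baseline: tuple[int, int] | None = None) -> WarmingSlice:
    """Convenience: find the crossing year and extract its decadal slice."""
    year = find_warming_year(run, delta_t, baseline=baseline)
    return extract_slice(run, year, delta_t)


def anomaly_to_obs(slc: WarmingSlice, run_reference_t: Field, obs_t: Field,
                   model_id: str = "", scenario_id: str = "",
                   method: str = "bilinear") -> PseudoObsTemperature:
    """Add a model's warming anomaly to the observational temperature field.

    anomaly = t_future - reference-decade temperature, regridded to the
    observational grid and added to obs_t; the historical pseudo-observation
    is obs_t itself, so model mean-state bias cancels.
    """
    anom_native = Field(
        slc.t_future.grid,
        slc.t_future.values - run_reference_t.values,
        "degC",
        slc.t_future.mask & run_reference_t.mask,
    )
    if anom_native.grid == obs_t.grid:
        anom = anom_native
    else:
        anom = regrid(anom_native, obs_t.grid, method=method)
    mask = anom.mask & obs_t.mask
    future = np.where(mask, obs_t.values + anom.values, np.nan)
    return PseudoObsTemperature(
        model_id=model_id, scenario_id=scenario_id,
        t_obs_hist=obs_t,
        t_obs_future=Field(obs_t.grid, future, "degC", mask),
    )
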