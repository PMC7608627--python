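"""Effective soil-carbon turnover time diagnostics.

The effective turnover time is the apparent whole-pool residence time
tau_s = C_s / R_h (years), diagnosed per grid cell from the soil carbon
stock and the heterotrophic respiration flux. Reference-decade means of
C_s, R_h and temperature feed the spatial-fit and reconstruction stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_io import AnnualSeries, Field, GridError, ModelRun

SECONDS_PER_YEAR = 86400 * 365

#: Cells respiring less than this (kg C m-2 yr-1) — deserts, ice — give
#: unbounded turnover times and are masked.
RH_FLOOR = 1e-4


@dataclass
class TurnoverDiagnostics:
    """Reference-decade turnover state of one run or observation bundle:
    tau (years), cs0 (kg C m-2), rh0 (kg C m-2 yr-1), t_ref (degC)."""

    tau: Field
    cs0: Field
    rh0: Field
    t_ref: Field
    reference_period: tuple[int, int]


def reference_mean(series: AnnualSeries, period: tuple[int, int]) -> Field:
    """Unweighted mean of the annual fields over an inclusive year range.

    The result is masked wherever any contributing year is masked.
    """
    sub = series.subset(*period)
    if sub.years[0] != period[0] or sub.years[-1] != period[1]:
        raise ValueError(
            f"period {period} not fully covered by series "
            f"({series.years[0]}..{series.years[-1]})"
        )
    mask = sub.mask.all(axis=0)
    vals = np.where(mask, sub.values.mean(axis=0), np.nan)
    return Field(series.grid, vals, series.units, mask)


def rh_to_per_year(rh: Field) -> Field:
    """Convert a respiration flux field to kg C m-2 yr-1 if it is per-second."""
    u = rh.units.lower()
    if "s-1" in u or "/s" in u or "s^-1" in u:
        return rh.copy_with(rh.values * SECONDS_PER_YEAR, units="kg m-2 yr-1")
    return rh.copy_with(rh.values, units="kg m-2 yr-1")


def compute_tau(cs: Field, rh: Field, rh_units: str = "per_year",
                rh_floor: float = RH_FLOOR) -> Field:
    """Effective turnover time tau_s = C_s / R_h, in years.

    Per-second fluxes are converted with tau_s = C_s / (R_h * 86400 * 365).
    Cells with R_h below ``rh_floor`` (in kg C m-2 yr-1) or C_s <= 0 are
    masked rather than raising.
    """
    if cs.grid != rh.grid:
        raise GridError("compute_tau: cs and rh on different grids")
    if rh_units == "per_second":
        rh_yr = rh.values * SECONDS_PER_YEAR
    elif rh_units == "per_year":
        rh_yr = rh.values
    else:
        raise ValueError(f"rh_units must be per_second or per_year, got {rh_units!r}")
    mask = cs.mask & rh.mask & (rh_yr > rh_floor) & (cs.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(mask, cs.values / rh_yr, np.nan)
    return Field(cs.grid, tau, "yr", mask)


def annual_tau_series(run: ModelRun, rh_units: str = "per_year",
                      rh_floor: float = RH_FLOOR) -> AnnualSeries:
    """Per-year turnover-time fields for a run; each year keeps its own mask."""
    cs, rh = run.cs, run.rh
    if not np.array_equal(cs.years, rh.years):
        raise ValueError("annual_tau_series: cs and rh year coverage differ")
    nyears = cs.years.size
    vals = np.empty((nyears, *cs.grid.shape))
    msk = np.empty((nyears, *cs.grid.shape), dtype=bool)
    for i in range(nyears):
        f = compute_tau(
            Field(cs.grid, cs.values[i], cs.units, cs.mask[i]),
            Field(rh.grid, rh.values[i], rh.units, rh.mask[i]),
            rh_units=rh_units, rh_floor=rh_floor,
        )
        vals[i], msk[i] = f.values, f.mask
    return AnnualSeries(cs.grid, cs.years, vals, "yr", msk)


def diagnose(run: ModelRun, rh_units: str = "per_year",
             rh_floor: float = RH_FLOOR) -> TurnoverDiagnostics:
    """Reference-decade turnover diagnostics for one run.

    tau is the reference-period mean of C_s divided by the reference-period
    mean of R_h (equivalently the turnover time of the time-averaged state);
    rh0 is returned in kg C m-2 yr-1 whatever the input flux units.
    """
    period = run.reference_period
    cs0 = reference_mean(run.cs, period)
    rh0 = reference_mean(run.rh, period)
    t_ref = reference_mean(run.tas, period)
    tau = compute_tau(cs0, rh0, rh_units=rh_units, rh_floor=rh_floor)
    if rh_units == "per_second":
        rh0 = rh0.copy_with(rh0.values * SECONDS_PER_YEAR, units="kg m-2 yr-1")
    return TurnoverDiagnostics(tau=tau, cs0=cs0, rh0=rh0, t_ref=t_ref,
                               reference_period=period)
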