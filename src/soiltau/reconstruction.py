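"""Actual and relationship-derived turnover-driven soil-carbon change.

The turnover component of soil-carbon change is dC_s,tau = R_h0 * dtau_s,
with R_h0 frozen at its reference-decade mean. The "actual" value diagnoses
dtau_s from a model's own evolving C_s and R_h; the "estimated" value
replaces the model's temporal response with its spatial ln(tau)-temperature
fit, dtau_s = exp(p(T_future)) - exp(p(T_hist)). Agreement between the two
across an ensemble is the proof of concept that spatial variability predicts
the temporal response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids_io import Field, GridError, ModelRun, global_total_pgc
from .spatial_fit import QuadFit, extrapolation_fraction, fit_log_tau_vs_t
from .turnover import RH_FLOOR, annual_tau_series, diagnose
from .warming_levels import LevelNotReachedError, WarmingSlice, slice_at_level


@dataclass
class DeltaCsTauPoint:
    """One model x scenario point of the actual-vs-estimated comparison."""

    model_id: str
    scenario_id: str
    label: str                 # warming level ("2.0C") or horizon ("2090-2100")
    actual_pgc: float          # y-axis: model-diagnosed dC_s,tau
    estimated_pgc: float       # x-axis: relationship-derived dC_s,tau
    cs0_pgc: float             # global initial soil-carbon stock


@dataclass
class EstimatedDelta:
    """Relationship-derived dC_s,tau with its extrapolation diagnostic."""

    pgc: float
    extrapolation_fraction: float
    delta_field: Field         # kg C m-2 per cell


@dataclass
class ScatterResult:
    points: list[DeltaCsTauPoint]
    r2: float | None           # undefined (None) for < 2 points
    skipped: list[str]         # runs that never reach the level


def _window_mean_tau(run: ModelRun, window: tuple[int, int], rh_units: str,
                     rh_floor: float) -> Field:
    tau = annual_tau_series(run, rh_units=rh_units, rh_floor=rh_floor)
    sub = tau.subset(*window)
    mask = sub.mask.all(axis=0)
    vals = np.where(mask, sub.values.mean(axis=0), np.nan)
    return Field(tau.grid, vals, "yr", mask)


def actual_delta_cs_tau(run: ModelRun, slc: WarmingSlice,
                        rh_units: str = "per_year", rh_floor: float = RH_FLOOR,
                        tau_from_mean_state: bool = False) -> float:
    """Model-diagnosed global dC_s,tau (PgC) between the reference decade and
    a warming slice.

    Per-cell annual tau_s values are averaged over each window (set
    ``tau_from_mean_state`` to instead divide window-mean C_s by window-mean
    R_h, for sensitivity checks), then dC = R_h0 * (tau_f - tau_h) is
    integrated area-weighted over valid cells.
    """
    diag = diagnose(run, rh_units=rh_units, rh_floor=rh_floor)
    if tau_from_mean_state:
        from .turnover import compute_tau, reference_mean
        tau_h = diag.tau
        cs_f = reference_mean(run.cs, slc.window)
        rh_f = reference_mean(run.rh, slc.window)
        tau_f = compute_tau(cs_f, rh_f, rh_units=rh_units, rh_floor=rh_floor)
    else:
        tau_h = _window_mean_tau(run, run.reference_period, rh_units, rh_floor)
        tau_f = _window_mean_tau(run, slc.window, rh_units, rh_floor)
    mask = tau_h.mask & tau_f.mask & diag.rh0.mask
    delta = np.where(mask, diag.rh0.values * (tau_f.values - tau_h.values), np.nan)
    return global_total_pgc(Field(run.cs.grid, delta, "kg m-2", mask))


def estimated_delta_cs_tau(fit: QuadFit, rh0: Field, t_hist: Field,
                           t_future: Field) -> EstimatedDelta:
    """Relationship-derived global dC_s,tau (PgC).

    dtau = exp(p(T_future)) - exp(p(T_hist)) per cell on jointly valid cells,
    dC = rh0 * dtau, integrated to a global total. rh0 must be in
    kg C m-2 yr-1. The fraction of cells whose future temperature falls
    outside the fitted range is reported alongside.
    """
    if not (rh0.grid == t_hist.grid == t_future.grid):
        raise GridError("estimated_delta_cs_tau: fields on different grids")
    mask = rh0.mask & t_hist.mask & t_future.mask
    dtau = np.exp(fit(t_future.values)) - np.exp(fit(t_hist.values))
    delta = np.where(mask, rh0.values * dtau, np.nan)
    field = Field(rh0.grid, delta, "kg m-2", mask)
    return EstimatedDelta(
        pgc=global_total_pgc(field),
        extrapolation_fraction=extrapolation_fraction(fit, t_future),
        delta_field=field,
    )


def _r_squared(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def build_scatter(ensemble: Sequence[ModelRun], delta_t: float,
                  rh_units: str = "per_year",
                  rh_floor: float = RH_FLOOR) -> ScatterResult:
    """Actual-vs-estimated scatter at one global warming level.

    Each run is fitted on its own reference decade and sliced at its own
    crossing year; runs that never reach the level are skipped and listed.
    """
    if len(ensemble) == 0:
        raise ValueError("build_scatter: empty ensemble")
    points: list[DeltaCsTauPoint] = []
    skipped: list[str] = []
    for run in ensemble:
        try:
            slc = slice_at_level(run, delta_t)
        except LevelNotReachedError:
            skipped.append(f"{run.model_id}/{run.scenario_id}")
            continue
        diag = diagnose(run, rh_units=rh_units, rh_floor=rh_floor)
        fit = fit_log_tau_vs_t(diag.tau, diag.t_ref)
        est = estimated_delta_cs_tau(fit, diag.rh0, diag.t_ref, slc.t_future)
        actual = actual_delta_cs_tau(run, slc, rh_units=rh_units, rh_floor=rh_floor)
        points.append(DeltaCsTauPoint(
            model_id=run.model_id, scenario_id=run.scenario_id,
            label=f"{delta_t:g}C",
            actual_pgc=actual, estimated_pgc=est.pgc,
            cs0_pgc=global_total_pgc(diag.cs0),
        ))
    xs = np.array([p.estimated_pgc for p in points])
    ys = np.array([p.actual_pgc for p in points])
    return ScatterResult(points=points, r2=_r_squared(xs, ys), skipped=skipped)


def build_scatter_horizon(ensemble: Sequence[ModelRun],
                          window: tuple[int, int] = (2090, 2100),
                          rh_units: str = "per_year",
                          rh_floor: float = RH_FLOOR) -> ScatterResult:
    """Actual-vs-estimated scatter for a fixed end-of-century horizon
    (window-mean vs reference-decade mean) instead of a warming level."""
    if len(ensemble) == 0:
        raise ValueError("build_scatter_horizon: empty ensemble")
    points = []
    for run in ensemble:
        sel = (run.tas.years >= window[0]) & (run.tas.years <= window[1])
        mask = run.tas.mask[sel].all(axis=0)
        t_future = Field(run.tas.grid,
                         np.where(mask, run.tas.values[sel].mean(axis=0), np.nan),
                         "degC", mask)
        slc = WarmingSlice(delta_t_target=np.nan,
                           central_year=(window[0] + window[1]) // 2,
                           t_future=t_future, window=window)
        diag = diagnose(run, rh_units=rh_units, rh_floor=rh_floor)
        fit = fit_log_tau_vs_t(diag.tau, diag.t_ref)
        est = estimated_delta_cs_tau(fit, diag.rh0, diag.t_ref, slc.t_future)
        actual = actual_delta_cs_tau(run, slc, rh_units=rh_units, rh_floor=rh_floor)
        points.append(DeltaCsTauPoint(
            model_id=run.model_id, scenario_id=run.scenario_id,
            label=f"{window[0]}-{window[1]}",
            actual_pgc=actual, estimated_pgc=est.pgc,
            cs0_pgc=global_total_pgc(diag.cs0),
        ))
    xs = np.array([p.estimated_pgc for p in points])
    ys = np.array([p.actual_pgc for p in points])
    return ScatterResult(points=points, r2=_r_squared(xs, ys), skipped=[])


def fractional_change_curve(total_pgc: float, cs0_pgc: float) -> float:
    """dC_s,tau / C_s,0 — the dimensionless fractional stock change."""
    if cs0_pgc <= 0:
        raise ValueError("fractional_change_curve: cs0_pgc must be positive")
    return total_pgc / cs0_pgc


def scatter_to_rows(result: ScatterResult) -> Iterable[dict]:
    """Rows (model, scenario, label, x_pgc, y_pgc, cs0_pgc) for CSV output."""
    for p in result.points:
        yield {
            "model": p.model_id, "scenario": p.scenario_id, "label": p.label,
            "x_pgc": p.estimated_pgc, "y_pgc": p.actual_pgc, "cs0_pgc": p.cs0_pgc,
        }
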