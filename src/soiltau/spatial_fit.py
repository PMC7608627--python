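"""Quadratic spatial relationship between ln(tau_s) and temperature.

Across space, cold regions hold carbon far longer than warm ones; a
quadratic p(T) fitted to per-cell (T, ln tau_s) points captures that
spatial temperature sensitivity for each model and for the observations.
The natural logarithm is used throughout so exp(p(T)) inverts the fit.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from .grids_io import Field, GridError


@dataclass
class QuadFit:
    """p(T) = c2*T^2 + c1*T + c0, T in degC, p in ln(years)."""

    c2: float
    c1: float
    c0: float
    n_cells: int
    resid_sd: float
    t_range: tuple[float, float]

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        return self.c2 * t**2 + self.c1 * t + self.c0

    def to_json(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["t_range"] = list(self.t_range)
        with open(os.fspath(path), "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "QuadFit":
        with open(os.fspath(path)) as fh:
            d = json.load(fh)
        d["t_range"] = tuple(d["t_range"])
        return cls(**d)


def fit_log_tau_vs_t(tau: Field, t: Field, area_weighted: bool = False) -> QuadFit:
    """Least-squares quadratic of ln(tau_s) on temperature over jointly
    valid cells.

    Each land grid cell is one unweighted point by default (the scatter-plot
    convention); ``area_weighted=True`` weights cells by spherical area.
    """
    if tau.grid != t.grid:
        raise GridError("fit_log_tau_vs_t: tau and t on different grids")
    joint = tau.mask & t.mask & (tau.values > 0)
    n = int(joint.sum())
    if n < 3:
        raise ValueError(f"fit_log_tau_vs_t: need >= 3 jointly valid cells, have {n}")
    x = t.values[joint]
    y = np.log(tau.values[joint])
    if np.ptp(x) == 0:
        raise ValueError("fit_log_tau_vs_t: all temperatures equal (rank-deficient)")
    if area_weighted:
        from .grids_io import cell_areas
        w = cell_areas(tau.grid)[joint]
    else:
        w = None
    # numpy polynomial least squares; highest-degree coefficient first
    c2, c1, c0 = np.polyfit(x, y, deg=2, w=None if w is None else np.sqrt(w))
    resid = y - (c2 * x**2 + c1 * x + c0)
    return QuadFit(
        c2=float(c2), c1=float(c1), c0=float(c0),
        n_cells=n,
        resid_sd=float(np.std(resid)),
        t_range=(float(x.min()), float(x.max())),
    )


def extrapolation_fraction(fit: QuadFit, t: Field) -> float:
    """Fraction of valid cells whose temperature lies outside the fitted range."""
    tmin, tmax = fit.t_range
    vals = t.values[t.mask]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals < tmin) | (vals > tmax)))


def predict_tau(fit: QuadFit, t: Field) -> Field:
    """tau_hat = exp(p(T)) elementwise, in years.

    Extrapolation beyond the fitted temperature range is allowed; callers can
    quantify it with :func:`extrapolation_fraction`.
    """
    vals = np.where(t.mask, np.exp(fit(t.values)), np.nan)
    return Field(t.grid, vals, "yr", t.mask.copy())
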