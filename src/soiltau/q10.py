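"""Effective q10 sensitivity of global soil carbon to global warming.

If decomposition follows a simple q10 law, turnover time responds to a
global-mean warming dT as tau = tau_0 * exp(-0.1 ln(q10) dT), and the
turnover-driven carbon change is

    dC_s,tau = C_s0 * (exp(-0.1 ln(q10) dT) - 1).

For q10 = 2 this is the familiar ~7 % loss per degC. Inverting the relation
turns a constrained dC_s,tau at a given warming level into an effective
global q10, an aggregate sensitivity with no direct link to the spatial
ln(tau)-temperature fit coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Q10Curve:
    """dC_s,tau vs warming curve for one q10 value and initial stock."""

    q10: float
    cs0_pgc: float
    delta_t: np.ndarray        # degC
    delta_cs: np.ndarray       # PgC


def q10_delta_cs(q10: float, cs0_pgc: float, delta_t):
    """dC_s,tau = C_s0 * (exp(-0.1 ln(q10) dT) - 1), in PgC."""
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    if cs0_pgc <= 0:
        raise ValueError("cs0_pgc must be positive")
    dt = np.asarray(delta_t, dtype=float)
    out = cs0_pgc * (np.exp(-0.1 * np.log(q10) * dt) - 1.0)
    return float(out) if out.ndim == 0 else out


def q10_curve(q10: float, cs0_pgc: float, t_max: float = 5.0,
              n: int = 101) -> Q10Curve:
    dt = np.linspace(0.0, t_max, n)
    return Q10Curve(q10=q10, cs0_pgc=cs0_pgc, delta_t=dt,
                    delta_cs=q10_delta_cs(q10, cs0_pgc, dt))


def effective_q10(delta_cs_pgc: float, cs0_pgc: float, delta_t: float) -> float:
    """Invert the q10 relation: q10 = exp(-(10/dT) ln(1 + dC/C0)).

    Round-trips :func:`q10_delta_cs` exactly. Fails when the loss exceeds the
    whole stock (1 + dC/C0 <= 0) or when dT = 0.
    """
    if cs0_pgc <= 0:
        raise ValueError("cs0_pgc must be positive")
    if delta_t == 0:
        raise ValueError("effective_q10 undefined at delta_t = 0")
    ratio = 1.0 + delta_cs_pgc / cs0_pgc
    if ratio <= 0:
        raise ValueError("effective_q10: carbon loss exceeds the initial stock")
    return float(np.exp(-(10.0 / delta_t) * np.log(ratio)))


def effective_q10_from_pdf(y_grid: np.ndarray, pdf: np.ndarray,
                           cs0_pgc: float, delta_t: float,
                           n_draws: int = 100_000,
                           seed: int = 0) -> tuple[float, float]:
    """Effective q10 (mean, sd) propagated through a constrained dC_s,tau
    density by inverse-CDF sampling with a fixed seed.

    Draws where the loss exceeds the stock are rejected (they have no q10).
    """
    rng = np.random.default_rng(seed)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(y_grid))])
    cdf = cdf / cdf[-1]
    u = rng.uniform(0.0, 1.0, n_draws)
    draws = np.interp(u, cdf, y_grid)
    ratio = 1.0 + draws / cs0_pgc
    ok = ratio > 0
    q = np.exp(-(10.0 / delta_t) * np.log(ratio[ok]))
    return float(q.mean()), float(q.std(ddof=1))
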