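"""Alcohol purchase task processing and exponentiated demand-curve estimation.

Responses are how many standard drinks a participant would buy at each of 13
ascending prices ($0–$80/drink).  Quantities above the overconsumption cap
(50 drinks at any price) are truncated to the cap.  Demand is summarized by
observed metrics (intensity, Omax, Pmax) and by the exponentiated demand
equation

    Q(C) = Q0 * 10 ** (k * (exp(-alpha * Q0 * C) - 1))

fit on the raw consumption scale so that zero-consumption prices are retained.
``Q0`` is demand intensity (consumption at price 0), ``alpha`` the elasticity
rate, and ``k`` the log10 span of the curve, fixed across all fits in a
dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "DEFAULT_PRICES",
    "DemandObservationSet",
    "DemandFit",
    "cap_overconsumption",
    "observed_metrics",
    "shared_k_span",
    "exponentiated_demand",
    "fit_exponentiated",
    "fitted_pmax",
]

# 13 ascending prices in $/drink: count, order and endpoints fixed by the
# task; interior values are the package default and travel with the data file.
DEFAULT_PRICES: tuple[float, ...] = (
    0.0, 0.25, 0.50, 1.0, 1.50, 2.0, 2.50, 3.0, 4.0, 5.0, 6.0, 10.0, 80.0,
)

DEFAULT_CAP = 50


@dataclass
class DemandObservationSet:
    """One purchase-task administration: aligned price/quantity vectors."""

    prices: tuple[float, ...]
    quantities: tuple[int, ...]
    cap: int = DEFAULT_CAP
    capped_flags: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.prices, dtype=float)
        q = np.asarray(self.quantities)
        if p.size != q.size:
            raise ValueError("prices and quantities must align")
        if p[0] != 0.0 or np.any(np.diff(p) <= 0):
            raise ValueError("prices must start at 0 and be strictly ascending")
        if np.any(q < 0):
            raise ValueError("quantities must be >= 0")

    def capped(self) -> "DemandObservationSet":
        q, flags = cap_overconsumption(self.quantities, self.cap)
        return DemandObservationSet(self.prices, tuple(int(x) for x in q),
                                    self.cap, tuple(bool(f) for f in flags))


@dataclass
class DemandFit:
    """Fitted and observed demand metrics for one administration."""

    Q0: float
    alpha: float
    k_span: float
    converged: bool
    ln_alpha: float
    intensity_obs: int
    omax_obs: float
    pmax_obs: float
    sse: float = float("nan")


def cap_overconsumption(raw_quantities, cap: int = DEFAULT_CAP):
    """Truncate quantities above ``cap``; flag where truncation occurred."""
    q = np.asarray(raw_quantities)
    if np.any(q < 0):
        raise ValueError("negative quantity in purchase-task responses")
    flags = q > cap
    return np.minimum(q, cap), flags


def observed_metrics(obs: DemandObservationSet) -> tuple[int, float, float]:
    """Observed intensity, Omax and Pmax.

    Intensity is consumption at price 0; Omax the maximum expenditure
    (price x quantity); Pmax the smallest price attaining Omax.
    """
    p = np.asarray(obs.prices, dtype=float)
    q = np.asarray(obs.quantities, dtype=float)
    expenditure = p * q
    omax = float(expenditure.max())
    pmax = float(p[int(np.argmax(expenditure))])  # argmax returns first/lowest
    return int(q[0]), omax, pmax


def shared_k_span(all_quantities) -> float:
    """Span constant shared across a dataset's fits.

    log10(max pooled consumption) - log10(min pooled nonzero consumption)
    + 0.5.  Requires at least one positive quantity.
    """
    pooled = np.concatenate([np.asarray(q, dtype=float) for q in all_quantities])
    pos = pooled[pooled > 0]
    if pos.size == 0:
        raise ValueError("no positive quantities in pooled purchase data")
    return float(math.log10(pos.max()) - math.log10(pos.min()) + 0.5)


def exponentiated_demand(prices, q0: float, alpha: float, k_span: float):
    """Evaluate Q(C); defined (and equal to Q0) at C = 0."""
    c = np.asarray(prices, dtype=float)
    return q0 * 10.0 ** (k_span * (np.exp(-alpha * q0 * c) - 1.0))


# deterministic multi-start (Q0 scale x alpha) keeps refits reproducible
_ALPHA_STARTS = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)
_ALPHA_BOUNDS = (1e-8, 10.0)


def fit_exponentiated(obs: DemandObservationSet, k_span: float,
                      cap: int | None = None) -> DemandFit:
    """Least-squares fit of (Q0, alpha) to capped raw-scale quantities.

    Zeros are retained.  All-zero response sets and optimizer failures (or
    alpha pinned at its bounds) are returned with ``converged=False`` so the
    caller can exclude them, never as an exception.
    """
    cap = obs.cap if cap is None else cap
    p = np.asarray(obs.prices, dtype=float)
    q = np.asarray(obs.quantities, dtype=float)
    intensity, omax, pmax = observed_metrics(obs)

    def make(q0, alpha, conv, sse=float("nan")):
        return DemandFit(Q0=q0, alpha=alpha, k_span=k_span, converged=conv,
                         ln_alpha=math.log(alpha), intensity_obs=intensity,
                         omax_obs=omax, pmax_obs=pmax, sse=sse)

    if not np.any(q > 0):
        return make(1e-6, _ALPHA_BOUNDS[0], False)

    def resid(theta):
        return exponentiated_demand(p, theta[0], theta[1], k_span) - q

    q0_start = max(float(q[0]), 1.0)
    lb = (1e-6, _ALPHA_BOUNDS[0])
    ub = (2.0 * cap, _ALPHA_BOUNDS[1])
    best = None
    for a0 in _ALPHA_STARTS:
        try:
            sol = least_squares(resid, x0=(q0_start, a0), bounds=(lb, ub),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return make(q0_start, _ALPHA_STARTS[0], False)

    q0_hat, a_hat = float(best.x[0]), float(best.x[1])
    sse = float(2.0 * best.cost)
    at_bound = a_hat <= _ALPHA_BOUNDS[0] * (1 + 1e-6) or \
        a_hat >= _ALPHA_BOUNDS[1] * (1 - 1e-6)
    return make(q0_hat, a_hat, not at_bound, sse)


def fitted_pmax(fit: DemandFit, grid_points: int = 200001) -> float:
    """Price where the fitted curve's expenditure elasticity is -1.

    Solves u * exp(-u) = 1/(k ln 10) for u in (0, 1) with u = alpha*Q0*C,
    the first stationary point (local maximum) of expenditure C*Q(C).  When
    k ln 10 <= e no interior maximum exists (the exponentiated curve's
    expenditure eventually grows linearly); a bounded grid maximization of
    C*Q(C) on [0, 10*pmax_obs + 1] is returned instead.
    """
    if not fit.converged:
        raise ValueError("fitted_pmax unavailable: fit did not converge")
    lam = fit.alpha * fit.Q0
    target = 1.0 / (fit.k_span * math.log(10.0))
    if target < 1.0 / math.e:  # root of u e^-u = target exists in (0, 1)
        u = brentq(lambda u: u * math.exp(-u) - target, 1e-15, 1.0,
                   xtol=1e-14)
        return float(u / lam)
    upper = 10.0 * fit.pmax_obs + 1.0
    grid = np.linspace(0.0, upper, grid_points)
    expenditure = grid * exponentiated_demand(grid, fit.Q0, fit.alpha, fit.k_span)
    return float(grid[int(np.argmax(expenditure))])
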