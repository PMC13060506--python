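"""Adjusting-amount delay-discounting task: titration engine, systematicity
screening, and hyperbolic discount-rate estimation.

The task presents repeated choices between a smaller-sooner (SS) amount
available now and a larger-later (LL) amount ``A`` at delay ``D``.  The SS
amount is titrated by halving steps toward the participant's indifference
point, and the per-delay indifference points V are fit with the hyperbolic
model

    V = A / (1 + k * D)

where ``k`` (1/days) is the discount rate.  ``k`` is reported on the natural
log scale downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "TitrationSchedule",
    "IndifferenceCurve",
    "DiscountingFit",
    "ProtocolError",
    "run_titration",
    "johnson_bickel_screen",
    "fit_hyperbolic",
    "hyperbolic_value",
    "DEFAULT_DELAYS_DAYS",
]

# Calendar delays of the task (1 day, 2 weeks, 1 month, 3 months, 1 year,
# 5 years, 25 years) converted with the 30-day-month / 365-day-year convention.
DEFAULT_DELAYS_DAYS: tuple[float, ...] = (1.0, 14.0, 30.0, 90.0, 365.0, 1825.0, 9125.0)

# Chooser protocol: chooser(ss_amount, ll_amount, delay_days) -> "SS" | "LL"
Chooser = Callable[[float, float, float], str]


class ProtocolError(RuntimeError):
    """A chooser returned something other than 'SS'/'LL' during titration."""


def hyperbolic_value(amount: float, k: float, delay_days: float) -> float:
    """Present value of ``amount`` delayed by ``delay_days`` at rate ``k``."""
    return amount / (1.0 + k * delay_days)


@dataclass(frozen=True)
class TitrationSchedule:
    """Parameters of the adjusting-amount task.

    ll_amount
        The constant larger-later amount A in dollars (default $1000).
    delays_days
        Strictly increasing delays in days.
    trials_per_delay
        Number of binary choices per delay (default 6).
    """

    ll_amount: float = 1000.0
    delays_days: tuple[float, ...] = DEFAULT_DELAYS_DAYS
    trials_per_delay: int = 6

    def __post_init__(self) -> None:
        if self.ll_amount <= 0:
            raise ValueError("ll_amount must be > 0")
        if self.trials_per_delay < 1:
            raise ValueError("trials_per_delay must be >= 1")
        d = np.asarray(self.delays_days, dtype=float)
        if d.size == 0 or np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("delays_days must be strictly increasing and positive")
        object.__setattr__(self, "delays_days", tuple(float(x) for x in d))

    @property
    def resolution(self) -> float:
        """Half-step beyond the final trial: A / 2**(T+1)."""
        return self.ll_amount / 2 ** (self.trials_per_delay + 1)


@dataclass
class IndifferenceCurve:
    """Per-delay indifference points from one task administration."""

    session: str
    delays_days: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.delays_days) != len(self.values):
            raise ValueError("delays and values must align")


@dataclass
class DiscountingFit:
    """Hyperbolic fit of one indifference curve."""

    k: float
    ln_k: float
    sse: float
    criterion1_ok: bool | None = None
    criterion2_ok: bool | None = None
    boundary_flag: bool = False
    method: str = "least-squares on indifference points"

    def __post_init__(self) -> None:
        assert math.isclose(self.ln_k, math.log(self.k), rel_tol=1e-9)


def run_titration(chooser: Chooser, schedule: TitrationSchedule,
                  session: str = "S1") -> IndifferenceCurve:
    """Run the adjusting-amount procedure against a chooser.

    For each delay, trial 1 presents SS = A/2.  After the choice on trial t
    the SS moves by A / 2**(t+1): down if the SS was taken, up if the LL was
    taken.  The indifference point is the amount that *would* be presented on
    trial T+1, giving a resolution of A / 2**(T+1).
    """
    A = schedule.ll_amount
    points: list[float] = []
    for delay in schedule.delays_days:
        ss = A / 2.0
        for t in range(1, schedule.trials_per_delay + 1):
            choice = chooser(ss, A, delay)
            step = A / 2 ** (t + 1)
            if choice == "SS":
                ss -= step
            elif choice == "LL":
                ss += step
            else:
                raise ProtocolError(
                    f"invalid choice {choice!r} at delay {delay} trial {t}"
                )
        points.append(ss)
    return IndifferenceCurve(session=session,
                             delays_days=schedule.delays_days,
                             values=tuple(points))


def johnson_bickel_screen(curve: IndifferenceCurve, ll_amount: float,
                          rise_frac: float = 0.20,
                          drop_frac: float = 0.10) -> tuple[bool, bool]:
    """Flag nonsystematic indifference-point series.

    Criterion 1 fails when any point exceeds the point at the preceding
    (shorter) delay by more than ``rise_frac`` of A.  Criterion 2 fails when
    the last point is not below the first by at least ``drop_frac`` of A.
    Flagged data are never dropped downstream.
    """
    v = np.asarray(curve.values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 indifference points to screen")
    c1 = bool(np.all(np.diff(v) <= rise_frac * ll_amount))
    c2 = bool(v[0] - v[-1] >= drop_frac * ll_amount)
    return c1, c2


def _sse(ln_k: float, delays: np.ndarray, v: np.ndarray, A: float) -> float:
    pred = A / (1.0 + math.exp(ln_k) * delays)
    r = v - pred
    return float(r @ r)


def fit_hyperbolic(curve: IndifferenceCurve,
                   schedule: TitrationSchedule | None = None,
                   ll_amount: float | None = None,
                   k_bounds: tuple[float, float] = (1e-10, 1e3),
                   n_grid: int = 600) -> DiscountingFit:
    """Least-squares hyperbolic fit of an indifference curve.

    Minimizes sum((V - A/(1+kD))**2) over ln k in [ln k_lo, ln k_hi] by a
    dense grid followed by bounded local refinement.  Degenerate curves
    (e.g. V == A everywhere) return the boundary optimum with
    ``boundary_flag`` set rather than raising.
    """
    if schedule is not None:
        A = schedule.ll_amount
    elif ll_amount is not None:
        A = ll_amount
    else:
        raise ValueError("provide schedule or ll_amount")
    delays = np.asarray(curve.delays_days, dtype=float)
    v = np.asarray(curve.values, dtype=float)

    lo, hi = math.log(k_bounds[0]), math.log(k_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    # vectorized SSE over the grid
    pred = A / (1.0 + np.exp(grid)[:, None] * delays[None, :])
    sse_grid = np.sum((v[None, :] - pred) ** 2, axis=1)
    i = int(np.argmin(sse_grid))
    bl = grid[max(i - 1, 0)]
    bu = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(_sse, bounds=(bl, bu), args=(delays, v, A),
                          method="bounded",
                          options={"xatol": 1e-12})
    ln_k = float(res.x)
    sse = float(res.fun)
    # keep whichever is better, grid point or refined point
    if sse_grid[i] < sse:
        ln_k, sse = float(grid[i]), float(sse_grid[i])

    span = hi - lo
    boundary = ln_k <= lo + 1e-6 * span or ln_k >= hi - 1e-6 * span
    if boundary:
        ln_k = lo if ln_k - lo < hi - ln_k else hi
        sse = _sse(ln_k, delays, v, A)
    return DiscountingFit(k=math.exp(ln_k), ln_k=ln_k, sse=sse,
                          boundary_flag=bool(boundary))
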