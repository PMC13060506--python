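"""Covariate-adaptive minimization randomization.

Sequentially assigns participants to EFT or CET with a biased coin that
favors the group minimizing covariate imbalance.  The balancing covariates
are the square-root-transformed baseline drinks/day (the transform tames the
right skew of drinking rates) and baseline ln(k).  Imbalance for a
hypothetical assignment is

    sum over covariates of |mean_EFT - mean_CET| / pooled SD   (standardized;
    a covariate is skipped while its pooled SD is still undefined)
    + lambda * |n_EFT - n_CET|

with lambda = 0.5.  The candidate goes to the imbalance-minimizing group with
probability ``bias_probability`` (default 0.8); exact ties fall back to a
fair coin, so the very first allocation is 50/50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GROUPS", "AllocationState", "allocate", "allocate_stream"]

GROUPS = ("EFT", "CET")


@dataclass
class AllocationState:
    bias_probability: float = 0.8
    size_penalty: float = 0.5
    seed: int = 0
    rosters: dict = field(default_factory=lambda: {g: [] for g in GROUPS})
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.5 <= self.bias_probability <= 1.0:
            raise ValueError("bias_probability must be in [0.5, 1]")
        self._rng = np.random.default_rng(self.seed)

    def group_sizes(self) -> dict:
        return {g: len(self.rosters[g]) for g in GROUPS}


def _imbalance(rosters: dict, size_penalty: float) -> float:
    """Standardized covariate imbalance plus the group-size penalty."""
    total = size_penalty * abs(len(rosters["EFT"]) - len(rosters["CET"]))
    if not rosters["EFT"] or not rosters["CET"]:
        return total
    eft = np.asarray(rosters["EFT"], dtype=float)
    cet = np.asarray(rosters["CET"], dtype=float)
    pooled = np.vstack([eft, cet])
    for j in range(pooled.shape[1]):
        sd = pooled[:, j].std(ddof=1) if pooled.shape[0] >= 2 else 0.0
        if sd > 0:
            total += abs(eft[:, j].mean() - cet[:, j].mean()) / sd
    return total


def allocate(state: AllocationState, sqrt_drinks_per_day: float,
             ln_k: float) -> tuple[str, float, float]:
    """Assign one candidate; mutates ``state``.

    Returns (group, imbalance_before, imbalance_after).
    """
    cov = (float(sqrt_drinks_per_day), float(ln_k))
    if not all(math.isfinite(c) for c in cov):
        raise ValueError("non-finite balancing covariate")
    before = _imbalance(state.rosters, state.size_penalty)

    hypo = {}
    for g in GROUPS:
        trial = {k: list(v) for k, v in state.rosters.items()}
        trial[g].append(cov)
        hypo[g] = _imbalance(trial, state.size_penalty)

    if math.isclose(hypo["EFT"], hypo["CET"], rel_tol=1e-12, abs_tol=1e-12):
        preferred = GROUPS[state._rng.integers(2)]
        p = 0.5  # tie: fair coin regardless of bias
    else:
        preferred = min(GROUPS, key=lambda g: hypo[g])
        p = state.bias_probability
    other = "CET" if preferred == "EFT" else "EFT"
    group = preferred if state._rng.random() < p else other

    state.rosters[group].append(cov)
    return group, before, _imbalance(state.rosters, state.size_penalty)


def allocate_stream(sqrt_dpd, ln_k, bias_probability: float = 0.8,
                    seed: int = 0) -> list[str]:
    """Allocate a whole candidate sequence; convenience for simulations."""
    state = AllocationState(bias_probability=bias_probability, seed=seed)
    return [allocate(state, s, k)[0] for s, k in zip(sqrt_dpd, ln_k, strict=True)]
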