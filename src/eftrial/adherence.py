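"""Exhaustive BIC model search over logistic models of submission adherence.

The outcome is whether a scheduled daily submission (drink-count report or a
breath sample) is missing.  Candidate predictors are group, monitoring phase,
their interaction, and demographics; for the breath outcome also the
within-day submission slot (first/second/third) and its interactions with
phase and group.  Every hierarchy-respecting subset of terms is enumerated,
each fit by maximum-likelihood logistic regression, and models are ranked by

    BIC = -2 * loglik + n_params * ln(n)

with the lowest-BIC model selected.  Models with separation or failed
convergence are excluded with a warning rather than aborting the search.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = [
    "CandidateModelSpace",
    "ModelFit",
    "SelectionResult",
    "DRINK_COUNT_SPACE",
    "BREATH_SPACE",
    "enumerate_models",
    "select_by_bic",
]

DEMOGRAPHICS = ("age", "sex", "ethnicity", "race", "education", "income")


@dataclass(frozen=True)
class CandidateModelSpace:
    """Main effects plus allowed interactions, under the hierarchy rule."""

    outcome: str
    main_effects: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        mains = set(self.main_effects)
        for a, b in self.interactions:
            if a not in mains or b not in mains:
                raise ValueError(
                    f"interaction {a}:{b} lists a term absent from the main effects")


DRINK_COUNT_SPACE = CandidateModelSpace(
    outcome="missing_drink_count",
    main_effects=("group", "phase") + DEMOGRAPHICS,
    interactions=(("group", "phase"),),
)

BREATH_SPACE = CandidateModelSpace(
    outcome="missing_breath_sample",
    main_effects=("group", "phase") + DEMOGRAPHICS + ("time_of_submission",),
    interactions=(("group", "phase"),
                  ("time_of_submission", "phase"),
                  ("time_of_submission", "group")),
)


@dataclass
class ModelFit:
    terms: tuple[str, ...]
    loglik: float
    n_params: int
    bic: float


@dataclass
class SelectionResult:
    ranked: list[ModelFit]
    warnings: list[str] = field(default_factory=list)

    @property
    def best(self) -> ModelFit:
        return self.ranked[0]


def enumerate_models(space: CandidateModelSpace) -> list[tuple[str, ...]]:
    """All hierarchy-respecting term subsets, intercept-only included.

    Deterministic order: by model size, then lexicographically in the
    space's term order.
    """
    models: list[tuple[str, ...]] = []
    for r in range(len(space.main_effects) + 1):
        for mains in itertools.combinations(space.main_effects, r):
            chosen = set(mains)
            allowed = [i for i in space.interactions
                       if i[0] in chosen and i[1] in chosen]
            for s in range(len(allowed) + 1):
                for inters in itertools.combinations(allowed, s):
                    models.append(mains + tuple(f"{a}:{b}" for a, b in inters))
    models.sort(key=lambda m: (len(m), m))
    return models


def _formula(outcome: str, terms: tuple[str, ...]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{outcome} ~ {rhs}"


def select_by_bic(term_sets: list[tuple[str, ...]], data: pd.DataFrame,
                  outcome: str) -> SelectionResult:
    """Fit every candidate logistic model and rank by BIC.

    Categorical (object/category) columns are dummy-coded with the first
    level as reference by the formula machinery; the parameter count includes
    the intercept.  Nonconverged or separated fits are skipped with a
    recorded warning.
    """
    n = len(data)
    fits: list[ModelFit] = []
    warns: list[str] = []
    for terms in term_sets:
        formula = _formula(outcome, terms)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=RuntimeWarning)
                res = smf.logit(formula, data=data).fit(disp=0, maxiter=200,
                                                        tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception as exc:
            warns.append(f"{formula}: excluded ({type(exc).__name__}: {exc})")
            continue
        if not converged or not np.isfinite(res.llf):
            warns.append(f"{formula}: excluded (no convergence)")
            continue
        k = int(len(res.params))
        if n <= k:
            warns.append(f"{formula}: excluded (n <= parameter count)")
            continue
        fits.append(ModelFit(terms=terms, loglik=float(res.llf), n_params=k,
                             bic=float(-2.0 * res.llf + k * np.log(n))))
    if not fits:
        raise RuntimeError("no candidate model converged")
    fits.sort(key=lambda f: (f.bic, len(f.terms), f.terms))
    return SelectionResult(ranked=fits, warnings=warns)
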