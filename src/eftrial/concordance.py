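"""Breathalyzer / self-report concordance.

Each monitored day yields up to three breath alcohol concentration (BrAC)
samples and one self-reported drink count.  A day is breath-positive when its
peak sample is at or above the positivity threshold (default 0.02% BrAC).
The module builds the 3x3 cross-tabulation of breath status (negative /
positive / missing) against report status (none / one or more / missing),
computes the Fisher exact association on the non-missing 2x2, and the
rank-based ROC AUC of peak BrAC as a predictor of drinking days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata
from scipy.stats.contingency import odds_ratio

__all__ = [
    "BRAC_POSITIVE_THRESHOLD",
    "BREATH_LEVELS",
    "REPORT_LEVELS",
    "DayClassification",
    "DegenerateTableError",
    "classify_day",
    "build_concordance_matrix",
    "nonmissing_2x2",
    "fisher_exact_or",
    "roc_auc",
]

BRAC_POSITIVE_THRESHOLD = 0.02  # % BrAC

BREATH_LEVELS = ("Negative", "Positive", "Missing")
REPORT_LEVELS = ("None", "One or more", "Missing")


class DegenerateTableError(ValueError):
    """A 2x2 margin is zero: the odds ratio is undefined."""


@dataclass
class DayClassification:
    participant: str
    day_index: int
    breath_status: str  # Negative | Positive | Missing
    report_status: str  # None | One or more | Missing
    peak_brac: float | None


def classify_day(samples: Sequence[float], reported: int | None,
                 participant: str = "", day_index: int = 0,
                 threshold: float = BRAC_POSITIVE_THRESHOLD) -> DayClassification:
    """Classify one participant-day.

    Breath status uses the peak (highest) sample of the day; >= threshold is
    positive, strictly below is negative, no samples is missing.  Report
    status is 'None' only for an explicit zero count.
    """
    samples = [float(s) for s in samples]
    if any(s < 0 for s in samples):
        raise ValueError("negative BrAC reading")
    if samples:
        peak = max(samples)
        breath = "Positive" if peak >= threshold else "Negative"
    else:
        peak, breath = None, "Missing"
    if reported is None or (isinstance(reported, float) and math.isnan(reported)):
        report = "Missing"
    else:
        report = "None" if int(reported) == 0 else "One or more"
    return DayClassification(participant, day_index, breath, report, peak)


def build_concordance_matrix(classifications: Sequence[DayClassification]) -> pd.DataFrame:
    """3x3 counts, rows = breath status, columns = report status."""
    mat = pd.DataFrame(0, index=list(BREATH_LEVELS), columns=list(REPORT_LEVELS),
                       dtype=int)
    for c in classifications:
        mat.loc[c.breath_status, c.report_status] += 1
    return mat


def nonmissing_2x2(matrix: pd.DataFrame) -> np.ndarray:
    """Drop the missing row/column: days with both a breath reading and a report."""
    return matrix.loc[["Negative", "Positive"], ["None", "One or more"]].to_numpy()


def fisher_exact_or(table: np.ndarray) -> tuple[float, float]:
    """Fisher exact test on a 2x2 table.

    Returns the conditional maximum-likelihood odds ratio (noncentral
    hypergeometric model) and the two-sided p-value summing the
    probabilities of tables, at fixed margins, no more probable than the
    observed one under OR = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a nonnegative 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateTableError("zero margin: odds ratio undefined")
    or_cond = float(odds_ratio(t, kind="conditional").statistic)
    p = float(fisher_exact(t, alternative="two-sided").pvalue)
    return or_cond, p


def roc_auc(peaks: Sequence[float], labels: Sequence[int]) -> float:
    """AUC of peak BrAC for discriminating drinking from non-drinking days.

    Computed as the tie-aware rank statistic, equal to
    P(peak_drinking > peak_non) + 0.5 * P(tie) over all cross-class pairs.
    """
    x = np.asarray(peaks, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.shape != y.shape:
        raise ValueError("peaks and labels must align")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: need both drinking and non-drinking days")
    ranks = rankdata(x)  # midranks handle ties exactly
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))
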