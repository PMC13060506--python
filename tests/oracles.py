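"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by enumeration or exhaustive search,
sharing no code path with the package implementation it validates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln
from scipy.optimize import minimize_scalar


def titration_binary_search(choices: list[str], A: float = 1000.0) -> float:
    """Hand-apply the adjusting-amount update rule for one delay.

    ``choices`` is the sequence of 'SS'/'LL' responses; returns the would-be
    next presented amount (the indifference point).
    """
    ss = A / 2.0
    for t, ch in enumerate(choices, start=1):
        step = A / 2 ** (t + 1)
        ss += step if ch == "LL" else -step
    return ss


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_table_probs(table: np.ndarray):
    """Null (central hypergeometric) probabilities of every table sharing the
    observed margins.  Returns (support of cell a, probabilities)."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = (_log_comb(r1, support) + _log_comb(n - r1, c1 - support)
            - _log_comb(n, c1))
    return support, np.exp(logp - logp.max()) / np.exp(logp - logp.max()).sum()


def fisher_p_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p: total probability of margin-compatible tables no
    more probable than the observed one."""
    a = int(table[0, 0])
    support, probs = hypergeom_table_probs(table)
    p_obs = probs[support == a][0]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def conditional_mle_or(table: np.ndarray) -> float:
    """Conditional-MLE odds ratio by direct maximization of the noncentral
    hypergeometric likelihood over log-psi."""
    a = int(table[0, 0])
    support, _ = hypergeom_table_probs(table)
    if a == support.min():
        return 0.0
    if a == support.max():
        return math.inf
    r1 = int(table[0].sum())
    c1 = int(table[:, 0].sum())
    n = int(table.sum())
    logw = _log_comb(r1, support) + _log_comb(n - r1, c1 - support)

    def neg_loglik(log_psi):
        terms = logw + support * log_psi
        m = terms.max()
        return -(logw[support == a][0] + a * log_psi
                 - (m + math.log(np.exp(terms - m).sum())))

    res = minimize_scalar(neg_loglik, bounds=(-40.0, 40.0), method="bounded",
                          options={"xatol": 1e-12})
    return float(math.exp(res.x))


def auc_pair_counting(peaks, labels) -> float:
    """AUC as explicit counting over all positive-negative pairs."""
    pos = [p for p, l in zip(peaks, labels) if l == 1]
    neg = [p for p, l in zip(peaks, labels) if l == 0]
    score = 0.0
    for p in pos:
        for q in neg:
            score += 1.0 if p > q else (0.5 if p == q else 0.0)
    return score / (len(pos) * len(neg))


def logistic_loglik(beta0: float, beta1: float, x: np.ndarray,
                    y: np.ndarray) -> float:
    eta = beta0 + beta1 * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def logistic_grid_fit(x: np.ndarray, y: np.ndarray, span: float = 6.0,
                      steps: int = 601) -> tuple[float, float, float]:
    """Coarse-grid maximum likelihood for a 1-predictor logistic model."""
    b0s = np.linspace(-span, span, steps)
    b1s = np.linspace(-span, span, steps)
    eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
    ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=2)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(b0s[i]), float(b1s[j]), float(ll[i, j])
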