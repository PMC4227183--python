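"""Significance of a count difference between two un-replicated libraries.

The statistic is the classic digital-gene-expression probability for two
libraries of total sizes N1 and N2: given x reads for a gene in library 1,
the probability of seeing i reads in library 2 is

    p(i | x) = (N2/N1)^i * (x+i)! / (x! i!) / (1 + N2/N1)^(x+i+1)

which is exactly the negative-binomial mass with size x+1 and success
probability N1/(N1+N2) evaluated at i — the posterior predictive of a
Poisson count under a flat prior on the (scaled) rate. Everything is
computed in log space via log-gamma so counts up to at least 1e6 neither
overflow nor underflow; tails are accumulated with a geometric stopping
bound (relative tolerance 1e-15) rather than term-by-term to infinity.

Two-sided p-value: min(1, 2*min(lower tail, upper tail)), the standard
symmetric construction for a discrete statistic; the observed point mass
belongs to both tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ac_point_prob",
    "ac_tail_probs",
    "ac_two_sided_pvalue",
    "bh_fdr",
]

_CHUNK = 1 << 14  # terms summed per block when scanning a tail


@dataclass(frozen=True)
class TestResult:
    """Point probability and two-sided p-value for one unigene."""

    unigene_id: str
    point_prob: float
    p_value: float


def _check_args(x: int, i: int, n1: int, n2: int) -> tuple[int, int]:
    for name, v in (("x", x), ("i", i)):
        if isinstance(v, bool) or not float(v).is_integer():
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library totals must be positive, got n1={n1}, n2={n2}")
    return int(x), int(i)


def _log_pmf(i, x: int, log_r: float, log_1pr: float):
    """log p(i|x) for scalar or array i (negative binomial, size x+1)."""
    i = np.asarray(i, dtype=float)
    return (
        i * log_r
        + gammaln(x + i + 1.0)
        - gammaln(x + 1.0)
        - gammaln(i + 1.0)
        - (x + i + 1.0) * log_1pr
    )


def ac_point_prob(x: int, i: int, n1: int, n2: int) -> float:
    """p(i|x): probability of i reads in library 2 given x in library 1.

    Evaluated in log space; exact to ~1e-15 relative for counts into the
    millions.
    """
    x, i = _check_args(x, i, n1, n2)
    r = n2 / n1
    lp = _log_pmf(i, x, math.log(r), math.log1p(r))
    return float(np.exp(lp))


def _sum_lower(x: int, i_obs: int, log_r: float, log_1pr: float) -> float:
    """Sum p(i|x) for i = 0..i_obs, chunked logsumexp."""
    total_log = -math.inf
    for lo in range(0, i_obs + 1, _CHUNK):
        hi = min(lo + _CHUNK, i_obs + 1)
        total_log = np.logaddexp(total_log, logsumexp(_log_pmf(np.arange(lo, hi), x, log_r, log_1pr)))
    return float(np.exp(total_log))


def _sum_upper(x: int, i_obs: int, log_r: float, log_1pr: float, r: float) -> float:
    """Sum p(i|x) for i >= i_obs until the geometric remainder bound drops
    below 1e-15 of the running total."""
    total_log = -math.inf
    lo = i_obs
    while True:
        idx = np.arange(lo, lo + _CHUNK)
        lp = _log_pmf(idx, x, log_r, log_1pr)
        total_log = np.logaddexp(total_log, logsumexp(lp))
        i_last = lo + _CHUNK - 1
        # successive-term ratio p(i+1|x)/p(i|x) = r(x+i+1)/((i+1)(1+r));
        # past the mode it is < 1 and decreasing, so the remainder is
        # bounded by a geometric series starting at the last term.
        ratio = r * (x + i_last + 2) / ((i_last + 2) * (1.0 + r))
        if ratio < 1.0:
            rem_log = lp[-1] + math.log(ratio) - math.log1p(-ratio)
            if rem_log < total_log + math.log(1e-15):
                break
        lo += _CHUNK
    return float(np.exp(total_log))


def ac_tail_probs(x: int, i_obs: int, n1: int, n2: int) -> tuple[float, float]:
    """Lower and upper tail probabilities of the count distribution.

    lower = P(I <= i_obs | x), upper = P(I >= i_obs | x); both include the
    observed point mass, so lower + upper - p(i_obs|x) = 1. The cheaper
    tail is summed directly and the other obtained by complement.
    """
    x, i_obs = _check_args(x, i_obs, n1, n2)
    r = n2 / n1
    log_r, log_1pr = math.log(r), math.log1p(r)
    point = float(np.exp(_log_pmf(i_obs, x, log_r, log_1pr)))

    # expected terms to cross the bulk from i_obs upward vs i_obs+1 downward
    mean = r * (x + 1)
    sd = math.sqrt(r * (1.0 + r) * (x + 1))
    n_upper_est = max(0.0, mean - i_obs) + 20.0 * sd + 64.0
    if i_obs + 1 <= n_upper_est:
        lower = _sum_lower(x, i_obs, log_r, log_1pr)
        upper = 1.0 - lower + point
    else:
        upper = _sum_upper(x, i_obs, log_r, log_1pr, r)
        lower = 1.0 - upper + point
    return min(max(lower, 0.0), 1.0), min(max(upper, 0.0), 1.0)


def ac_two_sided_pvalue(x: int, i_obs: int, n1: int, n2: int) -> float:
    """Two-sided p-value: min(1, 2*min(lower, upper))."""
    lower, upper = ac_tail_probs(x, i_obs, n1, n2)
    return min(1.0, 2.0 * min(lower, upper))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q(k) = min_{j >= k} p(j)*m/j over ascending ranks, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
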