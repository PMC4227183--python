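"""Independent exact-rational oracles for the count statistic.

Everything here is computed with fractions.Fraction and math.comb only —
no floats, no shared code with the package's log-space implementation —
so it can serve as ground truth on small inputs.
"""

from fractions import Fraction
from math import comb


def exact_point_prob(x: int, i: int, n1: int, n2: int) -> Fraction:
    """p(i|x) = r^i * C(x+i, i) / (1+r)^(x+i+1), r = n2/n1, exactly."""
    r = Fraction(n2, n1)
    return r**i * comb(x + i, i) / (1 + r) ** (x + i + 1)


def exact_lower_tail(x: int, i_obs: int, n1: int, n2: int) -> Fraction:
    return sum(exact_point_prob(x, k, n1, n2) for k in range(i_obs + 1))


def exact_upper_tail(x: int, i_obs: int, n1: int, n2: int) -> Fraction:
    return 1 - exact_lower_tail(x, i_obs, n1, n2) + exact_point_prob(x, i_obs, n1, n2)


def exact_two_sided(x: int, i_obs: int, n1: int, n2: int) -> Fraction:
    lo = exact_lower_tail(x, i_obs, n1, n2)
    up = exact_upper_tail(x, i_obs, n1, n2)
    return min(Fraction(1), 2 * min(lo, up))


def exact_bh(p_values):
    """Step-up BH from the definition: q(k) = min_{j>=k} p(j)*m/j, capped."""
    m = len(p_values)
    order = sorted(range(m), key=lambda k: p_values[k])
    q = [None] * m
    best = Fraction(1)
    for rank in range(m, 0, -1):
        j = order[rank - 1]
        best = min(best, Fraction(p_values[j]) * m / rank)
        q[j] = best
    return q
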