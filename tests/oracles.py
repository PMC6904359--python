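"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic from first principles (enumeration or the
literal textbook definition) and never calls the implementation it checks.
"""

from __future__ import annotations

import itertools
import math


def hypergeom_point_prob(a: int, b: int, c: int, d: int) -> float:
    """P(this exact 2x2 table | fixed margins) = product of binomials."""
    return (
        math.comb(a + b, a)
        * math.comb(c + d, c)
        / math.comb(a + b + c + d, a + c)
    )


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summing point probabilities <= the observed one."""
    col1 = a + c
    p_obs = hypergeom_point_prob(a, b, c, d)
    total = 0.0
    for x in range(0, col1 + 1):
        aa, cc = x, col1 - x
        bb, dd = a + b - aa, c + d - cc
        if bb < 0 or dd < 0:
            continue
        p = hypergeom_point_prob(aa, bb, cc, dd)
        if p <= p_obs * (1.0 + 1e-12):
            total += p
    return min(1.0, total)


def mwu_u_statistic(values_a, values_b) -> float:
    """U of sample a: number of (a, b) pairs with a > b (+0.5 per tie)."""
    u = 0.0
    for x in values_a:
        for y in values_b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mwu_two_sided_enumeration(values_a, values_b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p over all rank arrangements (no ties).

    Enumerates every way of assigning the pooled observations to the first
    group; two-sided p = 2 * min(P(U <= u_obs), P(U >= u_obs)), capped at 1.
    """
    pooled = list(values_a) + list(values_b)
    if len(set(pooled)) != len(pooled):
        raise ValueError("enumeration oracle requires tie-free data")
    n_a = len(values_a)
    u_obs = mwu_u_statistic(values_a, values_b)
    u_all = [
        mwu_u_statistic(subset, [v for i, v in enumerate(pooled) if i not in idx])
        for idx in map(set, itertools.combinations(range(len(pooled)), n_a))
        for subset in [[pooled[i] for i in idx]]
    ]
    n = len(u_all)
    p_le = sum(1 for u in u_all if u <= u_obs) / n
    p_ge = sum(1 for u in u_all if u >= u_obs) / n
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def bh_stepup(pvalues) -> list[float]:
    """Literal Benjamini-Hochberg step-up: adj_i = min_{j>=rank(i)} m*p_(j)/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, m * pvalues[i] / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def hypergeom_upper_tail(k: int, n_universe: int, n_term: int, n_study: int) -> float:
    """P(X >= k) for X ~ Hypergeom by direct summation of point probabilities."""
    total = 0.0
    for x in range(k, min(n_term, n_study) + 1):
        total += (
            math.comb(n_term, x)
            * math.comb(n_universe - n_term, n_study - x)
            / math.comb(n_universe, n_study)
        )
    return min(1.0, total)
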