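"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic for the discrete tests, direct formula evaluation for the
scores, and exhaustive enumeration for the rank-sum null.
"""

from fractions import Fraction
from itertools import combinations
from math import comb, log2

import numpy as np


def fisher_exact_two_sided(table) -> Fraction:
    """Two-sided Fisher exact p for a 2x2 table by full enumeration of
    the hypergeometric support: sum the probabilities of all tables (with
    the observed margins) no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = prob(x)
        if px <= p_obs:
            total += px
    return total


def hypergeom_sf(k: int, universe: int, category: int, draw: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(universe, category, draw)."""
    denom = comb(universe, draw)
    total = Fraction(0)
    for x in range(k, min(category, draw) + 1):
        total += Fraction(comb(category, x) * comb(universe - category, draw - x),
                          denom)
    return total


def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all assignments of
    the pooled (distinct) values to the first group."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    u_obs = sum(rank[v] for v in x) - n1 * (n1 + 1) / 2
    us = [sum(ranks) - n1 * (n1 + 1) / 2
          for ranks in combinations(range(1, n1 + n2 + 1), n1)]
    total = len(us)
    p_le = sum(u <= u_obs for u in us) / total
    p_ge = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def dysbiosis_direct(values, feature_ids, enriched, depleted, pc) -> np.ndarray:
    """Direct per-sample evaluation of the log2 geometric-mean ratio."""
    idx = {f: j for j, f in enumerate(feature_ids)}
    out = []
    for row in np.asarray(values, dtype=float):
        num = 1.0
        for f in enriched:
            num *= row[idx[f]] + pc
        den = 1.0
        for f in depleted:
            den *= row[idx[f]] + pc
        out.append(log2(num ** (1.0 / len(enriched)))
                   - log2(den ** (1.0 / len(depleted))))
    return np.array(out)


def bh_direct(p) -> np.ndarray:
    """Step-up BH by literal definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        value = min(prev, p[order[i]] * m / rank)
        q[order[i]] = value
        prev = value
    return q
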