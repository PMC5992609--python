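"""Independent brute-force oracles used to pin down expected values.

These deliberately avoid the code paths (and the scipy/statsmodels routines)
they are used to check: Fisher p-values come from explicit hypergeometric
enumeration over all tables with fixed margins, Mann-Whitney p-values from
enumeration of rank arrangements, and the BH adjustment from a literal
transcription of the step-up definition.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """P(top-left cell = a) for a 2x2 table with margins row1, row2, col1."""
    n = row1 + row2
    return comb(row1, a) * comb(row2, col1 - a) / comb(n, col1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: total probability of tables no more likely
    than the observed one, enumerated over the fixed-margin family."""
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    lo, hi = max(0, col1 - row2), min(col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        p_k = hypergeom_pmf(k, row1, row2, col1)
        if p_k <= p_obs * (1 + 1e-9):  # relative guard against float noise
            total += p_k
    return min(1.0, total)


def fisher_one_sided_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher p: P(cell >= a) under the null."""
    row1, row2, col1 = a + b, c + d, a + c
    hi = min(col1, row1)
    return min(1.0, sum(hypergeom_pmf(k, row1, row2, col1) for k in range(a, hi + 1)))


def mannwhitney_exact_less(x, y) -> tuple[float, float]:
    """Exact one-sided Mann-Whitney p (alternative: x smaller) by enumerating
    every assignment of the pooled values' ranks to the x group.

    Requires all values distinct.  Returns (U, p)."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)

    def u_of(ranks):
        return sum(ranks) - n1 * (n1 + 1) / 2

    u_obs = u_of([rank[v] for v in x])
    count = sum(
        1 for subset in combinations(range(1, n1 + n2 + 1), n1) if u_of(subset) <= u_obs
    )
    return u_obs, count / comb(n1 + n2, n1)


def bh_step_up(pvalues) -> list[float]:
    """Benjamini-Hochberg adjusted values, straight from the definition:
    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1, in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        idx = order[pos]
        running_min = min(running_min, p[idx] * m / (pos + 1))
        adjusted[idx] = running_min
    return adjusted.tolist()
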