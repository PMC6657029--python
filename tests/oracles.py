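"""Independent brute-force oracles for the statistical tests.

Each oracle enumerates the exact null distribution directly (label
permutations, sign assignments, hypergeometric tables) without touching
the implementations it checks.
"""

from itertools import combinations

import numpy as np
from scipy.stats import hypergeom


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of labelings.

    Assumes no ties across the pooled sample. Uses the symmetry of the
    null U distribution: p = fraction of labelings at least as far from
    n1*n2/2 as the observed U.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1, n2 = len(x), len(y)
    center = n1 * n2 / 2.0

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    observed = abs(u_stat(x, y) - center)
    count = 0
    total = 0
    for idx in combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - center) >= observed - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact signed-rank p by enumeration of all sign vectors.

    Assumes no zero differences and no tied absolute values.
    """
    d = np.asarray(diffs, dtype=float)
    assert (d != 0).all(), "oracle requires nonzero differences"
    absd = np.abs(d)
    assert len(set(absd)) == len(absd), "oracle requires tie-free |d|"
    ranks = absd.argsort().argsort() + 1
    n = len(d)
    center = n * (n + 1) / 4.0
    observed = abs(float(ranks[d > 0].sum()) - center)
    count = 0
    for mask in range(2**n):
        w_plus = sum(ranks[i] for i in range(n) if (mask >> i) & 1)
        if abs(w_plus - center) >= observed - 1e-12:
            count += 1
    return count / 2**n


def fisher_exact_p(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration: the sum of the
    probabilities of all tables with the same margins whose probability
    does not exceed the observed table's."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    dist = hypergeom(n, row1, col1)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    p_obs = dist.pmf(a)
    return float(
        sum(dist.pmf(k) for k in range(lo, hi + 1) if dist.pmf(k) <= p_obs * (1 + 1e-9))
    )


def bh_stepup(pvalues) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up in the original order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted
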