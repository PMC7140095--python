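"""Independent brute-force oracles used by the test suite.

These deliberately take different computational routes from the package:
exact rational arithmetic from the factorial formula, explicit subset
enumeration, and reference implementations from statsmodels/R.
"""

from fractions import Fraction
from itertools import combinations
from math import factorial


def fisher_2x3_fraction_oracle(table) -> Fraction:
    """Two-sided exact p for a 2x3 table via the factorial-product formula
    P(x) = (r1! r2! c1! c2! c3!) / (N! prod x_ij!) in exact Fractions."""
    (a, b, c), (d, e, f) = table
    r1, r2 = a + b + c, d + e + f
    cols = (a + d, b + e, c + f)
    n = r1 + r2
    const = Fraction(
        factorial(r1) * factorial(r2) * factorial(cols[0]) * factorial(cols[1]) * factorial(cols[2]),
        factorial(n),
    )

    def prob(x11, x12, x13):
        x21, x22, x23 = cols[0] - x11, cols[1] - x12, cols[2] - x13
        denom = 1
        for x in (x11, x12, x13, x21, x22, x23):
            denom *= factorial(x)
        return const / denom

    p_obs = prob(a, b, c)
    total = Fraction(0)
    for x11 in range(min(r1, cols[0]) + 1):
        for x12 in range(min(r1 - x11, cols[1]) + 1):
            x13 = r1 - x11 - x12
            if x13 > cols[2]:
                continue
            p = prob(x11, x12, x13)
            if p <= p_obs:
                total += p
    return total


def fisher_2x3_subset_oracle(table) -> Fraction:
    """Same p by enumerating which of the N samples land in row 1: each
    sample carries its bin label; every C(N, r1) assignment is equally
    likely under the margins.  Only feasible for small N."""
    (a, b, c), (d, e, f) = table
    r1 = a + b + c
    labels = [0] * (a + d) + [1] * (b + e) + [2] * (c + f)
    n = len(labels)
    counts: dict[tuple, int] = {}
    for subset in combinations(range(n), r1):
        t = [0, 0, 0]
        for i in subset:
            t[labels[i]] += 1
        key = tuple(t)
        counts[key] = counts.get(key, 0) + 1
    total_assignments = sum(counts.values())
    obs = counts[(a, b, c)]
    extreme = sum(v for v in counts.values() if v <= obs)
    return Fraction(extreme, total_assignments)


def hypergeom_tail_oracle(M: int, n_set: int, n_query: int, k: int) -> Fraction:
    """P(overlap >= k) by summing the hypergeometric pmf exactly."""
    from math import comb

    total = Fraction(0)
    for j in range(k, min(n_set, n_query) + 1):
        total += Fraction(comb(n_set, j) * comb(M - n_set, n_query - j), comb(M, n_query))
    return total


def bh_stepup_oracle(pvals):
    """Step-up BH applied literally to the order statistics."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj
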