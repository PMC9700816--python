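"""Independent brute-force oracles used only by the test suite.

Each function recomputes a statistic from first principles (enumeration or
direct summation) without touching the package's implementation paths, so the
tests compare two independent routes to the same number.
"""

from __future__ import annotations

import itertools
import math
from math import comb


def hypergeom_prob(a: int, b: int, c: int, d: int) -> float:
    """Probability of the 2x2 table [[a,b],[c,d]] under fixed margins."""
    n = a + b + c + d
    return comb(a + b, a) * comb(c + d, c) / comb(n, a + c)


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p by enumerating all tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_prob(a, b, c, d)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = hypergeom_prob(x, row1 - x, col1 - x, n - row1 - col1 + x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def strand_bias_phred_enum(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> int:
    """Phred-scaled strand bias from the enumerated Fisher probability."""
    if ref_fwd + ref_rev + alt_fwd + alt_rev == 0:
        return 0
    p = fisher_two_sided_enum(ref_fwd, ref_rev, alt_fwd, alt_rev)
    return int(round(-10.0 * math.log10(p)))


def rank_sum_exact_enum(x: list[float], y: list[float]) -> float:
    """Two-sided rank-sum p by enumerating all assignments of pooled values.

    Valid for small untied samples; counts assignments whose rank sum is at
    least as extreme (two-sided, doubling the smaller tail) as observed.
    """
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    observed = sum(ranks[v] for v in x)
    nx = len(x)
    sums = [
        sum(combo)
        for combo in itertools.combinations([ranks[v] for v in pooled], nx)
    ]
    mean = sum(sums) / len(sums)
    dev = abs(observed - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-9)
    return extreme / len(sums)


def binom_sf(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation of the pmf."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        term = comb(n, i) * (p ** i) * ((1 - p) ** (n - i))
        total += term
        if term < 1e-30 and i > n * p:
            break
    return min(total, 1.0)
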