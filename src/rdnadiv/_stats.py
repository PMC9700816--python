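"""Shared statistical helpers: rank-sum tests, Fisher exact, BH adjustment."""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (order-preserving, never decreasing)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Uses the exact null distribution when both samples are small (each at most
    ``exact_max_n``) and untied; otherwise the normal approximation with
    continuity and tie correction. Returns (U statistic of x, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:  # degenerate: all observations tie
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact probability of a 2x2 table (hypergeometric)."""
    return float(stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")[1])


def pairwise_rank_sum(groups: dict[str, Sequence[float]]) -> "pd.DataFrame":
    """All pairwise two-sided rank-sum tests with BH adjustment across pairs."""
    import pandas as pd

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            stat, p = rank_sum_test(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "statistic": stat, "p_raw": p})
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_raw"])
    df["p_adj"] = bh_adjust(df["p_raw"]) if len(df) else df["p_raw"]
    return df
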