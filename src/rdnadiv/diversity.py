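"""Per-site entropy, element summaries, sharing statistics and correlations.

Sequence diversity at each rDNA position is quantified by Shannon's entropy
over the five categories {A, T, G, C, indel}, computed in rDNA *copy* units:
every isolate contributes M_i copies to the pooled total N, and a variant with
frequency iVF in isolate i occupies round(iVF x M_i) of them; the remainder
read the reference base. Entropy is reported in nats and is zero at
monomorphic sites, at most ln(5) overall.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import pairwise_rank_sum
from .errors import DataError
from .pileup import BASE_INDEX
from .prototype import RDNAPrototype

ENTROPY_CATEGORIES = ("A", "C", "G", "T", "indel")
#: element grouping used for sharing comparisons
ELEMENT_GROUPS = {
    "5S": "rRNA", "5.8S": "rRNA", "18S": "rRNA", "25S": "rRNA",
    "ETS1": "ETS+ITS", "ETS2": "ETS+ITS", "ITS1": "ETS+ITS", "ITS2": "ETS+ITS",
    "NTS1": "NTS", "NTS2": "NTS",
}


def entropy_profile(
    calls: pd.DataFrame,
    copy_numbers: Mapping[str, float],
    prototype: RDNAPrototype,
) -> pd.DataFrame:
    """Per-position entropy tally over the cohort, in copy units.

    ``calls`` is a call table (isolate_id, position, ref, alt, ivf); every
    isolate appearing there must have a total copy number in ``copy_numbers``.
    All indel alleles at a position pool into the single "indel" category.
    Returns one row per position: n_A, n_C, n_G, n_T, n_indel, N, H.
    """
    missing = set(calls["isolate_id"]) - set(copy_numbers)
    if missing:
        raise DataError(f"isolates without copy estimates: {sorted(missing)[:5]}")
    L = prototype.unit_length
    N = float(sum(copy_numbers.values()))
    counts = np.zeros((L, 5), dtype=float)
    ref_col = np.fromiter(
        (BASE_INDEX[b] for b in prototype.sequence), dtype=np.int64, count=L
    )
    counts[np.arange(L), ref_col] = N  # start fully reference

    for row in calls.itertuples(index=False):
        m = copy_numbers[row.isolate_id]
        copies = float(round(row.ivf * m))
        pos0 = int(row.position) - 1
        cat = 4 if len(row.ref) != 1 or len(row.alt) != 1 else BASE_INDEX[row.alt]
        counts[pos0, cat] += copies
        counts[pos0, ref_col[pos0]] -= copies
        if counts[pos0, ref_col[pos0]] < -1e-9:
            raise DataError(
                f"position {row.position}: summed variant copies exceed pooled N"
            )
    counts = np.maximum(counts, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / N
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    out = pd.DataFrame(counts, columns=[f"n_{c}" for c in ENTROPY_CATEGORIES])
    out.insert(0, "position", np.arange(1, L + 1))
    out["N"] = N
    out["H"] = np.maximum(h, 0.0)
    return out


def summarize_elements(calls: pd.DataFrame, prototype: RDNAPrototype) -> pd.DataFrame:
    """Element-level summary of a filtered call table.

    A "variant" is a distinct (position, ref, alt); a polymorphic site is a
    position with at least one variant; an iVFP is one (isolate, variant) row.
    SNV/indel splits are reported for variants and iVFPs.
    """
    rows = []
    df = calls.copy()
    df["element"] = [prototype.element_of(int(p)) for p in df["position"]]
    df["is_indel"] = (df["ref"].str.len() != 1) | (df["alt"].str.len() != 1)
    for iv in prototype.elements:
        sub = df[df["element"] == iv.label]
        variants = sub.drop_duplicates(["position", "ref", "alt"])
        rows.append({
            "element": iv.label,
            "length": iv.length,
            "polymorphic_sites": sub["position"].nunique(),
            "polymorphic_fraction": sub["position"].nunique() / iv.length,
            "variants": len(variants),
            "variants_snv": int((~variants["is_indel"]).sum()),
            "variants_indel": int(variants["is_indel"].sum()),
            "ivfps": len(sub),
            "ivfps_snv": int((~sub["is_indel"]).sum()),
            "ivfps_indel": int(sub["is_indel"].sum()),
        })
    return pd.DataFrame(rows)


def sharing_distribution(
    calls: pd.DataFrame, prototype: RDNAPrototype
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Isolates-per-variant distribution by element group plus pairwise tests.

    Elements are pooled into rRNA, ETS+ITS and NTS; each variant contributes
    the number of isolates carrying it. Returns (per-variant table, pairwise
    rank-sum/BH comparison of the three groups).
    """
    df = calls.copy()
    df["element"] = [prototype.element_of(int(p)) for p in df["position"]]
    unknown = set(df["element"]) - set(ELEMENT_GROUPS)
    if unknown:
        raise DataError(f"calls in unannotated/unknown elements: {sorted(unknown)}")
    df["group"] = df["element"].map(ELEMENT_GROUPS)
    sharing = (
        df.groupby(["group", "position", "ref", "alt"])["isolate_id"]
        .nunique()
        .reset_index(name="n_isolates")
    )
    groups = {
        g: sub["n_isolates"].tolist() for g, sub in sharing.groupby("group")
    }
    tests = pairwise_rank_sum(groups) if len(groups) >= 2 else pd.DataFrame()
    return sharing, tests


def nonfixed_variant_count(isolate_calls: pd.DataFrame, total_copies: float) -> int:
    """Variants present in at most M-1 of the isolate's M rDNA copies."""
    if total_copies <= 0:
        raise DataError("total_copies must be positive")
    cutoff = (total_copies - 1.0) / total_copies
    return int((isolate_calls["ivf"] <= cutoff + 1e-12).sum())


def correlate_counts(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Pearson product-moment correlation with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DataError("need paired 1-d vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def ivf_class_counts(calls: pd.DataFrame) -> pd.Series:
    """iVFP counts in the empirical low/mid/high iVF classes."""
    from .filtering import classify_ivf

    classes = calls["ivf"].map(classify_ivf)
    return classes.value_counts().reindex(["low", "mid", "high"], fill_value=0)


def entropy_value(copy_counts: Sequence[float]) -> float:
    """Shannon entropy (nats) of one position's copy counts; scalar convenience."""
    n = np.asarray(copy_counts, dtype=float)
    if (n < 0).any():
        raise DataError("negative copy counts")
    total = n.sum()
    if total == 0:
        return 0.0
    p = n / total
    p = p[p > 0]  # mask after division: tiny counts can underflow to zero
    return float(-(p * np.log(p)).sum())
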