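"""rDNA copy-number estimation and group comparisons.

Each rDNA unit carries one copy of RDN5.8, RDN18 and RDN25, so per-haploid
copy-number estimates of the three genes are averaged and multiplied by ploidy
to give the isolate's total rDNA copy number M. 1/M is the theoretical
frequency of a variant present on exactly one copy ("one-copy iVF"). RDN5
copy numbers are not reported by the source cohort and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import pairwise_rank_sum
from .errors import DataError
from .filtering import one_copy_ivf

HABITATS = ("domesticated", "wild", "human body", "unknown")
ZYGOSITIES = ("haploid", "homozygous", "heterozygous", "polyploid")

METADATA_COLUMNS = [
    "isolate_id", "ploidy", "rdn58", "rdn18", "rdn25", "clade", "niche",
    "habitat", "zygosity", "het_snps_per_kb", "loh",
]


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Total rDNA copies of one isolate, from per-haploid gene estimates x ploidy."""

    isolate_id: str
    per_haploid: tuple[float, float, float]  # RDN5.8, RDN18, RDN25
    ploidy: int

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_haploid):
            raise DataError(f"negative per-haploid copy estimate: {self.per_haploid}")
        if self.ploidy < 1:
            raise DataError(f"ploidy must be >= 1, got {self.ploidy}")

    @property
    def per_haploid_mean(self) -> float:
        return float(np.mean(self.per_haploid))

    @property
    def total_copies(self) -> float:
        """M = mean of the three per-haploid estimates times ploidy."""
        return self.per_haploid_mean * self.ploidy

    @property
    def one_copy_ivf(self) -> float:
        return one_copy_ivf(self.total_copies)


def estimate_total_copies(
    per_haploid: Sequence[float], ploidy: int, isolate_id: str = ""
) -> CopyNumberEstimate:
    """Build a :class:`CopyNumberEstimate` from the (RDN5.8, RDN18, RDN25) triple."""
    triple = tuple(float(v) for v in per_haploid)
    if len(triple) != 3:
        raise DataError(f"expected three per-haploid estimates, got {len(triple)}")
    return CopyNumberEstimate(isolate_id=isolate_id, per_haploid=triple, ploidy=int(ploidy))


@dataclass
class IsolateRecord:
    """Per-isolate metadata: ploidy, copy numbers, labels and heterozygosity."""

    isolate_id: str
    ploidy: int
    copy_estimate: CopyNumberEstimate
    clade: str = "unassigned"
    niche: str = "unknown"
    habitat: str = "unknown"
    zygosity: str = "heterozygous"
    het_snps_per_kb: float = float("nan")
    loss_of_heterozygosity: float = float("nan")

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise DataError("ploidy must be >= 1")
        if self.habitat not in HABITATS:
            raise DataError(f"habitat {self.habitat!r} not in {HABITATS}")
        if self.zygosity not in ZYGOSITIES:
            raise DataError(f"zygosity {self.zygosity!r} not in {ZYGOSITIES}")

    @property
    def total_copies(self) -> float:
        return self.copy_estimate.total_copies


def isolates_to_table(isolates: Iterable[IsolateRecord]) -> pd.DataFrame:
    rows = []
    for iso in isolates:
        r58, r18, r25 = iso.copy_estimate.per_haploid
        rows.append(
            (iso.isolate_id, iso.ploidy, r58, r18, r25, iso.clade, iso.niche,
             iso.habitat, iso.zygosity, iso.het_snps_per_kb, iso.loss_of_heterozygosity)
        )
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def read_isolate_metadata(tsv_path: str | Path) -> list[IsolateRecord]:
    """Read the per-isolate metadata TSV (columns as in ``METADATA_COLUMNS``)."""
    df = pd.read_csv(tsv_path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"metadata TSV missing columns: {sorted(missing)}")
    isolates = []
    for row in df.itertuples(index=False):
        est = estimate_total_copies(
            (row.rdn58, row.rdn18, row.rdn25), int(row.ploidy), str(row.isolate_id)
        )
        isolates.append(
            IsolateRecord(
                isolate_id=str(row.isolate_id), ploidy=int(row.ploidy),
                copy_estimate=est, clade=str(row.clade), niche=str(row.niche),
                habitat=str(row.habitat), zygosity=str(row.zygosity),
                het_snps_per_kb=float(row.het_snps_per_kb),
                loss_of_heterozygosity=float(row.loh),
            )
        )
    return isolates


def write_isolate_metadata(isolates: Iterable[IsolateRecord], tsv_path: str | Path) -> None:
    isolates_to_table(isolates).to_csv(tsv_path, sep="\t", index=False)


def group_median_copies(
    isolates: Sequence[IsolateRecord], group_key: str = "habitat"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median total rDNA copies per group plus pairwise rank-sum comparisons.

    Returns ``(summary, pairwise)``: the summary has one row per group
    (group, n, median M); the pairwise table carries the two-sided Wilcoxon
    rank-sum p-value of every group pair with BH adjustment across pairs.
    Groups with no isolates are dropped.
    """
    values: dict[str, list[float]] = {}
    for iso in isolates:
        key = getattr(iso, "loss_of_heterozygosity" if group_key == "loh" else group_key)
        values.setdefault(str(key), []).append(iso.total_copies)
    values = {g: v for g, v in values.items() if v}
    if len(values) < 2:
        raise DataError("need at least two non-empty groups to compare")
    summary = pd.DataFrame(
        [(g, len(v), float(np.median(v))) for g, v in sorted(values.items())],
        columns=["group", "n", "median_copies"],
    )
    pairwise = pairwise_rank_sum(values)
    return summary, pairwise


def clade_median_copies(isolates: Sequence[IsolateRecord]) -> pd.DataFrame:
    """Median copy number per clade (the clade-level copy-number summary)."""
    df = isolates_to_table(isolates)
    df["total_copies"] = [iso.total_copies for iso in isolates]
    out = (
        df.groupby("clade")["total_copies"]
        .agg(n="size", median_copies="median")
        .reset_index()
    )
    return out
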