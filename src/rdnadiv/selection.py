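"""Structure-stratified selection statistics on the rRNA.

Under a neutral model, iVFPs should distribute across the ribosome's
concentric shells in proportion to how many resolved nucleotides each shell
holds. Per shell i the expected fraction is F_i = n_i / N (shell nucleotides
over resolved subunit total) and the observed fraction is F*_i = m_i / M
(shell iVFPs over the iVF-class total); log10(F*_i / F_i) below zero marks
constrained, above zero relaxed, sequence variability. Calls at structurally
unresolved positions are excluded from both sides of the comparison and
reported in a side channel. Region enrichment (expansion segments, conserved
nucleotide elements) compares inside/outside iVFP counts against the
inside/outside nucleotide split with Fisher exact tests, BH-adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_two_sided, rank_sum_test
from .errors import ConfigError, DataError
from .filtering import classify_ivf
from .prototype import RDNAPrototype, RRNA_GENES
from .structure import SUBUNIT_GENES, StructureAnnotation

IVF_CLASSES = ("low", "mid", "high")
#: sentinel used by report/plot export for shells with zero observed iVFPs
LOG_RATIO_SENTINEL = -2.0


@dataclass
class ShellTally:
    """Observed vs expected iVFP distribution across one subunit's shells."""

    subunit: str
    ivf_class: str
    nucleotides: dict[str, int]  # shell -> resolved nucleotide count n_i
    ivfps: dict[str, int]  # shell -> iVFP count m_i in the class
    excluded: int = 0  # class iVFPs at structurally unresolved positions

    def __post_init__(self) -> None:
        if set(self.ivfps) - set(self.nucleotides):
            raise DataError("iVFP tally contains unknown shells")
        if any(v < 0 for v in self.nucleotides.values()) or any(
            v < 0 for v in self.ivfps.values()
        ):
            raise DataError("negative tally counts")

    @property
    def total_nucleotides(self) -> int:
        """N: resolved nucleotides of the subunit."""
        return sum(self.nucleotides.values())

    @property
    def total_ivfps(self) -> int:
        """M: class iVFPs at resolved positions."""
        return sum(self.ivfps.values())

    def expected_fraction(self, shell: str) -> float:
        return self.nucleotides[shell] / self.total_nucleotides

    def observed_fraction(self, shell: str) -> float:
        if self.total_ivfps == 0:
            return 0.0
        return self.ivfps.get(shell, 0) / self.total_ivfps

    def log_ratio(self, shell: str) -> float | None:
        """log10(F*_i/F_i); None (undefined) when the shell has no iVFPs."""
        return shell_log_ratio(self.observed_fraction(shell), self.expected_fraction(shell))

    def to_table(self, sentinel: bool = False) -> pd.DataFrame:
        """One row per shell; ``sentinel=True`` substitutes -2 for undefined
        log ratios (presentation convention for plots/reports only)."""
        rows = []
        for shell in self.nucleotides:
            lr = self.log_ratio(shell)
            rows.append({
                "subunit": self.subunit, "ivf_class": self.ivf_class, "shell": shell,
                "n_nucleotides": self.nucleotides[shell],
                "m_ivfps": self.ivfps.get(shell, 0),
                "expected_fraction": self.expected_fraction(shell),
                "observed_fraction": self.observed_fraction(shell),
                "log10_ratio": (LOG_RATIO_SENTINEL if lr is None and sentinel else lr),
            })
        return pd.DataFrame(rows)


def shell_log_ratio(f_star: float, f: float) -> float | None:
    """log10(F*/F): the constrained (<0) vs relaxed (>0) variability metric.

    Undefined (``None``) when F* = 0; a presentation layer may substitute the
    -2 sentinel. F = 0 is a domain error (an empty shell has no expectation).
    """
    if f <= 0:
        raise DataError("expected fraction F must be positive")
    if f_star == 0:
        return None
    return math.log10(f_star / f)


def _gene_local_calls(
    calls: pd.DataFrame, prototype: RDNAPrototype
) -> pd.DataFrame:
    """Restrict a call table to rRNA genes and add gene/local-position columns."""
    df = calls.copy()
    df["element"] = [prototype.element_of(int(p)) for p in df["position"]]
    df = df[df["element"].isin(RRNA_GENES)].copy()
    locals_ = [prototype.to_gene_coordinate(int(p))[1] for p in df["position"]]
    df["gene"] = df["element"]
    df["local_position"] = locals_
    return df


def shell_tally(
    calls: pd.DataFrame,
    annotation: StructureAnnotation,
    prototype: RDNAPrototype,
    subunit: str,
    ivf_class: str,
) -> ShellTally:
    """Tally one subunit's iVFPs of one iVF class across shells.

    ``calls`` is a (filtered) call table; rows outside rRNA genes or outside
    the requested subunit are ignored, rows at unresolved positions are
    counted in the ``excluded`` side channel.
    """
    if ivf_class not in IVF_CLASSES:
        raise ConfigError(f"ivf_class must be one of {IVF_CLASSES}")
    genes = set(SUBUNIT_GENES[subunit])
    df = _gene_local_calls(calls, prototype)
    df = df[df["gene"].isin(genes)]
    df = df[df["ivf"].map(classify_ivf) == ivf_class]
    nucleotides = annotation.shell_nucleotide_counts(subunit)
    ivfps = {shell: 0 for shell in nucleotides}
    excluded = 0
    for row in df.itertuples(index=False):
        shell = annotation.shell_at(row.gene, int(row.local_position))
        if shell is None:
            excluded += 1
        else:
            ivfps[shell] += 1
    return ShellTally(
        subunit=subunit, ivf_class=ivf_class,
        nucleotides=nucleotides, ivfps=ivfps, excluded=excluded,
    )


def all_shell_tallies(
    calls: pd.DataFrame, annotation: StructureAnnotation, prototype: RDNAPrototype
) -> list[ShellTally]:
    """Shell tallies for every (subunit, iVF class) combination."""
    return [
        shell_tally(calls, annotation, prototype, su, cls)
        for su in SUBUNIT_GENES
        for cls in IVF_CLASSES
    ]


def shell_skew_test(tallies: Sequence[ShellTally]) -> pd.DataFrame:
    """Rank-sum skew test per tally, BH-adjusted across the family.

    The observed sample is the shell ordinal of each counted iVFP; the
    expected sample is the shell ordinal of each resolved nucleotide. Shell
    ordinals are massively tied, so the tie-corrected normal approximation is
    the applicable method. Tallies with zero iVFPs are skipped and flagged.
    """
    rows = []
    for t in tallies:
        ordinals = {shell: i + 1 for i, shell in enumerate(t.nucleotides)}
        observed = np.repeat(
            [ordinals[s] for s in t.nucleotides], [t.ivfps.get(s, 0) for s in t.nucleotides]
        )
        expected = np.repeat(
            [ordinals[s] for s in t.nucleotides], [t.nucleotides[s] for s in t.nucleotides]
        )
        if len(observed) == 0:
            rows.append({"subunit": t.subunit, "ivf_class": t.ivf_class,
                         "n_ivfps": 0, "p_raw": np.nan, "skipped": True})
            continue
        _, p = rank_sum_test(observed, expected)
        rows.append({"subunit": t.subunit, "ivf_class": t.ivf_class,
                     "n_ivfps": int(len(observed)), "p_raw": p, "skipped": False})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    tested = ~df["skipped"]
    if tested.any():
        df.loc[tested, "p_adj"] = bh_adjust(df.loc[tested, "p_raw"].to_numpy())
    return df


# -- region enrichment --------------------------------------------------------------

#: Fig. 5e-style iVF bins: (label, inclusive lower, exclusive upper)
DEFAULT_IVF_CUTOFFS = (
    ("lt1pct", 0.005, 0.01),
    ("1to5pct", 0.01, 0.05),
    ("5to95pct", 0.05, 0.95),
    ("ge95pct", 0.95, 1.0000001),
)


@dataclass
class RegionTally:
    """Inside/outside iVFP accounting for one named region set."""

    region: str
    genes: tuple[str, ...]
    n_inside: int  # region nucleotides n
    n_outside: int  # remaining universe nucleotides N
    per_cutoff: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def expected_inside_fraction(self) -> float:
        return self.n_inside / (self.n_inside + self.n_outside)

    @property
    def expected_outside_fraction(self) -> float:
        return self.n_outside / (self.n_inside + self.n_outside)


def region_enrichment(
    calls: pd.DataFrame,
    annotation: StructureAnnotation,
    prototype: RDNAPrototype,
    region: str,
    genes: Sequence[str] | None = None,
    cutoffs: Sequence[tuple[str, float, float]] = DEFAULT_IVF_CUTOFFS,
) -> RegionTally:
    """Observed vs expected iVFP fractions inside/outside a named region.

    The nucleotide universe is the full sequence of ``genes`` (default: the
    genes the region set touches); expected fractions are n/(n+N) and N/(n+N),
    observed fractions are m_i/(m_i+M_i) and M_i/(m_i+M_i) per iVF cutoff, and
    each cutoff gets a two-sided Fisher exact test of (m_i, M_i) vs (n, N),
    BH-adjusted across cutoffs.
    """
    if region not in annotation.region_sets or not annotation.region_sets[region]:
        raise ConfigError(f"region set {region!r} is missing or empty")
    positions = annotation.region_sets[region]
    if genes is None:
        genes = tuple(sorted({g for g, _ in positions}))
    genes = tuple(genes)
    universe = sum(annotation.gene_lengths[g] for g in genes)
    inside_set = {(g, p) for g, p in positions if g in genes}
    n_inside = len(inside_set)
    n_outside = universe - n_inside

    df = _gene_local_calls(calls, prototype)
    df = df[df["gene"].isin(genes)].copy()
    df["inside"] = [
        (g, int(p)) in inside_set for g, p in zip(df["gene"], df["local_position"])
    ]
    rows = []
    for label, lo, hi in cutoffs:
        sub = df[(df["ivf"] >= lo) & (df["ivf"] < hi)]
        m_in = int(sub["inside"].sum())
        m_out = int(len(sub) - m_in)
        p = fisher_exact_two_sided([[m_in, m_out], [n_inside, n_outside]])
        denom = m_in + m_out
        rows.append({
            "cutoff": label, "ivf_lo": lo, "ivf_hi": hi,
            "m_inside": m_in, "m_outside": m_out,
            "observed_inside_fraction": m_in / denom if denom else 0.0,
            "observed_outside_fraction": m_out / denom if denom else 0.0,
            "p_raw": p,
        })
    per_cutoff = pd.DataFrame(rows)
    per_cutoff["p_adj"] = bh_adjust(per_cutoff["p_raw"].to_numpy())
    return RegionTally(
        region=region, genes=genes, n_inside=n_inside, n_outside=n_outside,
        per_cutoff=per_cutoff,
    )


def bridge_proximity_report(
    calls: pd.DataFrame,
    annotation: StructureAnnotation,
    prototype: RDNAPrototype,
    bridge_region: str = "bridge_proximal",
    interface_region: str = "rp_interface",
) -> tuple[pd.DataFrame, dict]:
    """Mid/high-iVF calls near intersubunit bridges, and an iVF comparison
    inside vs outside ribosomal-protein interfaces.

    Proximity sets are consumed as annotations; no distances are computed.
    Returns (qualifying-call table, rank-sum comparison summary).
    """
    df = _gene_local_calls(calls, prototype).copy()
    df["ivf_class"] = df["ivf"].map(classify_ivf) if len(df) else pd.Series(dtype=object)
    bridges = annotation.region_sets.get(bridge_region, set())
    interfaces = annotation.region_sets.get(interface_region, set())
    in_bridge = pd.Series(
        [(g, int(p)) in bridges for g, p in zip(df["gene"], df["local_position"])],
        index=df.index, dtype=bool,
    )
    in_interface = pd.Series(
        [(g, int(p)) in interfaces for g, p in zip(df["gene"], df["local_position"])],
        index=df.index, dtype=bool,
    )
    near = df[df["ivf_class"].isin(("mid", "high")) & in_bridge][
        ["isolate_id", "position", "gene", "local_position", "ref", "alt", "ivf", "ivf_class"]
    ]
    inside = df.loc[in_interface, "ivf"].to_numpy()
    outside = df.loc[~in_interface, "ivf"].to_numpy()
    comparison: dict = {
        "n_inside": int(len(inside)), "n_outside": int(len(outside)),
        "p_value": np.nan,
    }
    if len(inside) and len(outside):
        _, p = rank_sum_test(inside, outside)
        comparison["p_value"] = p
    return near.reset_index(drop=True), comparison
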