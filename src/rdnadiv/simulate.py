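"""Synthetic cohorts of isolates with heterogeneous rDNA copies.

The generator emulates the study conditions of a deep-sequenced yeast cohort:
isolates with ploidies 1-5, per-haploid rDNA copy numbers in a realistic
range, clade/niche/habitat labels, and spiked variants with known target iVFs.
Because variants occupy whole rDNA copies, every true iVF is a lattice value
k/M for the isolate's total copy number M. Per-isolate pileups are simulated
with Poisson depth, binomial allele sampling, a strand-symmetric uniform
miscall error model and a fair-coin strand assignment — plus truth tables for
benchmark scoring. Same seed, same output, bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .copynumber import CopyNumberEstimate, IsolateRecord, estimate_total_copies
from .errors import ConfigError, DataError
from .pileup import BASE_INDEX, BASES, PileupMatrix
from .prototype import ElementInterval, RDNAPrototype

TRUTH_COLUMNS = [
    "isolate_id", "position", "ref", "alt", "true_ivf", "element",
    "coupled_group", "promoted",
]


# -- synthetic prototype ------------------------------------------------------------

#: element layout of the synthetic prototype: NTS before the 35S transcription
#: unit, rRNA gene lengths matching the reference strain (25S 3396, 18S 1800,
#: 5.8S 158, 5S 121), spacer lengths approximate. Unit length 9137.
SYNTHETIC_ELEMENT_LENGTHS = [
    ("NTS1", 1359), ("5S", 121), ("NTS2", 800), ("ETS1", 700), ("18S", 1800),
    ("ITS1", 361), ("5.8S", 158), ("ITS2", 232), ("25S", 3396), ("ETS2", 210),
]


def synthetic_prototype(seed: int = 20220901) -> RDNAPrototype:
    """A synthetic ~9.1 kb rDNA unit with realistic element layout.

    The sequence is random (seeded); a 12-nt poly(A) stretch is embedded in
    NTS1 so that the poly-stretch filter rule has real targets. Element
    boundaries are approximate stand-ins, not the deposited annotation.
    """
    rng = np.random.default_rng(seed)
    length = sum(n for _, n in SYNTHETIC_ELEMENT_LENGTHS)
    seq = rng.choice(list(BASES), size=length)
    seq[600:612] = "A"  # poly stretch inside NTS1 (positions 601-612)
    seq[599] = "C"  # pin the run boundaries so the stretch is exactly 12 nt
    seq[612] = "C"
    elements = []
    start = 1
    for label, n in SYNTHETIC_ELEMENT_LENGTHS:
        elements.append(ElementInterval(label, start, start + n - 1))
        start += n
    return RDNAPrototype(sequence="".join(seq), elements=elements, name="rDNA_synthetic")


# -- cohort configuration -----------------------------------------------------------


@dataclass(frozen=True)
class VariantSpec:
    """One spiked variant: where, what, at which iVF, in which fraction of isolates."""

    position: int
    alt: str
    ivf: float | tuple[float, float]  # fixed value or uniform (low, high)
    sharing: float = 1.0  # fraction of isolates carrying the variant
    ref: str | None = None  # filled from the prototype when None

    def draw_ivf(self, rng: np.random.Generator) -> float:
        if isinstance(self.ivf, tuple):
            lo, hi = self.ivf
            return float(rng.uniform(lo, hi))
        return float(self.ivf)


@dataclass(frozen=True)
class CoupledPairSpec:
    """Two variants that ride the same rDNA copies: one common iVF per isolate."""

    first: VariantSpec
    second: VariantSpec
    sharing: float = 1.0
    ivf: float | tuple[float, float] = (0.1, 0.9)

    def draw_ivf(self, rng: np.random.Generator) -> float:
        if isinstance(self.ivf, tuple):
            return float(rng.uniform(*self.ivf))
        return float(self.ivf)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the real cohort: mostly diploid isolates (with a haploid
    minority and a tail of higher ploidies), per-haploid copy numbers giving
    total M of roughly 120-260, ~3000-fold rDNA coverage and a 0.1% per-base
    miscall rate.
    """

    n_isolates: int = 20
    ploidy_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.14, 2: 0.76, 3: 0.06, 4: 0.03, 5: 0.01}
    )
    copy_number_range: tuple[float, float] = (60.0, 130.0)  # per haploid
    clades: tuple[str, ...] = ("clade1", "clade2", "clade3")
    niches: tuple[str, ...] = ("wine", "dairy", "soil")
    habitats: tuple[str, ...] = ("domesticated", "wild", "human body", "unknown")
    variants: tuple[VariantSpec, ...] = ()
    coupled_pairs: tuple[CoupledPairSpec, ...] = ()
    error_rate: float = 0.001
    rdna_coverage: float = 3000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_isolates < 1:
            raise ConfigError("n_isolates must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigError("error_rate must be in [0, 0.05]")
        if self.rdna_coverage <= 0:
            raise ConfigError("rdna_coverage must be positive")
        if any(p < 1 or p > 5 for p in self.ploidy_weights):
            raise ConfigError("ploidies must be in 1..5")
        lo, hi = self.copy_number_range
        if not 0 < lo <= hi:
            raise ConfigError("invalid copy_number_range")
        for spec in self._all_variant_specs():
            ivfs = spec.ivf if isinstance(spec.ivf, tuple) else (spec.ivf, spec.ivf)
            if not all(0.0 < v <= 1.0 for v in ivfs):
                raise ConfigError(f"target iVF out of (0,1]: {spec.ivf}")
            if not 0.0 <= spec.sharing <= 1.0:
                raise ConfigError("sharing fraction must be in [0,1]")

    def _all_variant_specs(self) -> list[VariantSpec]:
        out = list(self.variants)
        for pair in self.coupled_pairs:
            out.extend([pair.first, pair.second])
        return out


# -- cohort generation --------------------------------------------------------------


def _lattice_ivf(target: float, total_copies: float) -> tuple[float, bool]:
    """Round a target iVF to the nearest whole-copy multiple of 1/M.

    M is the isolate's copy-number estimate rounded to the nearest integer
    (variants occupy whole copies, so the lattice denominator must be an
    integer count). Requests below the one-copy frequency 1/M are promoted to
    exactly one copy and flagged as promoted.
    """
    m_int = max(int(round(total_copies)), 1)
    promoted = target * m_int < 1.0 - 1e-9
    copies = min(max(int(round(target * m_int)), 1), m_int)
    return copies / m_int, promoted


def generate_cohort(
    config: CohortConfig, prototype: RDNAPrototype
) -> tuple[list[IsolateRecord], pd.DataFrame]:
    """Draw a cohort and its ground-truth variant table. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    ploidies = sorted(config.ploidy_weights)
    weights = np.array([config.ploidy_weights[p] for p in ploidies], dtype=float)
    weights /= weights.sum()

    isolates: list[IsolateRecord] = []
    for i in range(config.n_isolates):
        ploidy = int(rng.choice(ploidies, p=weights))
        base = rng.uniform(*config.copy_number_range)
        triple = np.maximum(base * (1.0 + rng.normal(0.0, 0.03, size=3)), 1.0)
        est = estimate_total_copies(triple, ploidy, f"ISO{i:04d}")
        zygosity = (
            "haploid" if ploidy == 1
            else "polyploid" if ploidy > 2
            else ("homozygous" if rng.random() < 0.2 else "heterozygous")
        )
        isolates.append(
            IsolateRecord(
                isolate_id=f"ISO{i:04d}", ploidy=ploidy, copy_estimate=est,
                clade=str(rng.choice(config.clades)),
                niche=str(rng.choice(config.niches)),
                habitat=str(rng.choice(config.habitats)),
                zygosity=zygosity,
                het_snps_per_kb=float(rng.gamma(2.0, 1.2)) if zygosity == "heterozygous" else 0.0,
                loss_of_heterozygosity=float(rng.uniform(0, 1)),
            )
        )

    rows: list[tuple] = []
    counter = itertools.count(1)

    def add_row(iso: IsolateRecord, spec: VariantSpec, target: float, group) -> None:
        ref = spec.ref or prototype.sequence[spec.position - 1]
        if not spec.alt or (len(spec.alt) == 1 == len(ref) and spec.alt == ref):
            raise ConfigError(f"variant at {spec.position} has alt equal to ref")
        true_ivf, promoted = _lattice_ivf(target, iso.total_copies)
        rows.append(
            (iso.isolate_id, spec.position, ref, spec.alt, true_ivf,
             prototype.element_of(spec.position), group, promoted)
        )

    for spec in config.variants:
        carriers = [iso for iso in isolates if rng.random() < spec.sharing]
        for iso in carriers:
            add_row(iso, spec, spec.draw_ivf(rng), None)
    for pair in config.coupled_pairs:
        group = f"pair{next(counter)}"
        carriers = [iso for iso in isolates if rng.random() < pair.sharing]
        for iso in carriers:
            common = pair.draw_ivf(rng)
            # both members of the pair receive the identical lattice iVF
            add_row(iso, pair.first, common, group)
            add_row(iso, pair.second, common, group)

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    _validate_truth(truth, isolates)
    return isolates, truth


def _validate_truth(truth: pd.DataFrame, isolates: Sequence[IsolateRecord]) -> None:
    """Alt copies at one position of one isolate must not exceed its M."""
    if truth.empty:
        return
    m_of = {iso.isolate_id: iso.total_copies for iso in isolates}
    grouped = truth.groupby(["isolate_id", "position"])["true_ivf"].sum()
    for (iso_id, position), total in grouped.items():
        if total > 1.0 + 1e-9:
            raise DataError(
                f"{iso_id} position {position}: summed variant copies exceed M={m_of[iso_id]}"
            )


# -- pileup simulation --------------------------------------------------------------


def simulate_pileup(
    prototype: RDNAPrototype,
    truth: pd.DataFrame,
    coverage: float,
    error_rate: float,
    seed: int,
    isolate_id: str = "sim",
    alt_strand_fraction: float = 0.5,
    coverage_profile: np.ndarray | None = None,
) -> PileupMatrix:
    """Simulate one isolate's strand-split pileup from its truth rows.

    Depth per position is Poisson(coverage x profile); variant-supporting reads
    are multinomial across the position's variants with the remainder reading
    reference; each non-variant read is miscalled to a uniformly chosen other
    base with probability ``error_rate``; strands are fair coins except that
    variant reads use ``alt_strand_fraction`` (a configurable strand-bias knob).
    """
    if coverage <= 0:
        raise ConfigError("coverage must be positive")
    rng = np.random.default_rng(seed)
    L = prototype.unit_length
    lam = np.full(L, float(coverage))
    if coverage_profile is not None:
        profile = np.asarray(coverage_profile, dtype=float)
        if profile.shape != (L,) or (profile < 0).any():
            raise ConfigError("coverage_profile must be a non-negative length-L vector")
        lam = lam * profile
    depth = rng.poisson(lam)

    base_counts = np.zeros((L, 4, 2), dtype=np.int64)
    indel_counts: dict[tuple[int, str, str], tuple[int, int]] = {}
    ref_reads = depth.copy()  # reads left reading the reference at each position

    if len(truth):
        for position, rows in truth.groupby("position"):
            ivfs = rows["true_ivf"].to_numpy(dtype=float)
            if ivfs.sum() > 1.0 + 1e-9:
                raise DataError(f"variant iVFs at position {position} exceed 1")
            n = int(depth[position - 1])
            counts = rng.multinomial(n, np.append(ivfs, max(1.0 - ivfs.sum(), 0.0)))
            for (row, k) in zip(rows.itertuples(index=False), counts[:-1]):
                if k == 0:
                    continue
                fwd = int(rng.binomial(k, alt_strand_fraction))
                if len(row.ref) == 1 == len(row.alt):
                    base_counts[position - 1, BASE_INDEX[row.alt], 0] += fwd
                    base_counts[position - 1, BASE_INDEX[row.alt], 1] += int(k) - fwd
                else:
                    key = (int(position), row.ref, row.alt)
                    f0, r0 = indel_counts.get(key, (0, 0))
                    indel_counts[key] = (f0 + fwd, r0 + int(k) - fwd)
            ref_reads[position - 1] = n - int(counts[:-1].sum())

    # error model: miscall each remaining reference read with prob error_rate,
    # uniformly into the three other bases; vectorized per reference base
    miscalled = rng.binomial(ref_reads, error_rate) if error_rate > 0 else np.zeros(L, dtype=np.int64)
    correct = ref_reads - miscalled
    totals = np.zeros((L, 4), dtype=np.int64)
    ref_idx = np.fromiter((BASE_INDEX[b] for b in prototype.sequence), dtype=np.int64, count=L)
    totals[np.arange(L), ref_idx] += correct
    if error_rate > 0:
        for b in range(4):
            sel = ref_idx == b
            if not sel.any():
                continue
            others = [j for j in range(4) if j != b]
            split = rng.multinomial(miscalled[sel], [1 / 3] * 3)
            for col, j in enumerate(others):
                totals[sel, j] += split[:, col]
    fwd = rng.binomial(totals, 0.5)
    base_counts[:, :, 0] += fwd
    base_counts[:, :, 1] += totals - fwd
    return PileupMatrix(
        isolate_id=isolate_id, reference=prototype.sequence,
        base_counts=base_counts, indel_counts=indel_counts,
    )


# -- spike-in titration -------------------------------------------------------------


def make_titration(
    prototype: RDNAPrototype,
    background_truth: pd.DataFrame,
    spike_truth: pd.DataFrame,
    frequencies: Sequence[float],
    coverage: float,
    error_rate: float,
    seed: int,
) -> list[tuple[float, PileupMatrix, pd.DataFrame]]:
    """Mix a spike isolate into a background isolate at a series of frequencies.

    At spike frequency f the expected iVF of a spike-only ("tracked") variant is
    f times its iVF in the pure spike isolate; background variants scale by
    (1-f). Returns one (frequency, pileup, truth) triple per frequency, where
    the truth table carries a boolean ``tracked`` column.
    """
    for f in frequencies:
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"spike frequency {f} outside [0,1]")
    spike_keys = set(zip(spike_truth["position"], spike_truth["alt"]))
    bg_keys = set(zip(background_truth["position"], background_truth["alt"])) if len(background_truth) else set()
    out = []
    for i, f in enumerate(frequencies):
        parts = []
        if len(spike_truth) and f > 0:
            s = spike_truth.copy()
            s["true_ivf"] = s["true_ivf"] * f
            parts.append(s)
        if len(background_truth) and f < 1:
            b = background_truth.copy()
            b["true_ivf"] = b["true_ivf"] * (1.0 - f)
            parts.append(b)
        mixed = (
            pd.concat(parts, ignore_index=True)
            .groupby(["position", "ref", "alt"], as_index=False)
            .agg(true_ivf=("true_ivf", "sum"),
                 element=("element", "first"),
                 coupled_group=("coupled_group", "first"),
                 promoted=("promoted", "any"))
            if parts else pd.DataFrame(columns=TRUTH_COLUMNS[1:])
        )
        mixed.insert(0, "isolate_id", f"mix_{f:g}")
        mixed["tracked"] = [
            (p, a) in spike_keys and (p, a) not in bg_keys
            for p, a in zip(mixed["position"], mixed["alt"])
        ]
        pile = simulate_pileup(
            prototype, mixed, coverage, error_rate,
            seed=seed + i, isolate_id=f"mix_{f:g}",
        )
        out.append((float(f), pile, mixed))
    return out


# -- auxiliary synthetic covariates -------------------------------------------------


def synthetic_variant_het_counts(
    n: int, r_true: float, seed: int,
    mean_variants: float = 13.0, sd_variants: float = 8.0,
    mean_het: float = 2.0, sd_het: float = 1.2,
) -> pd.DataFrame:
    """Per-isolate (rDNA variant count, het SNPs/kb) pairs with a set correlation.

    Bivariate normal with correlation ``r_true``, shifted/scaled to realistic
    marginals and floored at zero; used for correlation parameter-recovery
    checks at cohort scale.
    """
    rng = np.random.default_rng(seed)
    cov = [[1.0, r_true], [r_true, 1.0]]
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    variants = np.maximum(mean_variants + sd_variants * z[:, 0], 0.0)
    het = np.maximum(mean_het + sd_het * z[:, 1], 0.0)
    return pd.DataFrame({"n_variants": variants, "het_snps_per_kb": het})
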