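"""The variant filter cascade, iVF classes and replicate deduplication.

Raw low-frequency calls on the rDNA are dominated by alignment edge effects,
homopolymer slippage and strand artifacts. The cascade keeps a call only if
all of the following hold, and attributes each removal to the first failing
rule in this order:

1. ``position_bounds`` — unit position strictly between 10 and 9100
   (avoids end effects of the circularly permuted prototype);
2. ``min_ivf`` — iVF strictly above 0.005;
3. ``homopolymer_run`` — reference homopolymer run at the site shorter than 4;
4. ``long_indel_gc`` — indels longer than 5 nt are dropped when the GC
   fraction of the event sequence (allele minus the shared anchor base)
   reaches 0.6 in either allele;
5. ``poly_stretch`` — position not inside any 10-nt single-base stretch of
   the prototype;
6. ``one_copy`` — when enabled, iVF strictly above the isolate's theoretical
   one-copy frequency 1/M (variants below one rDNA copy are unresolvable);
7. ``strand_bias`` — phred-scaled strand bias below 144.

The cascade is idempotent and monotone; the report reconciles exactly
(input = output + sum of per-rule removals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, DataError
from .prototype import RDNAPrototype, indel_homopolymer_run
from .variants import VariantCall

RULE_ORDER = (
    "position_bounds",
    "min_ivf",
    "homopolymer_run",
    "long_indel_gc",
    "poly_stretch",
    "one_copy",
    "strand_bias",
)


def one_copy_ivf(total_copies: float) -> float:
    """Theoretical frequency of a variant occupying exactly one of M rDNA copies."""
    if total_copies <= 0:
        raise DataError(f"total copy number must be positive, got {total_copies}")
    return 1.0 / total_copies


def classify_ivf(ivf: float) -> str:
    """Empirical iVF class: low (<5%), mid (5% to <95%), high (>=95%)."""
    if ivf < 0.05:
        return "low"
    if ivf < 0.95:
        return "mid"
    return "high"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filter cascade (defaults are the published cascade)."""

    min_position: int = 10  # keep if position > min_position (exclusive)
    max_position: int = 9100  # keep if position < max_position (exclusive)
    min_ivf: float = 0.005  # keep if ivf > min_ivf (exclusive)
    max_homopolymer_run: int = 4  # keep if run < 4
    long_indel_len: int = 5  # GC rule applies to indels longer than this
    max_indel_gc: float = 0.6  # drop long indel if any event-sequence GC >= this
    poly_stretch_len: int = 10
    sb_phred_cutoff: int = 144  # drop if sb_phred >= this
    apply_one_copy_threshold: bool = False

    def __post_init__(self) -> None:
        if self.min_position >= self.max_position:
            raise ConfigError("min_position must be below max_position")
        for name in ("min_ivf", "max_homopolymer_run", "long_indel_len",
                     "max_indel_gc", "poly_stretch_len", "sb_phred_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class FilterReport:
    """Per-rule removal counts; reconciles exactly with input/output totals."""

    input_total: int = 0
    output_total: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def reconciles(self) -> bool:
        return self.input_total == self.output_total + sum(self.removed.values())


def _gc_fraction(seq: str) -> float:
    return sum(1 for b in seq if b in "GC") / len(seq) if seq else 0.0


def _failing_rule(
    call: VariantCall,
    prototype: RDNAPrototype,
    one_copy: float | None,
    cfg: FilterConfig,
    poly_positions: frozenset[int],
) -> str | None:
    """First failing rule name in cascade order, or None if the call is kept."""
    if not cfg.min_position < call.position < cfg.max_position:
        return "position_bounds"
    if not call.ivf > cfg.min_ivf:
        return "min_ivf"
    if call.hrun is not None:
        hrun = call.hrun  # HRUN from the input VCF takes precedence
    elif call.is_indel:
        hrun = indel_homopolymer_run(prototype.sequence, call.position)
    else:
        hrun = prototype.homopolymer_run(call.position)
    if not hrun < cfg.max_homopolymer_run:
        return "homopolymer_run"
    if call.is_indel and call.indel_length > cfg.long_indel_len:
        # GC is evaluated on the event sequence: the allele string minus the
        # shared left anchor (an anchored insertion REF is a single base whose
        # GC fraction would be degenerate)
        events = [s[1:] for s in (call.ref_seq, call.alt_seq) if len(s) > 1]
        if any(_gc_fraction(s) >= cfg.max_indel_gc for s in events):
            return "long_indel_gc"
    if call.position in poly_positions:
        return "poly_stretch"
    if cfg.apply_one_copy_threshold:
        if one_copy is None:
            raise ConfigError(
                "one-copy threshold enabled but no copy-number estimate supplied"
            )
        if not call.ivf > one_copy:
            return "one_copy"
    if call.sb_phred >= cfg.sb_phred_cutoff:
        return "strand_bias"
    return None


def apply_filter_cascade(
    calls: Sequence[VariantCall],
    prototype: RDNAPrototype,
    copy_estimate: "CopyNumberEstimate | float | None" = None,
    config: FilterConfig | None = None,
) -> tuple[list[VariantCall], FilterReport]:
    """Apply the filter cascade; returns (kept calls, reconciled report).

    ``copy_estimate`` may be a :class:`~rdnadiv.copynumber.CopyNumberEstimate`
    or the total copy number M directly; it is required only when the one-copy
    threshold is enabled.
    """
    cfg = config or FilterConfig()
    one_copy: float | None = None
    if copy_estimate is not None:
        total = getattr(copy_estimate, "total_copies", copy_estimate)
        one_copy = one_copy_ivf(float(total))
    poly_positions = prototype.poly_stretch_positions(cfg.poly_stretch_len)
    report = FilterReport(input_total=len(calls))
    kept: list[VariantCall] = []
    for call in calls:
        rule = _failing_rule(call, prototype, one_copy, cfg, poly_positions)
        if rule is None:
            kept.append(call)
        else:
            report.removed[rule] += 1
    report.output_total = len(kept)
    assert report.reconciles()
    return kept, report


def filter_eligible_positions(
    prototype: RDNAPrototype,
    config: FilterConfig | None = None,
    for_indel: bool = False,
) -> list[int]:
    """Unit positions where a true variant could survive the position-dependent
    rules of the cascade (bounds, homopolymer run, poly stretches).

    Used by the benchmark harness to place spike-in variants so that measured
    sensitivity reflects the caller rather than deterministic position filters.
    """
    cfg = config or FilterConfig()
    poly = prototype.poly_stretch_positions(cfg.poly_stretch_len)
    out = []
    for pos in range(cfg.min_position + 1, min(cfg.max_position, prototype.unit_length + 1)):
        if pos in poly:
            continue
        run = (
            indel_homopolymer_run(prototype.sequence, pos)
            if for_indel
            else prototype.homopolymer_run(pos)
        )
        if run >= cfg.max_homopolymer_run:
            continue
        out.append(pos)
    return out


def deduplicate_replicates(
    groups: Mapping[str, Iterable[tuple[str, float]]],
) -> dict[str, str]:
    """Pick one sample per replicate group: highest mean coverage wins.

    ``groups`` maps a group key to (sample_id, mean_coverage) pairs. Coverage
    ties break to the lexicographically first sample id.
    """
    selected: dict[str, str] = {}
    for group, samples in groups.items():
        samples = list(samples)
        if not samples:
            raise DataError(f"replicate group {group!r} is empty")
        selected[group] = min(samples, key=lambda s: (-s[1], s[0]))[0]
    return selected
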