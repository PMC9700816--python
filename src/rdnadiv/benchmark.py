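"""Pipeline-performance benchmarks on synthetic data.

Two harnesses mirror the published evaluation design: a spike-in titration
(one isolate's high-iVF variants mixed into a variant-free background at a
frequency series) and a simulated-dataset benchmark (a fixed number of SNVs
and indels spiked at a low target iVF across coverage tiers). Both run the
full caller + filter cascade and score recovery exactly against the truth
table: a call matches a truth variant iff it has the same unit position, the
same ref and the same alt allele (both sides use the left-anchored indel
representation). Claims produced here are properties of this pipeline on this
simulator, not byte-level reproductions of any external tool chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import call_variants
from .errors import ConfigError
from .filtering import FilterConfig, apply_filter_cascade, filter_eligible_positions
from .pileup import BASES
from .prototype import RDNAPrototype
from .simulate import TRUTH_COLUMNS, make_titration, simulate_pileup
from .variants import VariantCall, calls_to_table


@dataclass
class BenchmarkResult:
    """Recovery metrics for one benchmark condition (frequency or coverage)."""

    condition: float
    true_positives: int
    false_negatives: int
    false_positives: int
    recovery: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    caller_true_positives: int | None = None  # before the filter cascade

    @property
    def sensitivity(self) -> float:
        total = self.true_positives + self.false_negatives
        return self.true_positives / total if total else float("nan")

    @property
    def caller_sensitivity(self) -> float | None:
        if self.caller_true_positives is None:
            return None
        total = self.true_positives + self.false_negatives
        return self.caller_true_positives / total if total else float("nan")


def score_calls(
    calls: Sequence[VariantCall], truth: pd.DataFrame
) -> tuple[int, int, int, pd.DataFrame]:
    """Exact (position, ref, alt) matching of calls against a truth table."""
    called = {(c.position, c.ref_seq, c.alt_seq) for c in calls}
    truth_keys = list(zip(truth["position"], truth["ref"], truth["alt"]))
    recovered = [key in called for key in truth_keys]
    tp = int(sum(recovered))
    fn = len(truth_keys) - tp
    fp = len(called - set(truth_keys))
    recovery = truth.copy()
    recovery["recovered"] = recovered
    return tp, fn, fp, recovery


def _random_truth(
    prototype: RDNAPrototype,
    n_snvs: int,
    n_indels: int,
    ivf: float,
    rng: np.random.Generator,
    filter_config: FilterConfig,
    eligible_only: bool = True,
    isolate_id: str = "bench",
) -> pd.DataFrame:
    """Spike SNVs/indels at random positions, by default filter-eligible ones."""
    if eligible_only:
        snv_pool = filter_eligible_positions(prototype, filter_config)
        indel_pool = filter_eligible_positions(prototype, filter_config, for_indel=True)
    else:
        snv_pool = indel_pool = list(range(1, prototype.unit_length + 1))
    if n_snvs > len(snv_pool) or n_indels > len(indel_pool):
        raise ConfigError("requested variant count exceeds eligible positions")
    rows = []
    for pos in rng.choice(snv_pool, size=n_snvs, replace=False):
        pos = int(pos)
        ref = prototype.sequence[pos - 1]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        rows.append((isolate_id, pos, ref, alt, ivf, prototype.element_of(pos), None, False))
    taken = {r[1] for r in rows}
    indel_pool = [p for p in indel_pool if p not in taken and p + 3 <= prototype.unit_length]
    for pos in rng.choice(indel_pool, size=n_indels, replace=False):
        pos = int(pos)
        anchor = prototype.sequence[pos - 1]
        if rng.random() < 0.5:  # short insertion
            ref, alt = anchor, anchor + "".join(rng.choice(list(BASES), size=2))
        else:  # short deletion
            ref, alt = prototype.sequence[pos - 1 : pos + 2], anchor
        rows.append((isolate_id, pos, ref, alt, ivf, prototype.element_of(pos), None, False))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def run_simulated_dataset_benchmark(
    prototype: RDNAPrototype,
    seed: int,
    n_snvs: int = 56,
    n_indels: int = 3,
    ivf: float = 0.005,
    coverage_tiers: Sequence[float] = (3000.0, 60000.0),
    error_rate: float = 0.001,
    alpha: float = 0.01,
    filter_config: FilterConfig | None = None,
    total_copies: float | None = None,
    eligible_only: bool = True,
) -> list[BenchmarkResult]:
    """Spike known variants at a target iVF and score the pipeline per coverage tier.

    The same truth set is used across tiers (only the reads are redrawn), so
    tiers differ by sequencing depth alone. By default truth positions are
    sampled from filter-eligible space so that sensitivity measures the caller
    rather than the deterministic position filters; ``eligible_only=False``
    samples everywhere instead, to exercise the filters' specificity.
    """
    cfg = filter_config or FilterConfig()
    rng = np.random.default_rng(seed)
    truth = _random_truth(prototype, n_snvs, n_indels, ivf, rng, cfg, eligible_only)
    results = []
    for i, coverage in enumerate(coverage_tiers):
        pile = simulate_pileup(
            prototype, truth, coverage, error_rate,
            seed=int(rng.integers(2**31)), isolate_id=f"bench_cov{coverage:g}",
        )
        raw_calls = call_variants(pile, error_rate, alpha)
        kept, _report = apply_filter_cascade(raw_calls, prototype, total_copies, cfg)
        tp, fn, fp, recovery = score_calls(kept, truth)
        caller_tp, _, _, _ = score_calls(raw_calls, truth)
        results.append(
            BenchmarkResult(
                condition=float(coverage), true_positives=tp, false_negatives=fn,
                false_positives=fp, recovery=recovery, caller_true_positives=caller_tp,
            )
        )
    return results


def run_titration_benchmark(
    prototype: RDNAPrototype,
    seed: int,
    n_tracked: int = 10,
    tracked_ivf: float = 0.99,
    frequencies: Sequence[float] = (1.0, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001),
    coverage: float = 3000.0,
    error_rate: float = 0.001,
    alpha: float = 0.01,
    filter_config: FilterConfig | None = None,
    total_copies: float | None = None,
) -> list[BenchmarkResult]:
    """In-silico spike titration: high-iVF variants diluted over a frequency series.

    The spike isolate carries ``n_tracked`` SNVs at ``tracked_ivf`` (mirroring
    tracked variants with iVFs above 95%); the background is variant-free. At
    each frequency the mixed pileup is called and filtered, and recovery of
    the tracked variants is scored.
    """
    if n_tracked < 1:
        raise ConfigError("need at least one tracked variant")
    cfg = filter_config or FilterConfig()
    rng = np.random.default_rng(seed)
    spike_truth = _random_truth(
        prototype, n_tracked, 0, tracked_ivf, rng, cfg, eligible_only=True,
        isolate_id="spike",
    )
    background_truth = pd.DataFrame(columns=TRUTH_COLUMNS)
    results = []
    for f, pile, mixed in make_titration(
        prototype, background_truth, spike_truth, frequencies, coverage,
        error_rate, seed=int(rng.integers(2**31)),
    ):
        tracked = mixed[mixed["tracked"]] if len(mixed) else mixed
        if f == 0 or len(tracked) == 0:
            tracked = spike_truth.iloc[0:0]
        raw_calls = call_variants(pile, error_rate, alpha)
        kept, _report = apply_filter_cascade(raw_calls, prototype, total_copies, cfg)
        if len(tracked):
            tp, fn, fp_unused, recovery = score_calls(kept, tracked)
            caller_tp, _, _, _ = score_calls(raw_calls, tracked)
        else:
            tp = fn = caller_tp = 0
            recovery = tracked.copy()
        # false positives: kept calls matching neither tracked nor background truth
        truth_keys = set(zip(mixed["position"], mixed["ref"], mixed["alt"])) if len(mixed) else set()
        fp = sum(1 for c in kept if (c.position, c.ref_seq, c.alt_seq) not in truth_keys)
        results.append(
            BenchmarkResult(
                condition=float(f), true_positives=tp, false_negatives=fn,
                false_positives=fp, recovery=recovery, caller_true_positives=caller_tp,
            )
        )
    return results


def results_to_table(results: Sequence[BenchmarkResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "condition": r.condition, "tp": r.true_positives, "fn": r.false_negatives,
            "fp": r.false_positives, "sensitivity": r.sensitivity,
            "caller_sensitivity": r.caller_sensitivity,
        })
    return pd.DataFrame(rows)
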