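"""Internal low-frequency variant caller (binomial stand-in).

Candidate variants are emitted from a pileup by testing, per site and per
non-reference allele, whether the observed support count is implausibly large
under a per-allele sequencing-miscall null Binomial(depth, error_rate / 3),
with Bonferroni correction across all tested site-alleles. The caller is an
explicit stand-in for a quality-aware caller such as LoFreq: it works from raw
pileup counts, and its iVF estimate is simply alt reads over total depth.
Externally produced VCFs enter the package through
:func:`rdnadiv.variants.read_variant_calls` and never pass through here.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .errors import ConfigError
from .pileup import BASES, BASE_INDEX, PileupMatrix
from .prototype import homopolymer_run, indel_homopolymer_run
from .variants import VariantCall

#: cap for the phred-scaled strand-bias score (Fisher p-values underflow below
#: 1e-300; any value this large is unambiguous artifact territory)
SB_PHRED_CAP = 3000


def strand_bias_phred(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> int:
    """Phred-scaled two-tailed Fisher exact strand-bias score.

    -10*log10(p) of the 2x2 table [[ref+, ref-], [alt+, alt-]], rounded to the
    nearest integer and capped at :data:`SB_PHRED_CAP`. An all-zero table
    scores 0. Symmetric under swapping forward/reverse labels.
    """
    if min(ref_fwd, ref_rev, alt_fwd, alt_rev) < 0:
        raise ValueError("strand counts must be non-negative")
    if ref_fwd + ref_rev + alt_fwd + alt_rev == 0:
        return 0
    _, p = stats.fisher_exact(
        [[ref_fwd, ref_rev], [alt_fwd, alt_rev]], alternative="two-sided"
    )
    if p <= 0:
        return SB_PHRED_CAP
    return min(int(round(-10.0 * math.log10(p))), SB_PHRED_CAP)


def call_variants(
    pileup: PileupMatrix,
    error_rate: float,
    alpha: float = 0.01,
) -> list[VariantCall]:
    """Call variants from a strand-split pileup.

    For each non-reference allele with support k at depth n, a call is emitted
    iff the upper-tail probability P(X >= k), X ~ Binomial(n, error_rate/3),
    falls below ``alpha`` after Bonferroni correction across all tested
    site-alleles (three substitution alleles per covered position plus every
    distinct observed indel allele). iVF = k/n; strand counts and the Fisher
    strand-bias score are attached, as is the reference homopolymer run length
    at the site.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    if error_rate < 0:
        raise ConfigError("error_rate must be non-negative")

    depth = pileup.depths()
    covered = depth > 0
    n_tests = 3 * int(covered.sum()) + len(pileup.indel_counts)
    if n_tests == 0:
        return []
    threshold = alpha / n_tests
    p_null = error_rate / 3.0

    ref_idx = np.fromiter(
        (BASE_INDEX[b] for b in pileup.reference), dtype=np.int64, count=pileup.length
    )
    totals = pileup.base_counts.sum(axis=2)  # (L, 4)
    calls: list[VariantCall] = []

    # -- substitutions ---------------------------------------------------------
    alt_mask = np.ones_like(totals, dtype=bool)
    alt_mask[np.arange(pileup.length), ref_idx] = False
    candidate = alt_mask & (totals > 0) & covered[:, None]
    pos0s, alts = np.nonzero(candidate)
    if pos0s.size:
        ks = totals[pos0s, alts]
        ns = depth[pos0s]
        # P(X >= k) = sf(k-1); error_rate 0 makes any support significant
        pvals = stats.binom.sf(ks - 1, ns, p_null)
        keep = pvals < threshold
        for pos0, b, k, n in zip(pos0s[keep], alts[keep], ks[keep], ns[keep]):
            position = int(pos0) + 1
            ref_base = pileup.reference[pos0]
            rf, rr = pileup.base_count(position, ref_base)
            af, ar = pileup.base_count(position, BASES[b])
            calls.append(
                VariantCall(
                    isolate_id=pileup.isolate_id,
                    position=position,
                    ref_seq=ref_base,
                    alt_seq=BASES[b],
                    ivf=float(k) / float(n),
                    depth=int(n),
                    strand_counts=(rf, rr, af, ar),
                    sb_phred=strand_bias_phred(rf, rr, af, ar),
                    hrun=homopolymer_run(pileup.reference, position),
                )
            )

    # -- indels ----------------------------------------------------------------
    for (position, ref_seq, alt_seq), (f, r) in sorted(pileup.indel_counts.items()):
        k = f + r
        n = int(depth[position - 1])
        if k == 0 or n == 0:
            continue
        p = float(stats.binom.sf(k - 1, n, p_null))
        if p >= threshold:
            continue
        ref_base = pileup.reference[position - 1]
        rf, rr = pileup.base_count(position, ref_base)
        calls.append(
            VariantCall(
                isolate_id=pileup.isolate_id,
                position=position,
                ref_seq=ref_seq,
                alt_seq=alt_seq,
                ivf=float(k) / float(n),
                depth=n,
                strand_counts=(rf, rr, f, r),
                sb_phred=strand_bias_phred(rf, rr, f, r),
                hrun=indel_homopolymer_run(pileup.reference, position),
            )
        )

    calls.sort(key=lambda c: (c.position, c.ref_seq, c.alt_seq))
    return calls
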