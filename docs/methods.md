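# Methods

This note documents the models, parameter choices and numerical conventions
behind `rdnadiv`, and what the synthetic-data results do and do not show
about real cohorts.

## Coordinate model

All analyses run on a single rearranged rDNA prototype unit (~9.1 kb) in
1-based inclusive coordinates, with the non-transcribed spacers placed before
the 35S transcription unit. BED input is 0-based half-open and converted on
load. Positions inside the rRNA genes convert bijectively to gene-local
coordinates (`25S:1248` style), the convention used by rRNA nomenclature and
by the structural annotations. Indels are left-anchored VCF alleles; indel
length is |len(ref) − len(alt)|.

The bundled `synthetic_prototype()` reproduces the real unit's layout and
rRNA gene lengths (25S 3396, 18S 1800, 5.8S 158, 5S 121 nt; unit 9137 nt) but
carries a random seeded sequence and approximate spacer boundaries; a 12-nt
poly(A) stretch is embedded in NTS1 so the stretch-masking filter has real
targets. Real annotations enter via FASTA + BED.

## Copy numbers and the one-copy limit

Total rDNA copies per isolate are M = mean(per-haploid copies of RDN5.8,
RDN18, RDN25) × ploidy; RDN5 estimates are not available in the source
metadata and are ignored. 1/M is the theoretical frequency of a variant on a
single copy and bounds what any frequency-based caller can resolve. In the
simulator, variants occupy whole copies, so true iVFs live on the lattice
k/M with M rounded to the nearest integer (copy-number *estimates* are real
numbers; occupied copies are not). Requests below 1/M are promoted to
exactly one copy and flagged.

## Internal caller

The caller is a deliberate stand-in for a quality-aware low-frequency caller
(real VCFs bypass it entirely): for each non-reference allele with support k
at depth n it tests the binomial tail P(X ≥ k), X ~ Binomial(n, e/3) for
per-base miscall rate e, Bonferroni-corrected across all tested site-alleles
(three substitution alleles per covered position plus each distinct observed
indel allele), at significance level alpha = 0.01. Its iVF estimate is the
raw k/n over all pileup reads at the site. Indel alleles are tested against
the same e/3 null; the default simulator emits no indel errors, so indel
support is effectively all signal. Strand bias is the phred-scaled
(−10·log₁₀ p, rounded, capped at 3000) two-tailed Fisher exact probability of
the strand 2×2 table.

At 3000× and e = 0.001 the Bonferroni threshold works out to k ≈ 10
supporting reads, giving per-variant detection probability ≈ 0.95–0.97 for a
true iVF of 0.005 and essentially 1 above 1%.

## Filter cascade

Rules, in order, with removal attributed to the first failure: position in
(10, 9100) exclusive; iVF > 0.005 strictly; reference homopolymer run < 4
(for SNVs the maximal run containing the site, for indels the run 3′ of the
anchor, with a caller-supplied HRUN taking precedence); long indels (> 5 nt)
dropped when the GC fraction of either allele's event sequence (allele minus
anchor base) reaches 0.6 — the anchor is excluded because a single-base
insertion REF has degenerate GC; positions inside any ≥ 10-nt single-base
stretch of the prototype, computed from sequence rather than a side file;
optionally iVF > 1/M; strand bias < 144 phred. The "top 12%" provenance of
the 144 cutoff is dataset-specific and is not re-derived; the fixed value is
used. The cascade is idempotent and its report reconciles exactly.

**The threshold-coincidence caveat.** A variant whose *true* frequency sits
exactly on the minimum-iVF cutoff (one copy in M = 200 at the 0.5% rule) has
observed iVF k/n with mean at the cutoff, so the strict `>` comparison passes
with probability ≈ ½ regardless of depth or caller quality. Benchmarks
therefore report both post-cascade sensitivity and caller-level recovery;
at 3000× the former is ~55–70% for true iVF exactly 0.005 while the latter is
≥ 95%. Spiked frequencies even slightly above the cutoff (e.g. 1/150) recover
near-completely.

## Simulator

Per position, depth ~ Poisson(coverage × profile); variant-supporting reads
are multinomial across the position's variants with the remainder reading
reference; each non-variant read is miscalled to a uniformly chosen other
base with probability e (default 0.001, strand-symmetric; indel errors off by
default); strands are fair coins, with a configurable strand fraction for
variant reads to exercise the strand-bias filter. Titrations mix a spike
isolate into a background at frequencies f, scaling expected iVFs by f.
Defaults (3000× rDNA coverage, mostly diploid cohorts, per-haploid copies
60–130 giving M ≈ 120–260) emulate a deep-sequenced natural yeast cohort.

What the simulator does *not* model: alignment and mapping artifacts,
quality-score structure, GC- and position-dependent coverage (a per-position
profile hook exists but defaults to uniform), PCR duplicates, and indel
sequencing errors. Passing benchmarks therefore demonstrate correctness of
the calling/filtering/statistics machinery under the declared error model,
not end-to-end performance on real reads.

## Diversity statistics

Per-site entropy follows the five-category copy-unit formulation: each
isolate contributes round(iVF × M) copies per variant allele (all indel
alleles pool into one category), the remainder reading the reference; copy
overflows raise rather than truncate. Whether to round or keep fractional
copies is an open modelling choice; rounding is declared and matches the
whole-copy lattice. Element summaries define a variant as a distinct
(position, ref, alt), a polymorphic site as a position with ≥ 1 variant, and
an iVFP as one (isolate, variant) row. Sharing comparisons pool elements into
rRNA, ETS+ITS and NTS. Pearson correlations carry t-based two-sided p-values
and Fisher-z 95% CIs.

## Co-occurrence

Only iVFs in [0.05, 1] participate. For each unordered pair sharing ≥ 3
isolates within an ecological niche: D = Euclidean distance between the
per-isolate iVF vectors, mean = (ΣX + ΣY)/n as printed in the source
formulation (n = shared isolates, not 2n). The published text states the
mean condition as "< 0.05", which is unsatisfiable when every participating
iVF is ≥ 0.05 and the mean divides by n; the package defaults to
`mean > 0.05` and exposes the direction in `CooccurrenceConfig` rather than
resolving the contradiction silently. Pairs are evaluated per niche and the
union reported, with every evaluated pair (flagged or not) emitted.

## Structural stratification

Shell tallies count resolved nucleotides n_i and class iVFPs m_i per
concentric shell (iVF classes: low [0.005, 0.05), mid [0.05, 0.95), high
[0.95, 1]); calls at structurally unresolved positions are excluded from both
sides and surfaced in a side channel. log₁₀(F*_i/F_i) is undefined (None)
when a shell has no iVFPs; the −2 sentinel appears only in table/plot export,
never in analytical output. The skew test compares per-observation shell
ordinals (each iVFP vs each resolved nucleotide) by two-sided rank-sum —
the construction most consistent with an expectation "based on the
distribution of total rRNA nucleotides across the shells". Shell ordinals
are massively tied, so the tie-corrected normal approximation applies; the
generic rank-sum helper uses exact enumeration only for small untied
samples. Outer shells arrive pre-pooled ("6+7") from the annotation file,
not hard-coded. Region enrichment builds one 2×2 Fisher table per iVF
cutoff — (inside, outside) iVFPs vs (inside, outside) nucleotides — with BH
adjustment across cutoffs. Bridge-proximal and ribosomal-protein-interface
sets are consumed as annotations; no 3D distances are computed.

The bundled `synthetic_structure_annotation()` encodes only published
marginal totals (LSU 3428 resolved of 3675 with 82 in shell 1 and 247
unresolved; SSU 1781 of 1800; CNE 962 of the 3396-nt 25S; ES 883 LSU
nucleotides); the interior shell split and region placements are synthetic
stand-ins, clearly so named. Real shell maps enter as TSV.

## Statistical conventions

Rank-sum tests are two-sided Mann–Whitney; exact null distribution when both
samples are ≤ 10 and untied, otherwise normal approximation with continuity
and tie correction; a fully tied comparison returns p = 1. Fisher exact
tests are two-tailed hypergeometric. Each test family (habitat pairs,
sharing groups, shell classes, region cutoffs) is BH-adjusted separately.
The test suite cross-checks Fisher, rank-sum and strand-bias values against
brute-force enumeration oracles on small tables.

## Problem sizes and reproducibility

Simulated benchmarks run at the study's rDNA depth (3000×, one tier at
60,000×) over the full 9.1-kb unit with cohorts of 10–20 isolates and
100-variant spike sets — sizes chosen so the whole suite and the acceptance
script complete in minutes on one core while keeping binomial sampling error
on reported rates below a few percent. Every stochastic path takes an
explicit seed; pipeline stage seeds derive from the global seed by fixed
offsets, and a synthetic pipeline rerun with the same configuration is
bit-identical (outputs embed the config hash and seed).

## Known limitations

- Sensitivity estimates at the exact minimum-iVF threshold are dominated by
  the threshold-coincidence effect described above, not by caller power.
- The caller's Bonferroni family makes it conservative at marginal support
  (k ≈ 9–10 at 3000×); a per-site FDR formulation would trade specificity
  for sensitivity.
- iVFs are treated as independent binomial draws per site; linked variants
  within a read pair are not modelled (no read-level phasing).
- The uniform coverage default understates variance at real rDNA loci, where
  coverage is element-dependent.
- Replicate deduplication and clade handling assume externally supplied
  labels; no phylogenetic inference is performed.
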