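# Annotated pipeline run configuration (consumed by `rdnadiv run-all`).
# Exactly one of `synthetic` (a cohort generator config) or the real-input
# paths (prototype_fasta/prototype_bed/vcf_paths/metadata_tsv) may be active.
output_dir: scratch/example_run
seed: 42

synthetic:
  n_isolates: 12
  # distribution of ploidies 1..5 (mostly diploid, as in natural cohorts)
  ploidy_weights: {1: 0.14, 2: 0.76, 3: 0.06, 4: 0.03, 5: 0.01}
  copy_number_range: [60.0, 130.0]   # rDNA copies per haploid genome
  clades: [clade1, clade2, clade3]
  niches: [wine, dairy, soil]
  habitats: [domesticated, wild, human body, unknown]
  error_rate: 0.001                  # per-base miscall probability
  rdna_coverage: 3000.0              # mean fold-coverage over the rDNA unit
  seed: 0                            # overridden by the global seed

filter:
  min_position: 10                   # keep if position > 10
  max_position: 9100                 # ... and < 9100 (avoids unit-end effects)
  min_ivf: 0.005                     # keep if iVF > 0.5%
  max_homopolymer_run: 4             # keep if reference run < 4
  long_indel_len: 5                  # GC rule applies to indels > 5 nt
  max_indel_gc: 0.6
  poly_stretch_len: 10               # single-base stretches to mask
  sb_phred_cutoff: 144               # drop if phred strand bias >= 144
  apply_one_copy_threshold: true     # require iVF > 1/M per isolate

cooccurrence:
  min_shared_isolates: 3
  max_distance: 0.5                  # Euclidean distance over shared isolates
  mean_ivf_threshold: 0.05
  mean_ivf_direction: greater        # see docs/methods.md on this choice

run_entropy: true
run_cooccurrence: true
run_enrichment: true
alpha: 0.01                          # caller significance level (Bonferroni)
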