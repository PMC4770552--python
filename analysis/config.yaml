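# Shared configuration for the numbered analysis drivers.
# A moderate synthetic cohort: 30 sequences per clade (4 Bacillus-type),
# 8 % substitution noise outside protected positions, survey-like
# extension/multi-copy fractions, 200 bootstrap replicates.
outdir: results/pipeline
seed: 20
synthetic:
  n_clade1: 30
  n_clade2: 30
  n_bacillus_loop: 4
  substitution_rate: 0.08
  fraction_with_heme_ext: 0.15
  fraction_with_cupredoxin_ext: 0.15
  multi_copy_fraction: 0.05
  primer_mismatch_spec:
    I: {3: 0.05, 17: 0.05}
    II: {1: 0.30, 5: 0.25, 12: 0.20, 17: 0.35}
phylo:
  method: count_differences
  deletion_policy: complete
  replicates: 200
primers:
  three_prime_window: 3
  sets:
    # synthetic stand-in for a degenerate forward primer (config input:
    # published primer sequences are supplied by the user, never bundled)
    - {name: synF, sequence: GGWCAYGCNAARATHGT, orientation: forward}
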