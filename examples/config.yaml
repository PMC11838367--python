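# Annotated apolq pipeline configuration.
# Run with:  apolq run --config examples/config.yaml

ancestry: AFR            # AFR or EUR haplotype pool (published frequencies)
n_samples: 828           # cohort size
effect_profile: afr_table2   # afr_table2 | afr_stratified | eur_table2 | healthabc
seed: 1                  # mandatory top-level seed; stages derive sub-seeds
output_dir: apolq_run

# any prefix of: simulate, qc, scan, finemap, gxg, peptides, compare
stages: [simulate, qc, scan, finemap, gxg, peptides, compare]

qc:
  info_min: 0.6          # imputation INFO threshold (skipped for sequenced variants)
  mac_min: 10            # minor allele count threshold
  kinship_max: 0.125     # Pi_hat above which one of a pair is dropped

finemap:
  max_k: 3               # maximum causal variants per configuration
  prior_effect_scale: 0.5  # tau, residual SDs per standardized allele

n_reference_eur: 366     # European reference panel size for peptide inference
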