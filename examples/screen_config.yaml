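# Example configuration for `magescreen screen` / magescreen.pipeline.run_screen.
# Paths are relative to where you run the command; generate matching CSVs with
# `magescreen simulate --n-patients 2000 --seed 3 --out synthetic`.
inputs:
  hla_typing: synthetic/hla_typing.csv     # patient_id, genotype, race, ethnicity[, population]
  ihc: synthetic/ihc.csv                   # sample_id, patient_id, tumor_type, ..., pct0..pct3
  # concordance: concordance.csv           # sample_id, reference_genotype, assay_genotype

# Demographic columns for the eligibility summary (missing -> "Not recorded").
group_keys: [race, ethnicity]

# Eligibility rules; omit to use the defaults shown here.
rules:
  inclusion_groups: ["02:01P", "02:02P", "02:03P", "02:06P"]
  exclusion_groups: ["02:05P"]
  null_alleles_neutral: true

# Positivity cutoff; omit for the clinical-trial rule (>= 30% at >= 2+).
cutoff:
  min_pscore: 30
  min_intensity: 2

# Optional: path to a full IMGT-dialect P-group table; omit for the builtin subset.
# pgroup_table: hla_nom_p.txt

# Optional: covariate columns for the adjusted odds-ratio table.
covariate_terms: [histology, tissue_location]
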