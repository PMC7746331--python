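# Replication of the published six-trait glycemic analysis.
# Supply the consortium summary tables (DIAGRAM/MAGIC exposures, IGAP
# outcome) under data/supplementary/ in the documented TSV layout
# (columns: rsid, effect_allele, other_allele, eaf, beta, se, pvalue).
# Exposure tables are expected post pleiotropy screening; alternatively
# add exclusion_path entries with the screened rsids.
# HOMA-B estimates are reported per 1-SD *lower* beta-cell function
# (flip_exposure), matching the publication's direction convention.
traits:
  - name: type_2_diabetes
    exposure_path: data/supplementary/exposure_type_2_diabetes.tsv
    exposure_scale: log-odds
  - name: fasting_glucose
    exposure_path: data/supplementary/exposure_fasting_glucose.tsv
    exposure_scale: 1-SD
    leave_one_out: true
  - name: fasting_insulin
    exposure_path: data/supplementary/exposure_fasting_insulin.tsv
    exposure_scale: 1-SD (natural-log transformed)
  - name: hba1c
    exposure_path: data/supplementary/exposure_hba1c.tsv
    exposure_scale: "%-units"
  - name: homa_b
    exposure_path: data/supplementary/exposure_homa_b.tsv
    exposure_scale: 1-SD lower (natural-log transformed)
    flip_exposure: true
    leave_one_out: true
  - name: homa_ir
    exposure_path: data/supplementary/exposure_homa_ir.tsv
    exposure_scale: 1-SD (natural-log transformed)
outcome_path: data/supplementary/outcome_alzheimers_disease.tsv
methods: [ivw, ivw_penalized_robust, mr_egger, simple_median,
          weighted_median, weighted_mbe, mr_presso]
seed: 1
n_boot: 1000
n_sim: 1000
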