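# Synthetic demo: generate the input tables first with
#   mrkit simulate -o demo_data --seed 7 --n-snps 25 --allele-scramble
# then run
#   mrkit run configs/demo.yaml -o demo_results
traits:
  - name: simulated_trait
    exposure_path: demo_data/exposure.tsv
    exposure_scale: 1-SD
    leave_one_out: true
outcome_path: demo_data/outcome.tsv
methods: [ivw, ivw_penalized_robust, mr_egger, simple_median,
          weighted_median, weighted_mbe, mr_presso]
seed: 7
n_boot: 1000
n_sim: 1000
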