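# Default simulated study: 8 donors x 4 tissues, 4,000 probes.
# Replace the `simulate` section with an `inputs` section (beta, samples,
# annotation, detection_p paths) to run on your own data.
seed: 11
output_dir: oculoconcord_run
stages: all
simulate:
  n_probes: 4000
analysis:
  hypo_max: 0.2
  hyper_min: 0.8
  variability_range_min: 0.05
  corr_r_min: 0.5
  corr_p_max: 0.05
  detection_p_max: 0.01
  fdr_q: 0.05
  n_null_permutations: 50
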