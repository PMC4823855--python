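# Fully-worked pipeline configuration for `akicode run --config`.
# Exactly one of `simulation` or `input_dir` may be set.
simulation:
  n_patients: 524
  stage_prevalence: [0.55, 0.305, 0.04, 0.105]
  baseline_scr_median: 133.0
  baseline_scr_sigma: 0.3887
  seed: 7
seed: 7
suppress_threshold: 6
lr_mode: paper_rounded
out_dir: scratch/run_output
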