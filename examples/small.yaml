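# Small demonstration run: 12 subjects, 2-minute recordings, 3-fold CV.
# Finishes in a few minutes on one CPU; for a study-scale run raise the
# counts, durations, k and epochs.
cohort:
  n_per_class:
    AF: 4
    NSR: 4
    APC: 2
    SINUS_ARRHYTHMIA: 2
  duration_min_s: 120.0
  duration_max_s: 120.0
tasks: [AF_vs_NonAF]
cv:
  k: 3
train:
  epochs: 10
  batch_size: 16
  patience: null
  seed: 0
master_seed: 7
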