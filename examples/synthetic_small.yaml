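# A small synthetic cohort: 3 subjects, 6 clips per activity per context.
# Any key omitted here keeps its package default (see accelhar.synthetic).
n_subjects: 3
clips_per_activity_lab: 6
clips_per_activity_home: 6
seed: 0

# The lab-to-home shift; set all fields to 0 (and amp_scale to 1) for a
# home context statistically identical to the lab.
context_shift:
  amp_scale: 1.3
  freq_jitter_sd: 0.008
  extra_noise_sd_g: 0.003
  orientation_jitter_deg: 0.7
  placement_bias_deg: 8.0

# Per-activity signal parameters may be overridden field-by-field:
activity_params:
  walk:
    osc_freq_hz: 1.6
    osc_amp_g: 0.28
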