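# Cohort presets for the synthetic dual-site generator.
# Lags are MEC relative to CA1 in ms; negative means MEC leads.
wt:
  lag_mean_ms: -8.9
  lag_jitter_ms: 5.0
  coupled_fraction: 0.8
ad:
  lag_mean_ms: 23.2
  lag_jitter_ms: 5.0
  coupled_fraction: 0.5
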