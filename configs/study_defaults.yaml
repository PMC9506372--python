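# Full default configuration of the ITF extraction pipeline.
# These values are also the built-in defaults of itfx.RunConfig; pass this
# file to `itfx extract --config` and override only what differs.
preprocess:
  highpass_hz: 0.1
  line_freq_hz: 50.0
  reject_ptp_uv: 150.0
  excluded_channels: []
  line_method: notch
window:
  start_ms: 250.0
  end_ms: 1250.0
  width_ms: 100.0
  step_ms: 50.0
bands:
  delta: [2.0, 4.0]
  theta: [4.0, 8.0]
  alpha: [8.0, 12.0]
electrodes: [Cz, C3, C4, Pz, P3, P4]
fallback_electrodes: [PO7, PO8]
fallback_trigger_pct: 20.0
per_trial_baseline: false
window_stat: mean
epoch_buffer_ms: 1800.0
seed: 0
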