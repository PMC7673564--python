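# Bundled demonstration run: 4 synthetic animals, 3 ROIs x 4 hemodynamic
# states, full metrics + microsphere flows + permutation statistics.
# Runs end-to-end in well under two minutes on one CPU.
seed: 0
n_animals: 4
animal_flow_sd: 0.15
write_frames: false
reference_roi: D3

simulator:
  frame_rate: 25.0
  duration: 120.0
  injection_time: 10.0
  bit_depth: 8
  noise_sd: 2.0
  baseline_level: 10.0
  amplitude: 100.0
  time_to_peak: 6.0
  shape: 3.0
  recirculation_fraction: 0.15
  recirculation_delay: 30.0
  systemic_lag: 4.0
  reference_flow: 1.0
  state_flow_scales: {T0: 0.85, T1: 0.6, T2: 1.0, T3: 1.25}
  rois:
    - {name: D1, relative_flow: 0.5, arrival_delay: 4.0, pooling_offset: 3.0}
    - {name: D2, relative_flow: 0.75, arrival_delay: 1.5, pooling_offset: 3.0}
    - {name: D3, relative_flow: 1.0, arrival_delay: 0.0, pooling_offset: 3.0}

metrics:
  baseline_window: 5.0
  smooth_half_width: 4
  onset_k: 3.0
  onset_m: 5
  sd_floor: 0.5
  onset_refine_margin: 1.0
  slope_window: 25
  analysis_window: 60.0

assay:
  weight_g: 3.5
  weight_sd_g: 0.2
  withdrawal_rate_ml_min: 3.18
  reference_count_scale: 20000.0
  poisson_noise: true

stats:
  n_permutations: 1000
  n_bootstrap: 500
  metrics: [bsfi, sfi, tts_ratio]
  correlation_metrics: [sfi, bsfi]
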