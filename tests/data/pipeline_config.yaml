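seed: 11
reference: control
simulation:
  n_frames: 300
  frame_interval_s: 1.0
analysis:
  min_mt_length_um: 10.0
conditions:
  - label: control
    landing_rate_per_um_s: 2.0e-4
    n_microtubules: 8
  - label: activated
    landing_rate_per_um_s: 2.0e-3
    n_microtubules: 8
    dwell_mean_s: 21.0
    n_baits: 40
    arrival_rate_per_s: 0.01
    mass_mixture:
      n_samples: 3000
      k: 2
      components:
        - {loc: 330.0, scale: 18.0, shape: 0.0, weight: 0.55}
        - {loc: 430.0, scale: 18.0, shape: 0.0, weight: 0.45}
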