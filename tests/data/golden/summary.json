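{
  "analysis": {
    "association_radius_nm": 320.0,
    "max_pause_s": 3.0,
    "min_duration_s": 2.0,
    "min_mt_length_um": 10.0,
    "min_run_length_nm": 500.0
  },
  "conditions": [
    {
      "frequency_mean": 0.000112,
      "frequency_sd": 0.000164,
      "label": "control",
      "n_microtubules": 8,
      "n_runs": 4,
      "normalized_fold": 1.0,
      "seed": 11,
      "velocity_mean": 501.952033,
      "velocity_sd": 7.567316
    },
    {
      "dwell_n_censored": 4,
      "dwell_n_events": 81,
      "dwell_se_s": 2.265052,
      "dwell_tau_s": 19.875752,
      "frequency_mean": 0.001847,
      "frequency_sd": 0.000483,
      "label": "activated",
      "mass_means_kda": [
        329.565016,
        430.638025
      ],
      "mass_percentages": [
        55,
        45
      ],
      "n_microtubules": 8,
      "n_runs": 81,
      "normalized_fold": 16.471282,
      "seed": 12,
      "velocity_mean": 497.613402,
      "velocity_sd": 47.649288
    }
  ],
  "config_sha256": "4b9ede2446e4f629373e5f93a07dca2817f9e6fe639e1579729a9ad4e0d039c7",
  "reference": "control",
  "seed": 11
}
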