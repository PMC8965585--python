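{
  "grid_dims": [
    8,
    8,
    8
  ],
  "n_rois": 6,
  "n_subjects": 40,
  "n_timepoints": 90,
  "tr_s": 2.0,
  "voxel_size_mm": [
    3.0,
    3.0,
    3.0
  ],
  "fc_strength": 0.5,
  "local_coherence": 0.7,
  "bold_noise_sd": 1.0,
  "spike_fraction": 0.05,
  "fa_background": 0.25,
  "fa_background_sd": 0.05,
  "bundle_fa": 0.8,
  "bundle_pairs": [
    [
      1,
      2
    ]
  ],
  "samples_per_voxel": 10,
  "max_steps": 60,
  "fa_stop": 0.15,
  "angle_limit_deg": 45.0,
  "direction_jitter_kappa": 50.0,
  "n_planted": 2,
  "planted_weight": 0.3,
  "measurement_noise_sd": 0.1,
  "seed": 7,
  "log_level": "INFO",
  "selection_p": 0.05
}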