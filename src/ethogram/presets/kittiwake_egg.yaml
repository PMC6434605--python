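# Black-legged kittiwake, incubation deployment constants.
species: kittiwake
stage: egg
behaviors: [colony, flying, swimming]
sampling_rate: 25.0
flight_wbf_band: [3.0, 6.0]
dive_depth_threshold: null
activity_metric: SD_Z
gps_speed_error_cutoff: 20.0
gps_flight_speed: 3.0
gps_max_gap: 600.0
colony_radius: 500.0
fix_interval: 30.0
transition_window: 30.0
eval_subsample: 30.0
hmm_bin: 10.0
dee_coefficients:
  colony: 21.0
  flying: 99.9
  swimming: 25.8
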