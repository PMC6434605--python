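# Thick-billed murre, chick-rearing deployment constants.
species: murre
stage: chick
behaviors: [colony, flying, swimming, diving]
sampling_rate: 25.0
flight_wbf_band: [6.0, 9.0]
dive_depth_threshold: -1.0
activity_metric: SD_ODBA
gps_speed_error_cutoff: 30.0
gps_flight_speed: 2.0
gps_max_gap: null
colony_radius: 250.0
fix_interval: 60.0
transition_window: 60.0
eval_subsample: 60.0
hmm_bin: 5.0
dee_coefficients:       # kJ per hour of behavior
  colony: 32.0
  flying: 532.8
  swimming: 100.8
  diving: 97.2
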