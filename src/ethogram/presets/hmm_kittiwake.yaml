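# Starting values for the kittiwake hidden Markov model.
# Two colony states (quiet and active nest attendance) are merged to a
# single "colony" behavior after decoding.  Direct transitions between
# either colony state and swimming are structurally impossible (the bird
# must fly between the nest and the water).
states: [colony1, colony2, flying, swimming]
variables:
  pitch:
    family: normal
    mean: {colony1: 35.0, colony2: 10.0, flying: 0.0, swimming: 5.0}
    sd: {colony1: 10.0, colony2: 10.0, flying: 5.0, swimming: 5.0}
  activity:                 # SD_Z, g
    family: zi_lognormal
    location: {colony1: 0.05, colony2: 0.05, flying: 0.6, swimming: 0.15}
    scale: {colony1: 0.5, colony2: 0.5, flying: 0.5, swimming: 0.5}
    zero_mass: {colony1: 0.9, colony2: 0.9, flying: 0.1, swimming: 0.1}
  wbf:                      # Hz
    family: zi_lognormal
    location: {colony1: 0.5, colony2: 2.0, flying: 9.0, swimming: 2.0}
    scale: {colony1: 0.5, colony2: 0.5, flying: 0.2, swimming: 0.5}
    zero_mass: {colony1: 0.9, colony2: 0.9, flying: 0.1, swimming: 0.9}
forbidden_transitions:
  - [colony1, swimming]
  - [swimming, colony1]
  - [colony2, swimming]
  - [swimming, colony2]
state_map:
  colony1: colony
  colony2: colony
  flying: flying
  swimming: swimming
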