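# Starting values for the murre hidden Markov model.
# One hidden state per behavior; emissions are conditionally independent
# given the state.  The lognormal "location" is the median in natural
# units (Hz or g); "scale" is the SD on the log scale.  The depth
# Bernoulli probabilities are held fixed during fitting so that diving
# stays anchored to the below -1 m indicator.
states: [colony, diving, flying, swimming]
variables:
  pitch:
    family: normal
    mean: {colony: 30.0, diving: -5.0, flying: 0.0, swimming: -5.0}
    sd: {colony: 20.0, diving: 50.0, flying: 5.0, swimming: 10.0}
  activity:                 # SD_ODBA, g
    family: exponential
    rate: {colony: 25.0, diving: 5.0, flying: 2.5, swimming: 5.0}
  wbf:                      # Hz
    family: zi_lognormal
    location: {colony: 0.5, diving: 2.0, flying: 9.0, swimming: 2.0}
    scale: {colony: 0.5, diving: 0.5, flying: 0.2, swimming: 0.5}
    zero_mass: {colony: 0.9, diving: 0.9, flying: 0.1, swimming: 0.9}
  depth:                    # indicator of depth below -1 m
    family: bernoulli
    fixed: true
    p: {colony: 1.0e-12, diving: 0.999999999999, flying: 1.0e-12, swimming: 1.0e-12}
forbidden_transitions:
  - [colony, swimming]
  - [swimming, colony]
  - [colony, diving]
  - [diving, colony]
  - [diving, flying]
  - [flying, diving]
state_map:                  # decoded state -> reported behavior
  colony: colony
  diving: diving
  flying: flying
  swimming: swimming
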