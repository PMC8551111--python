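# Curated simulator configurations per pitch-width condition.
# Calibrated (seed-frozen, see tests) so that downstream analysis gives:
#   heading-change entropy:        narrow > square > wide
#   short-latency response share:  narrow > square > wide
#   speed saturation:              > 90% of samples above 90% of the cap
#   direction-change ratio:        > 1 (spurious anticipation present)
narrow:
  n_pairs: 12
  trials_per_pair: 50
  sample_rate: 120.0
  max_trial_duration: 20.0
  attacker:
    switch_hazard: 2.2
    refractory: 0.45
    goal_bias: 0.40
    boundary_margin: 1.5
    speed_fraction: 0.95
  defender:
    reaction_delay: 0.25
    anticipation_prob: 0.25
    noise_sd: 4.0
    spurious_rate: 0.30
    delay_jitter: 0.3
    vertical_cap: 0.15
square:
  n_pairs: 12
  trials_per_pair: 50
  sample_rate: 120.0
  max_trial_duration: 20.0
  attacker:
    switch_hazard: 1.2
    refractory: 0.45
    goal_bias: 0.50
    boundary_margin: 1.5
    speed_fraction: 0.95
  defender:
    reaction_delay: 0.25
    anticipation_prob: 0.12
    noise_sd: 4.0
    spurious_rate: 0.18
    delay_jitter: 0.3
    vertical_cap: 0.15
wide:
  n_pairs: 12
  trials_per_pair: 50
  sample_rate: 120.0
  max_trial_duration: 20.0
  attacker:
    switch_hazard: 0.5
    refractory: 0.45
    goal_bias: 0.60
    boundary_margin: 1.5
    speed_fraction: 0.95
  defender:
    reaction_delay: 0.25
    anticipation_prob: 0.05
    noise_sd: 4.0
    spurious_rate: 0.08
    delay_jitter: 0.3
    vertical_cap: 0.15
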