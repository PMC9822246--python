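# Motor parameters of the predictive model, measured in homogeneous-substrate
# recordings; speeds in mm/s, event probabilities per second (dt = 0.5 s).
dt_s: 0.5
params:
  rover:
    agar: {mean_v: 0.84, sd_v: 0.13, p_turn_per_s: 0.044, p_pause_per_s: 0.0083}
    sucrose: {mean_v: 0.68, sd_v: 0.092, p_turn_per_s: 0.041, p_pause_per_s: 0.012}
    yeast: {mean_v: 0.37, sd_v: 0.13, p_turn_per_s: 0.033, p_pause_per_s: 0.25}
  sitter:
    agar: {mean_v: 0.96, sd_v: 0.13, p_turn_per_s: 0.046, p_pause_per_s: 0.0063}
    sucrose: {mean_v: 0.68, sd_v: 0.085, p_turn_per_s: 0.035, p_pause_per_s: 0.021}
    yeast: {mean_v: 0.31, sd_v: 0.11, p_turn_per_s: 0.028, p_pause_per_s: 0.25}
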