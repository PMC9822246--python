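# Motor parameters of the corrected model, measured inside / outside patches
# in patchy-substrate recordings; speeds in mm/s, probabilities per second.
dt_s: 0.5
params:
  rover:
    sucrose:
      inside: {mean_v: 0.60, sd_v: 0.27, p_turn_per_s: 0.037, p_pause_per_s: 0.039}
      outside: {mean_v: 0.65, sd_v: 0.25, p_turn_per_s: 0.044, p_pause_per_s: 0.0014}
    yeast:
      inside: {mean_v: 0.37, sd_v: 0.19, p_turn_per_s: 0.039, p_pause_per_s: 0.17}
      outside: {mean_v: 0.44, sd_v: 0.20, p_turn_per_s: 0.068, p_pause_per_s: 0.023}
    apple_juice:
      inside: {mean_v: 0.44, sd_v: 0.24, p_turn_per_s: 0.026, p_pause_per_s: 0.096}
      outside: {mean_v: 0.53, sd_v: 0.26, p_turn_per_s: 0.017, p_pause_per_s: 0.076}
  sitter:
    sucrose:
      inside: {mean_v: 0.52, sd_v: 0.28, p_turn_per_s: 0.030, p_pause_per_s: 0.088}
      outside: {mean_v: 0.57, sd_v: 0.26, p_turn_per_s: 0.030, p_pause_per_s: 0.040}
    yeast:
      inside: {mean_v: 0.26, sd_v: 0.14, p_turn_per_s: 0.025, p_pause_per_s: 0.32}
      outside: {mean_v: 0.36, sd_v: 0.17, p_turn_per_s: 0.048, p_pause_per_s: 0.053}
    apple_juice:
      inside: {mean_v: 0.39, sd_v: 0.21, p_turn_per_s: 0.021, p_pause_per_s: 0.13}
      outside: {mean_v: 0.48, sd_v: 0.22, p_turn_per_s: 0.031, p_pause_per_s: 0.065}
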