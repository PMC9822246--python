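# SYNTHETIC example inward-turn bias profile for a 25-mm reference patch.
# Illustrative values only — experimental bias profiles must be supplied by
# the user as a file of this shape.  Distances in mm; bins are half-open.
bin_edges: [0, 10, 20, 30, 40, 50, 60]
p_bias: [0.85, 0.80, 0.75, 0.65, 0.60, 0.55]
cutoff_mm: 60
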