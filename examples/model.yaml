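baseline_differentiation: 0.05
max_differentiation: 0.5
dose_midpoint_ng_per_ml: 300
steepness: 0.04
seed: 1
cells_per_chamber: 200
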