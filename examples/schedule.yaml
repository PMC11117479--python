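profile: default
pulses:
  - species: EGF
    channel: 1
    path: path1
    inlet_ng_per_ml: 500
    repeats: 2
  - species: FGF
    channel: 2
    path: path2
    inlet_ng_per_ml: 200
    repeats: 1
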