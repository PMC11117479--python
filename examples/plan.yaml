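profile: default
drugs:
  - {name: EGF, inlet_ng_per_ml: 500, channel: 1, path: path1}
  - {name: FGF, inlet_ng_per_ml: 200, channel: 2, path: path2}
  - {name: PDGF, inlet_ng_per_ml: 1000, channel: 3, path: path2}
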