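n_arrays: 8
chambers_per_array: 5
channels_per_array: 3
geometry:
  chamber_width_um: 250.0
  chamber_length_um: 2000.0
  exchange_window_width_um: 250.0
  exchange_window_length_um: 790.0
  channel_height_class: rounded
metadata:
  footprint_cm: [6.0, 5.0, 0.5]
  valve_closing_pressure_psi: [25.0, 30.0]
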