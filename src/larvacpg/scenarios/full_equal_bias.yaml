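name: full_equal_bias
circuit: full_model
circuit_options: {}
duration_ms: 600000.0
dt_ms: 1.0
seed: 3
record_every: 5
episodes:
- {type: pulse_train, cell: C_F_L, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_F_R, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_HL, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_HR, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
blocks: []
opto: null
analysis:
  side: L
  sweep_channel: T1
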