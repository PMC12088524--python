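name: abdominal_poisson
circuit: abdominal_chain
circuit_options: {}
duration_ms: 300000.0
dt_ms: 1.0
seed: 1
record_every: 2
episodes:
- {type: pulse_train, cell: C_F, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_B, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
blocks: []
opto: null
analysis:
  anterior_group: [A1, A2]
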