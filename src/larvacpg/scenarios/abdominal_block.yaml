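name: abdominal_block
circuit: abdominal_chain
circuit_options: {}
duration_ms: 90000.0
dt_ms: 1.0
seed: 0
record_every: 1
episodes:
- {type: tonic, cell: C_F, start: 1000.0, stop: 90000.0, amplitude: 0.02}
blocks:
- {segment: A4, mode: forwards, window: [1000.0, 90000.0]}
opto: null
analysis:
  segments: [A8, A7, A6, A5]
  anterior_group: [A1, A2]
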