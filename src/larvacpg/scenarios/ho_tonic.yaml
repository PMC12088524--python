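name: ho_tonic
circuit: hemisegmental_oscillator
circuit_options: {}
duration_ms: 60000.0
dt_ms: 1.0
seed: 0
record_every: 1
episodes:
- {type: tonic, cell: C_B, start: 1000.0, stop: 60000.0, amplitude: 0.02}
blocks: []
opto: null
analysis: {}
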