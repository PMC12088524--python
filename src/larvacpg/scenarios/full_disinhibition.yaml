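name: full_disinhibition
circuit: full_model
circuit_options: {}
duration_ms: 420000.0
dt_ms: 1.0
seed: 4
record_every: 5
episodes:
- {type: pulse_train, cell: C_F_L, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_F_R, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_HL, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: pulse_train, cell: C_HR, msi: 1000.0, width: 100.0, amplitude: 0.01, start: 1000.0}
- {type: opto_window, start: 180000.0, stop: 240000.0}
blocks: []
opto:
  classes: [I, D_IF, D_IB, D_WF, D_WB, D_HL, D_HR]
  g_opto_Cl: 0.2
analysis:
  side: L
  sweep_channel: T1
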