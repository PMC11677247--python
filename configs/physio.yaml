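# Physiological loading: rest (100 N) and mastication (200 N)
geometry:
  d: 500.0e-6
  phase: 1
protocol: physio
target_list: [100.0, 200.0]
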