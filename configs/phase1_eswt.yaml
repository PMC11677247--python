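# Phase-1 (primary matrix) shock wave scenario on the scaled benchmark
geometry:
  d: 500.0e-6
  phase: 1
protocol: eswt
efd_list: [0.02, 0.15, 0.26]
cadence: 10
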