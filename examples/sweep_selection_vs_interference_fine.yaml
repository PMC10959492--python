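# gamma* over s1 x cri, neutral T2 -- finer grid (roughly an hour on one
# CPU; resumable, completed cells are cached in the output TSV).
params:
  s2: 0.0
sweep:
  axis1: {name: s1, values: [0.0025, 0.005, 0.0075, 0.01, 0.0125, 0.015, 0.0175, 0.02]}
  axis2: {name: cri, values: [0.0, 0.00125, 0.0025, 0.00375, 0.005]}
  gamma_t0: [0.5]
  output: selection_vs_interference_fine.tsv
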