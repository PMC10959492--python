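# gamma* over s1 x s2 (both traits under selection) at a fixed level of
# reproductive interference; run with cri 0 / 0.0025 / 0.005 to see the
# interference-driven reversal of which trait becomes sexy.
params:
  cri: 0.0025
sweep:
  axis1: {name: s1, values: [0.005, 0.01, 0.02]}
  axis2: {name: s2, values: [0.005, 0.01, 0.02]}
  gamma_t0: [0.5]
  output: two_trait_selection_coarse.tsv
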