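# gamma* over natural-selection strength (s1) x reproductive interference
# (cri), neutral T2 -- coarse grid (minutes on one CPU).
# At s1 = 0 with cri > 0 both traits are neutral and exactly symmetric, so
# the deterministic flow from gamma_t0 = 0.5 stays at 0.5; the grid starts
# at s1 > 0 where the contrast is meaningful.
params:
  s2: 0.0
sweep:
  axis1: {name: s1, values: [0.005, 0.01, 0.02]}
  axis2: {name: cri, values: [0.0, 0.0025, 0.005]}
  gamma_t0: [0.5]
  output: selection_vs_interference_coarse.tsv
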