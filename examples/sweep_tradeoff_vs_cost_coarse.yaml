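# gamma* over the trade-off shape a x cost of choosiness c, for three
# ancestral weightings (mainly-T1, balanced, mainly-T2): the regime where
# the sensory trade-off and the cost of choosiness decide between single-
# and multiple-trait preference and where ancestral preference matters.
params:
  s1: 0.02
  s2: 0.0
  cri: 0.0025
sweep:
  axis1: {name: a, values: [0.3679, 1.0, 2.7183]}   # log a = -1, 0, 1
  axis2: {name: c, values: [0.0, 0.005, 0.02]}
  gamma_t0: [0.01, 0.5, 0.99]
  output: tradeoff_vs_cost_coarse.tsv
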