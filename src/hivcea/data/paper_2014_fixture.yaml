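# Canonical published input set for the DAART vs SAART cost-utility model.
# Annual (per-cycle) quantities; money in US$2014. Diagonal (stay)
# probabilities are not listed: they are the residual row mass.
transitions:
  I:   {II: 0.227, III: 0.086, IV: 0.062, death: 0.022}
  II:  {I: 0.195, III: 0.202, IV: 0.099, death: 0.034}
  III: {I: 0.053, II: 0.171, IV: 0.237, death: 0.043}
  IV:  {I: 0.021, II: 0.095, III: 0.174, death: 0.106}
costs:
  I: 176.44
  II: 347.44
  III: 498.44
  IV: 1272.44
utilities:
  I: 0.94
  II: 0.89
  III: 0.83
  IV: 0.73
daart:
  annual_cost: 964.0
effect:
  rr: 1.29
  ci_low: 1.12
  ci_high: 1.48
# 'Natural' age-specific annual all-cause mortality, South Africa 2015
# projection; step function, last value held beyond age 80.
mortality:
  - [10, 0.0021]
  - [15, 0.0020]
  - [20, 0.0034]
  - [25, 0.0054]
  - [30, 0.0087]
  - [35, 0.0143]
  - [40, 0.0177]
  - [45, 0.0190]
  - [50, 0.0220]
  - [55, 0.0263]
  - [60, 0.0320]
  - [65, 0.0414]
  - [70, 0.0591]
  - [75, 0.0830]
  - [80, 0.1138]
econ:
  discount_rate_costs: 0.03
  discount_rate_qalys: 0.03
  start_age: 20
  max_age: 100
  cycle_length: 1
  half_cycle_correction: true
  wtp_threshold: 5086.0
  discount_from: second
  rr_adjusts_death: false
ranges:
  transition.I.II: [0.187, 0.271]
  transition.I.III: [0.061, 0.118]
  transition.I.IV: [0.040, 0.090]
  transition.I.death: [0.010, 0.042]
  transition.II.I: [0.163, 0.230]
  transition.II.III: [0.170, 0.238]
  transition.II.IV: [0.076, 0.127]
  transition.II.death: [0.021, 0.053]
  transition.III.I: [0.037, 0.074]
  transition.III.II: [0.142, 0.203]
  transition.III.IV: [0.204, 0.273]
  transition.III.death: [0.028, 0.063]
  transition.IV.I: [0.011, 0.037]
  transition.IV.II: [0.072, 0.122]
  transition.IV.III: [0.144, 0.208]
  transition.IV.death: [0.082, 0.134]
  # The published State I/II cost ranges are inconsistent with their base
  # values; they are stored verbatim and re-centred on the base for
  # uncertainty analysis.
  cost.state_I: [383.0, 639.0]
  cost.state_II: [383.0, 639.0]
  cost.state_III: [404.0, 674.0]
  cost.state_IV: [997.0, 1661.0]
  cost.daart: [723.0, 1205.0]
  utility.state_I: [0.92, 1.00]
  utility.state_II: [0.80, 1.00]
  utility.state_III: [0.45, 1.00]
  utility.state_IV: [0.24, 0.80]
  effect.rr: [1.12, 1.48]
  econ.discount_rate: [0.00, 0.05]
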