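# Utility inputs (general-population values).  Disease-state and strategy
# utilities act as multipliers on the age-specific disease-free utility
# (multiplicative age adjustment).  variation_pct is the +-% spread used in
# sensitivity analysis (interpreted as half-range of a 95% interval).
df_by_age:
  - {ages: "30-39", value: 0.901}
  - {ages: "40-49", value: 0.871}
  - {ages: "50-59", value: 0.842}
  - {ages: "60-69", value: 0.823}
  - {ages: "70-79", value: 0.790}
  - {ages: "80+",   value: 0.736}
state_multipliers:
  BC:  {value: 0.637, variation_pct: 20}
  CBC: {value: 0.637, variation_pct: 20}   # same utility weights as primary BC
  MBC: {value: 0.533, variation_pct: 20}
  OC:  {value: 0.410, variation_pct: 20}   # mean of 0.56/0.56/0.43/0.43/0.08, as printed
strategy_utilities:
  IS:       {value: 0.960, variation_pct: 5}
  PBM:      {value: 0.880, variation_pct: 10}
  PBSO:     {value: 0.900, variation_pct: 10}
  PBM_PBSO: {value: 0.790, variation_pct: 10}
  CP:       {value: 0.900, variation_pct: 5}
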