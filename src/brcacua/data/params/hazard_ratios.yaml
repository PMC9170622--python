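# Effectiveness of risk-reducing interventions, expressed as hazard ratios
# on the affected event rate (SE on the natural scale).
# CP_ERpos_BC is the relative effect of Tamoxifen on hormone-receptor-positive
# breast cancer only; it is diluted over the subtype mix by the engine.
PBSO_OC:          {value: 0.28, se: 0.14}   # OC incidence after PBSO (incl. residual peritoneal risk)
PBSO_OC_prior_BC: {value: 0.14, se: 0.14}   # OC incidence after PBSO given prior BC
PBM_BC:           {value: 0.09, se: 0.09}   # BC incidence after PBM
CP_ERpos_BC:      {value: 0.31, se: 0.06}   # ER+ BC incidence under Tamoxifen
CP_CBC_BRCA1:     {value: 0.44, se: 0.15}   # CBC incidence under Tamoxifen, BRCA1
CP_CBC_BRCA2:     {value: 0.33, se: 0.12}   # CBC incidence under Tamoxifen, BRCA2
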