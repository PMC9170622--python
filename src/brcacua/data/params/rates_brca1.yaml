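# Annual event rates (events per person-year) for BRCA1 mutation carriers,
# with standard errors (SE derived from 95% CIs, width ~ 4*SE) or ranges
# where only a range is reported.  Age bands are inclusive on both ends;
# "x+" is unbounded above.  Cancer-specific mortality applies during the
# first 10 years after diagnosis; afterwards only all-cause mortality acts.
mutation: BRCA1
tables:
  df_bc:
    - {ages: "21-30", rate: 0.0059, se: 0.002}
    - {ages: "31-40", rate: 0.0248, se: 0.003}
    - {ages: "41-50", rate: 0.0309, se: 0.004}
    - {ages: "51-60", rate: 0.0269, se: 0.007}
    - {ages: "61+",   rate: 0.0167, se: 0.005}
  df_oc:
    - {ages: "30-39", rate: 0.0016, se: 0.0007}
    - {ages: "40-49", rate: 0.0155, se: 0.0011}
    - {ages: "50-59", rate: 0.0220, se: 0.0013}
    - {ages: "60-69", rate: 0.0165, se: 0.0015}
    - {ages: "70+",   rate: 0.0079, se: 0.0011}
  bc_cbc:
    - {ages: "21-30", rate: 0.0119, se: 0.007}
    - {ages: "31-40", rate: 0.0407, se: 0.007}
    - {ages: "41-50", rate: 0.0209, se: 0.005}
    - {ages: "51-60", rate: 0.0328, se: 0.007}
    - {ages: "61-70", rate: 0.0117, se: 0.007}
    # printed band 71-80; kept open-ended so the lifelong horizon is covered
    - {ages: "71+",   rate: 0.0197, se: 0.014}
  bc_mbc:
    - {ages: "0+", rate: 0.0278, se: 0.002}
  bc_oc:
    - {ages: "0+", rate: 0.0185, range: [0.012, 0.058]}
  postoc_bc:
    - {ages: "0+", rate: 0.0144, range: [0.010, 0.043]}
  bc_dead:
    - {ages: "0-49",  rate: 0.0209, se: 0.0025}
    - {ages: "50-69", rate: 0.0318, se: 0.0027}
    - {ages: "70+",   rate: 0.1066, se: 0.005}
  mbc_dead:
    - {ages: "0-49",  rate: 0.2033, se: 0.0345}
    - {ages: "50-69", rate: 0.2558, se: 0.0487}
    - {ages: "70+",   rate: 0.2608, se: 0.029}
  oc_dead:
    - {ages: "15-44", rate: 0.0621, se: 0.006}
    - {ages: "45-54", rate: 0.1086, se: 0.007}
    - {ages: "55-64", rate: 0.1536, se: 0.007}
    - {ages: "65-74", rate: 0.1983, se: 0.008}
    - {ages: "75+",   rate: 0.2741, se: 0.012}
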