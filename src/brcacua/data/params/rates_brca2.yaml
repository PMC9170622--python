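# Annual event rates (events per person-year) for BRCA2 mutation carriers.
# Where the source table gives no separate BRCA2 value (cancer-specific
# mortality, BC/CBC->MBC) the BRCA1 value is duplicated.
mutation: BRCA2
tables:
  df_bc:
    - {ages: "21-30", rate: 0.0048, se: 0.002}
    - {ages: "31-40", rate: 0.0109, se: 0.002}
    - {ages: "41-50", rate: 0.0330, se: 0.005}
    - {ages: "51-60", rate: 0.0448, se: 0.008}
    - {ages: "61+",   rate: 0.0247, se: 0.005}
  df_oc:
    - {ages: "30-39", rate: 0.0000, se: 0.0000}
    - {ages: "40-49", rate: 0.0012, se: 0.0009}
    - {ages: "50-59", rate: 0.0050, se: 0.0014}
    - {ages: "60-69", rate: 0.0135, se: 0.0020}
    - {ages: "70+",   rate: 0.0037, se: 0.0013}
  bc_cbc:
    - {ages: "21-30", rate: 0.0000, se: 0.000}
    - {ages: "31-40", rate: 0.0186, se: 0.007}
    - {ages: "41-50", rate: 0.0240, se: 0.006}
    - {ages: "51-60", rate: 0.0224, se: 0.006}
    - {ages: "61-70", rate: 0.0167, se: 0.007}
    # printed band 71-80; kept open-ended so the lifelong horizon is covered
    - {ages: "71+",   rate: 0.0132, se: 0.012}
  bc_mbc:
    - {ages: "0+", rate: 0.0278, se: 0.002}
  bc_oc:
    - {ages: "0+", rate: 0.0102, se: 0.011}
  postoc_bc:
    - {ages: "0+", rate: 0.0095, range: [0.007, 0.0281]}
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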