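# Declarative definitions of the five risk-reducing strategies.  Hazard-ratio
# effects reference keys in params/hazard_ratios.yaml; utility decrements are
# looked up by strategy name in params/utilities.yaml.  "{mutation}" in an
# effect key is substituted with BRCA1/BRCA2 at run time.
IS:
  display: "IS"
  hr_effects: {}
  disutility_mode: surveillance   # decrement in every surveillance-imaging year
  one_off: []
PBM:
  display: "PBM"
  hr_effects:
    bc_incidence: PBM_BC
  disutility_mode: first_year
  one_off: [pbm_surgery]
  implant_replacement: true
PBSO:
  display: "PBSO"
  hr_effects:
    oc_incidence: PBSO_OC
    oc_incidence_prior_bc: PBSO_OC_prior_BC
  disutility_mode: first_year
  one_off: [pbso_surgery]
  hrt: true
PBM_PBSO:
  display: "PBM & PBSO"
  hr_effects:
    bc_incidence: PBM_BC
    oc_incidence: PBSO_OC
    oc_incidence_prior_bc: PBSO_OC_prior_BC
  disutility_mode: first_year
  one_off: [pbm_surgery, pbso_surgery]
  hrt: true
  implant_replacement: true
CP:
  display: "CP"
  hr_effects:
    erpos_bc_incidence: CP_ERpos_BC
    cbc_incidence: "CP_CBC_{mutation}"
  disutility_mode: drug_years     # decrement while on Tamoxifen (5 years)
  drug_years: 5
  one_off: []
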