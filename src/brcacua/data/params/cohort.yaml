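# Cohort assumptions: molecular subtype mix of incident breast cancers and
# treatment-pathway fractions used by the cost model.
subtype_mix:
  BRCA1: {hr_pos: 0.20, tnbc: 0.70, her2: 0.10}
  BRCA2: {hr_pos: 0.80, tnbc: 0.10, her2: 0.10}
assumptions:
  radiotherapy_fraction: 0.38       # nodal involvement requiring radiotherapy
  implant_fraction: 0.95            # implant-based vs autologous reconstruction
  reshaping_fraction: 0.50          # breast reshaping after reconstruction
  hrt_end_age: 51                   # hormone replacement until natural menopause
  implant_replacement_interval: 10  # years between implant replacements
  implant_replacement_stop_age: 70
  oc_residual_disease_fraction: 0.63
  oc_relapse_fraction: 0.73
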