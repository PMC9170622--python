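currency EUR
synthetic true
[one_off]
pbm_surgery 22050.000000
pbso_surgery 8000.000000
[state_year]
BC 1 56460.000000
BC 2 4000.000000
BC 3 2000.000000
BC 4 2000.000000
BC 5 2000.000000
BC 6 400.000000
BC 7 400.000000
BC 8 400.000000
BC 9 400.000000
BC 10 400.000000
OC 1 95000.000000
OC 2 48500.000000
OC 3 25500.000000
OC 4 25500.000000
OC 5 25500.000000
OC 6 500.000000
OC 7 500.000000
OC 8 500.000000
OC 9 500.000000
OC 10 500.000000
MBC 0 36000.000000
[recurring]
IS DF 0-59 1300.000000
IS DF 60-69 500.000000
IS DF 70+ 400.000000
PBM DF 0+ 300.000000
PBSO DF 0-59 1300.000000
PBSO DF 60-69 500.000000
PBSO DF 70+ 400.000000
PBSO DF 0-50 300.000000
PBM_PBSO DF 0+ 150.000000
PBM_PBSO DF 0-50 300.000000
CP DF 0-59 1300.000000
CP DF 60-69 500.000000
CP DF 70+ 400.000000
PBM PostBC 0+ 300.000000
PBM_PBSO PostBC 0+ 150.000000
IS PostBC 0-59 1300.000000
IS PostBC 60-69 500.000000
IS PostBC 70+ 400.000000
PBSO PostBC 0-59 1300.000000
PBSO PostBC 60-69 500.000000
PBSO PostBC 70+ 400.000000
CP PostBC 0-59 1300.000000
CP PostBC 60-69 500.000000
CP PostBC 70+ 400.000000
PBM PostCBC 0+ 300.000000
PBM_PBSO PostCBC 0+ 150.000000
IS PostCBC 0-59 1300.000000
IS PostCBC 60-69 500.000000
IS PostCBC 70+ 400.000000
PBSO PostCBC 0-59 1300.000000
PBSO PostCBC 60-69 500.000000
PBSO PostCBC 70+ 400.000000
CP PostCBC 0-59 1300.000000
CP PostCBC 60-69 500.000000
CP PostCBC 70+ 400.000000
PBM PostOC 0+ 270.000000
PBM_PBSO PostOC 0+ 270.000000
IS PostOC 0-59 1300.000000
IS PostOC 60-69 500.000000
IS PostOC 70+ 400.000000
IS PostOC 0+ 120.000000
PBSO PostOC 0-59 1300.000000
PBSO PostOC 60-69 500.000000
PBSO PostOC 70+ 400.000000
PBSO PostOC 0+ 120.000000
CP PostOC 0-59 1300.000000
CP PostOC 60-69 500.000000
CP PostOC 70+ 400.000000
CP PostOC 0+ 120.000000
[drug]
CP 350.000000
[annuity]
implant_replacement 8000.000000
[palliative]
all 25000.000000
[components]
bc_reconstruction 18600.000000
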