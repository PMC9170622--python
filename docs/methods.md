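# Methods

## Model structure

The model is a discrete-time Markov cohort simulation over nine aggregate
health states: disease-free (DF), breast cancer (BC), contralateral breast
cancer (CBC), metastatic breast cancer (MBC), ovarian cancer (OC), post-BC,
post-CBC, post-OC, and dead. BC, CBC and OC are expanded into ten one-year
tunnel states (36 expanded states in total) because three quantities depend
on time since diagnosis: cancer-specific mortality (applied for ten years,
after which only all-cause mortality acts in the post-cancer states),
treatment costs (a per-year schedule over the ten post-diagnosis years),
and utility (a disease multiplier recovering linearly over five years).

Allowed transitions follow the clinical logic of surveillance-detected
disease: metastatic disease arises only from BC/CBC (never directly from
DF); nothing returns from MBC except death; a woman who develops CBC starts
a fresh ten-year tunnel; BC after OC is possible only from the post-OC
state (metachronous disease, entering the ordinary BC tunnel); ipsilateral
recurrence is not modelled (contralateral disease is the recurrent-BC
proxy). The cohort starts 100% disease-free at the start age (40 in the
base case) and is propagated for 60 annual cycles; earlier start ages
extend the horizon so it always reaches age 100.

### Rates, probabilities and competing risks

All epidemiological inputs are annual event rates per person-year, held in
age-banded tables (bands inclusive on both ends; an age on a printed band
boundary belongs to the band it closes, so the start age 40 uses the 31–40
incidence band). Rates are converted to one-cycle probabilities exactly
once, inside the engine, with the proportional exponential split for
competing exits from a state:

    p_event = (r_event / R) · (1 − e^(−R)),  p_stay = e^(−R),  R = Σ r_event.

This is order-independent and normalises each matrix row exactly, which the
engine asserts to 1e−12 per row and 1e−10 on the propagated occupancy.

Two structural choices were genuinely open and are worth stating:

* **Background mortality inside cancer states.** Cancer-specific death
  rates govern the first ten years after diagnosis, but the source material
  is silent on whether all-cause mortality also acts there. We add the
  life-table rate as a competing risk inside the BC/CBC/OC tunnels and MBC
  (toggle `background_mortality_in_cancer_states`); omitting it produces
  an implausibly immortal cancer cohort at high ages.
* **Age-band edges.** The mortality tables print bands "0–49 / 50–69 /
  70+", and the CBC-incidence table ends at 80. Bands are read as
  non-overlapping and the terminal CBC band is extended open-ended so the
  lifelong horizon stays covered.

### Strategy effects

Each strategy is a declarative specification (shipped as YAML, not code)
binding hazard ratios to event classes: PBM multiplies BC incidence by
0.09; PBSO multiplies OC incidence by 0.28 from the disease-free state and
by 0.14 once a woman has a BC history (the stronger effect *replaces*, not
multiplies, the weaker one); PBSO has no effect on BC incidence;
chemoprevention applies its hazard ratio 0.31 only to the
hormone-receptor-positive fraction of incident BC, diluted over the
mutation-specific subtype mix (20% HR+ for BRCA1, 80% for BRCA2):
r_eff = r · (f_HR+ · 0.31 + (1 − f_HR+)), and reduces CBC incidence by the
mutation-specific hazard ratio (0.44 / 0.33). Surgical risk reduction is
anatomical and therefore lifelong; the Tamoxifen effect is lifelong in the
base case with a 5-year scenario. BC-incidence effects are also applied to
the post-OC → BC re-entry (the source is silent; a mastectomy's effect
persists regardless of an intervening ovarian cancer). A configuration
switch (`cp_value_is_rrr`) reinterprets the 0.31 as a relative risk
reduction (i.e. hazard ratio 0.69) for users who prefer that reading.

### Utilities

Utilities use the multiplicative age adjustment: age-specific disease-free
utilities (0.901 at 30–39 falling to 0.736 at 80+) times a state or
intervention multiplier. Disease multipliers (BC/CBC 0.637, MBC 0.533, OC
0.410) apply in the first year after diagnosis and recover linearly to 1 by
year six, m(t) = u_d + (1 − u_d)(t − 1)/5 — the only linear interpolation
with m(1) = u_d and full recovery after five years. MBC is terminal and
keeps its multiplier until death. The OC constant 0.410 is used as printed;
the five-component average it derives from (0.56, 0.56, 0.43, 0.43, 0.08 →
0.412) is implemented separately for verification. Strategy decrements in
the DF state: surgical utilities (PBM 0.88, PBSO 0.90, combined 0.79) for
one year after surgery; Tamoxifen 0.90 for the 5-year intake; surveillance
0.96 in **every** year in which imaging occurs (annually below 70,
biennially after) — the duration of the surveillance decrement is not
stated in the source, this choice materially lowers the IS QALY total, and
a switch (`is_disutility_every_year=False`) restricts it to the first year.
The duration scenarios hold the surgical multiplier constant for 5 or 10
years (no linear recovery), leaving IS and CP untouched.

### Costs

The cost model is a pure data artifact: a sectioned text schedule with
one-off surgery costs (mastectomy with 95% implant / 5% autologous
reconstruction and 50% reshaping; oophorectomy), per-year-since-diagnosis
treatment costs for BC/CBC (surgery, reconstruction, radiotherapy weighted
by the 38% nodal-involvement fraction, chemo-/targeted therapy weighted by
the mutation's subtype mix) and OC (surgery, chemotherapy, PARP-inhibitor
maintenance, recurrence-adjusted years 3–5), an annual MBC cost defined as
subtype-weighted total therapy cost divided by median overall survival,
strategy- and age-dependent recurring surveillance/follow-up costs, hormone
replacement to age 51 for oophorectomy arms, Tamoxifen drug plus annual
vaginal ultrasound during the intake window, an implant-replacement annuity
(every 10 years to age 70; charged as lump sums at cycles 10/20/30 for the
PBM arms and at post-state entry for cancer-related reconstructions, with
an amortised per-year mode as an alternative), and a palliative lump sum
charged to cohort mass dying out of BC, CBC, MBC or OC. CBC uses the BC
schedule throughout. The immediate-vs-later reconstruction scenario moves
the reconstruction amount from year 1 to year 2 of the BC schedule.
Costs are kept in EUR and converted at the fixed rate 1 EUR = 1.10 CHF.

Because the real tariff-level schedules are not public data, the packaged
schedules are synthetic fixtures assembled from per-item anchors chosen
once at plausible Swiss magnitudes (e.g. breast MRI 800 EUR, mastectomy
with implant reconstruction 19,000 EUR, PARP-inhibitor year 60,000 EUR,
palliative lump 25,000 EUR; full list in `brcacua.synthetic`). Every
fixture carries a `synthetic` flag that the CLI surfaces as a watermark
comment in all CSV output. Consequences: QALY and LY outputs depend only on
published inputs plus the life-table stand-in and are regression-tested
against the published base case at ±5%; absolute cost outputs are
fixture-dependent and only their direction and ordering (prophylaxis
cost-saving; BRCA1 dearer than BRCA2) are meaningful.

### Life-table fixture

All-cause female mortality uses a Gompertz–Makeham stand-in,
q(age) = 1 − exp(−(2.0e−4 + 4.1e−6·e^(0.118·age))), calibrated once against
public summary anchors for a modern low-mortality female population
(q40 ≈ 6.6e−4, q80 ≈ 5.0e−2, disease-free life expectancy at 40 ≈ 43 years
with the model's horizon truncation at age 100). It reproduces the shape,
not the exact values, of a national period life table; tests assert a
plausibility corridor rather than national statistics.

## Discounting and rewards

Costs and outcomes are discounted at 3%/year separately configurable;
cycle 0 is undiscounted and prophylactic surgery (cost and disutility)
falls at the start of cycle 0. Rewards accrue on beginning-of-cycle
occupancy; no half-cycle correction is applied by default (a
`half_cycle_correction` flag averages beginning- and end-of-cycle
membership for LY/QALY rewards). Palliative lump sums are charged in the
cycle during which the death transition occurs.

## Sensitivity analysis

Uncertain parameters carry the printed spreads: standard errors (95% CI
width / 4), ranges (sampled uniformly: the BRCA1 BC→OC rate and both
post-OC→BC rates), or ±% variations for utilities, read as the half-range
of a 95% interval (SE = pct·central/1.96; a switch treats the percentage as
the SE directly). Fixture cost amounts get a ±20% half-range. Families
follow parameter class: gamma for rates and costs, lognormal for hazard
ratios (moment-matched on the natural scale, since spreads are printed on
that scale), beta for utilities. Samplers are untruncated so their moments
match (central, SE) exactly — verified to 3 Monte-Carlo standard errors
over 10^6 draws — and draws are clipped to the admissible support only when
applied to the model (rates/costs ≥ 0, hazard ratios and utilities in
(0, 1]); the clipped mass is far below 1% for every base-case parameter.
Parameters are sampled jointly and independently (no correlation structure
is published), with the same draw applied to every strategy within an
iteration (common random numbers). One-way bounds are central ± 1.96·SE
truncated to support, or the stated range. The default PSA size is 10,000
iterations (~3 minutes per mutation on one CPU); the acceptance script uses
500 and the test suite 200 — at those sizes the probability that combined
surgery is optimal is already ≈ 1, so the qualitative conclusion is
insensitive to the iteration count.

## Verification strategy

The suite checks, among others: exact transcription of the published rate
tables; row-normalisation and structurally forbidden transitions of every
matrix; occupancy conservation to 1e−10 under 200 randomised
parameterisations; a closed-form geometric-series limit (DF/Dead-only
model) to 1e−9; agreement of the cohort trace with an independent
200,000-woman individual-level microsimulation driven by the same matrices
(within 3 Monte-Carlo SEs, implemented as per-state multinomial count
updates, which is distribution-identical to simulating women one at a
time); an exhaustive brute-force oracle for the dominance frontier on all
strategy subsets up to size six; and the directional findings (combined
surgery cheapest and most effective in both mutations, BRCA1 costlier than
BRCA2 under every strategy, QALY gains shrinking monotonically with longer
surgical disutility, PSA preserving the dominant strategy). Passing these
on synthetic fixtures demonstrates correctness of the machinery and
fidelity of the epidemiological/utility layers; it does not validate the
absolute cost level, which would require the original tariff data.

## Known limitations

* No compliance modelling beyond intention-to-treat effect sizes; no
  adverse events of Tamoxifen or surgery (endometrial cancer, thrombosis,
  perioperative mortality), no HRT-attributable cancer risk.
* Ten-year tunnels cap the memory of time since diagnosis; second implant
  replacements after cancer-related reconstruction (20+ years) are not
  tracked in lump mode.
* MBC utility does not recover (terminal state by construction).
* The cost fixture is synthetic: absolute costs, dCosts and ICER magnitudes
  should not be quoted as Swiss estimates.
* Utilities come from general-population samples; mutation-carrier-specific
  utilities (generally higher for prophylaxis) would shift QALY gaps.
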