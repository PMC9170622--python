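# brcacua

A decision-analytic Markov cohort model comparing risk-reducing strategies
for women who carry a pathogenic **BRCA1** or **BRCA2** mutation but have no
personal history of cancer. The package is written for health-economic
modellers and methods researchers: it reproduces a published Swiss
cost-utility analysis as tested, reusable Python, and exposes every layer
(parameters, transition engine, cost model, comparative economics,
sensitivity and scenario machinery) as a library plus a small CLI.

## The model

Five strategies, initiated at age 40, are compared from the healthcare-system
perspective:

| code | strategy |
|------|----------|
| `IS` | intensified surveillance (reference): semi-annual consultations, age-related MRI/mammography |
| `PBM` | prophylactic bilateral mastectomy (BC hazard ratio 0.09) |
| `PBSO` | prophylactic bilateral salpingo-oophorectomy (OC hazard ratio 0.28; 0.14 with prior BC) |
| `PBM_PBSO` | both surgeries combined |
| `CP` | chemoprevention with Tamoxifen for 5 years (hazard ratio 0.31 on the HR+ fraction of BC; CBC hazard ratio 0.44 / 0.33 for BRCA1 / BRCA2) |

The Markov model has nine aggregate health states — disease-free (DF),
breast cancer (BC), contralateral BC (CBC), metastatic BC (MBC), ovarian
cancer (OC), post-BC, post-CBC, post-OC, and dead — expanded into 36 states
by ten-year tunnels for BC, CBC and OC so that cancer-specific mortality,
year-specific treatment costs, and utility recovery can depend on time since
diagnosis. Cycles are annual; the horizon is 60 cycles (lifelong). Annual
event rates r are converted to probabilities with competing risks resolved
by the proportional exponential split

```
p_event = (r_event / R) (1 − e^(−R)),   p_stay = e^(−R),   R = Σ r_event ,
```

costs and QALYs are discounted at 3%/year, and utilities use the
multiplicative age adjustment (e.g. BC at age 50 in the diagnosis year:
0.842 × 0.637 = 0.536) with linear recovery to the age-specific baseline
over five years. Comparative results are summarised as a league table with
incremental costs/QALYs/LYs versus IS, ICERs or dominance labels, and net
monetary benefit at a willingness-to-pay of CHF 100,000/QALY
(= EUR 90,909 at 1 EUR = 1.10 CHF). One-way (tornado) and probabilistic
sensitivity analyses (gamma for rates/costs, lognormal for hazard ratios,
beta for utilities) and all published scenario analyses are included.

Two inputs are not public data and ship as clearly watermarked synthetic
fixtures generated by `brcacua.synthetic`: a Gompertz–Makeham female life
table and a tariff-level cost schedule with plausible Swiss magnitudes.
All other inputs (rates, hazard ratios, utilities) are the published values,
packaged as editable YAML under `src/brcacua/data/params/`.

## Worked example

```python
from brcacua import load_inputs, CohortConfig, run_all_strategies, league_table

inputs = load_inputs("BRCA1")            # packaged tables + synthetic fixtures
cfg = CohortConfig(mutation="BRCA1")     # age 40, 60 cycles, 3% discount
print(league_table(run_all_strategies(inputs, cfg)).to_string(index=False))
```

```
strategy          cost      qaly        ly        d_cost   d_qaly     d_ly      icer      dominance
      IS 120271.550249 14.794587 18.938116      0.000000 0.000000 0.000000 reference abs. dominated
      CP 115938.295296 15.104224 19.183959  -4333.254953 0.309637 0.245843  dominant abs. dominated
    PBSO 104241.287780 16.560155 20.506493 -16030.262469 1.765568 1.568377  dominant abs. dominated
     PBM 102488.099695 16.948506 20.756076 -17783.450555 2.153919 1.817959  dominant abs. dominated
PBM_PBSO  74154.396459 18.774471 22.838474 -46117.153790 3.979884 3.900358  dominant       dominant
```

Reading the table: under surveillance a BRCA1 carrier accrues 14.79
discounted QALYs and 18.94 discounted life years for ~120 kEUR of lifetime
costs (fixture cost schedule — hence the watermark in CSV outputs); every
prophylactic strategy is cheaper *and* more effective than surveillance
("dominant" in the ICER column means cost-saving with a QALY gain), and the
combined surgery dominates all alternatives — the published qualitative
result. The QALY/LY columns agree with the published table within ±5% on
the bundled life-table fixture; absolute costs depend on the synthetic
tariff fixture and are only directionally comparable.

The same analyses are available from the shell:

```bash
cua run --mutation both --out results/
cua psa --n 10000 --seed 7 --out results/
cua tornado --mutation BRCA1 --out results/
cua scenario --name disutility_10y --out results/
```

## Layout

```
src/brcacua/
  params.py       published rate/utility/hazard-ratio tables, validation, lookups
  statespace.py   9 aggregate states expanded to 36 tunnel states
  engine.py       transition matrices, cohort trace, reward accumulation
  strategies.py   the five strategies as declarative specs (data-driven)
  costs.py        sectioned-text cost schedules and per-cycle cost increments
  qol.py          multiplicative age-adjusted utilities with linear recovery
  economics.py    league table, ICER/dominance, net monetary benefit
  sensitivity.py  tornado and probabilistic sensitivity analysis
  scenarios.py    declarative scenario overrides
  synthetic.py    life-table and cost-schedule fixture generators
  cli.py          `cua` command-line interface
  data/           parameter YAML, strategy specs, synthetic fixtures
```

See `docs/methods.md` for modelling assumptions, parameter provenance, and
known limitations.
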