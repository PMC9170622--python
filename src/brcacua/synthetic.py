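"""Synthetic stand-ins for inputs that are not public data.

Two inputs of the full pipeline are not printed anywhere reusable: the
Swiss female period life table and the tariff-level cost schedules.  This
module generates both deterministically so the whole model runs and is
tested without downloads:

* a Gompertz-Makeham female life table (constant background hazard plus an
  exponentially increasing senescent hazard), calibrated once against
  public summary figures for a modern low-mortality female population
  (q40 ~ 5e-4, q80 ~ 4e-2, remaining life expectancy at 40 ~ 45 years);
* a cost schedule with plausible Swiss magnitudes built from per-item
  anchors (surgery, imaging, chemo-/targeted-therapy by molecular subtype,
  PARP-inhibitor maintenance, palliative care), weighted by the
  mutation-specific subtype mix.

Everything generated here is watermarked ``synthetic`` so reports cannot be
mistaken for real tariff data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .costs import CostSchedule, RecurringEntry, write_cost_schedule
from .params import AgeBand, LifeTable, ParameterError, SubtypeMix

# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz-Makeham hazard: h(age) = makeham + gompertz_a * exp(gompertz_b * age)."""

    makeham: float = 2.0e-4
    gompertz_a: float = 4.1e-6
    gompertz_b: float = 0.118
    max_age: int = 100

    def hazard(self, age: float) -> float:
        return self.makeham + self.gompertz_a * math.exp(self.gompertz_b * age)


def make_life_table(spec: LifeTableSpec = LifeTableSpec()) -> LifeTable:
    """Deterministic annual death probabilities qx(age) = 1 - exp(-h(age))."""
    if spec.makeham < 0 or spec.gompertz_a < 0:
        raise ParameterError("hazard components must be >= 0")
    qx = []
    for age in range(spec.max_age + 1):
        q = -math.expm1(-spec.hazard(age))
        if q >= 1.0:
            raise ParameterError(f"life-table spec produces qx >= 1 at age {age}")
        qx.append(q)
    return LifeTable(tuple(qx))


def write_life_table(table: LifeTable, path: str | Path) -> None:
    lines = ["# synthetic Gompertz-Makeham female life table (age, qx)", "age,qx"]
    lines += [f"{age},{q:.8f}" for age, q in enumerate(table.qx)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# cost schedule
# ---------------------------------------------------------------------------

#: per-item anchors in EUR; the schedule is assembled from these
DEFAULT_ANCHORS: dict[str, float] = {
    "consultation": 150.0,
    "mammography": 200.0,
    "breast_mri": 800.0,
    "vaginal_ultrasound": 120.0,
    "pbm_surgery_implant": 19_000.0,
    "pbm_surgery_autologous": 30_000.0,
    "breast_reshaping": 5_000.0,
    "pbso_surgery": 8_000.0,
    "implant_replacement": 8_000.0,
    "hrt_annual": 300.0,
    "tamoxifen_annual": 230.0,
    "bc_surgery": 15_000.0,
    "bc_reconstruction_implant": 18_000.0,
    "bc_reconstruction_autologous": 30_000.0,
    "radiotherapy": 12_000.0,
    "chemo_y1_hr_pos": 10_000.0,
    "chemo_y1_tnbc": 25_000.0,
    "chemo_y1_her2": 45_000.0,
    "her2_targeted_y2": 20_000.0,
    "endocrine_annual": 1_500.0,       # HR+ adjuvant therapy, years 1-5
    "bc_followup_y1_5": 800.0,
    "bc_followup_y6_10": 400.0,
    "oc_surgery": 20_000.0,
    "oc_chemo_y1": 15_000.0,
    "parpi_annual": 60_000.0,          # maintenance, years 1-2
    "oc_recurrence_y3_5": 25_000.0,    # second-line treatment, relapse-weighted
    "oc_followup": 500.0,
    "mbc_total_hr_pos": 120_000.0,     # lifetime therapy cost by subtype
    "mbc_total_tnbc": 80_000.0,
    "mbc_total_her2": 200_000.0,
    "mbc_os_hr_pos": 4.0,              # median overall survival, years
    "mbc_os_tnbc": 1.5,
    "mbc_os_her2": 3.0,
    "palliative": 25_000.0,
}

DEFAULT_ASSUMPTIONS: dict[str, float] = {
    "radiotherapy_fraction": 0.38,
    "implant_fraction": 0.95,
    "reshaping_fraction": 0.50,
    "parpi_y2_fraction": 0.80,
}


@dataclass(frozen=True)
class CostFixtureSpec:
    """Deterministic cost-fixture recipe: anchors, optional jitter, seed."""

    seed: int = 0
    anchors: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    assumptions: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ASSUMPTIONS))
    jitter_pct: float = 0.0  # +-% multiplicative jitter around the anchors


def _surveillance_recurring(a: Mapping[str, float], strategy: str, state: str) -> list[RecurringEntry]:
    """Age-dependent intensified-surveillance package: annual MRI+mammography
    below 60, annual mammography to 69, biennial mammography (halved annual
    amount) from 70, plus semi-annual consultations throughout."""
    consults = 2 * a["consultation"]
    return [
        RecurringEntry(strategy, state, AgeBand(0, 59), a["breast_mri"] + a["mammography"] + consults),
        RecurringEntry(strategy, state, AgeBand(60, 69), a["mammography"] + consults),
        RecurringEntry(strategy, state, AgeBand(70, None), 0.5 * a["mammography"] + consults),
    ]


def make_cost_schedule(mix: SubtypeMix, spec: CostFixtureSpec = CostFixtureSpec()) -> CostSchedule:
    """Assemble the synthetic cost schedule for one mutation's subtype mix."""
    rng = np.random.default_rng(spec.seed)
    a = dict(spec.anchors)
    if spec.jitter_pct:
        for key in sorted(a):
            a[key] *= 1.0 + spec.jitter_pct / 100.0 * rng.uniform(-1.0, 1.0)
    asm = spec.assumptions

    w = {"hr_pos": mix.hr_pos, "tnbc": mix.tnbc, "her2": mix.her2}
    recon = (asm["implant_fraction"] * a["bc_reconstruction_implant"]
             + (1 - asm["implant_fraction"]) * a["bc_reconstruction_autologous"])
    chemo_y1 = sum(w[s] * a[f"chemo_y1_{s}"] for s in w)

    state_year: dict[tuple[str, int], float] = {}
    state_year[("BC", 1)] = (
        a["bc_surgery"] + recon + asm["reshaping_fraction"] * a["breast_reshaping"]
        + asm["radiotherapy_fraction"] * a["radiotherapy"]
        + chemo_y1 + a["bc_followup_y1_5"]
    )
    state_year[("BC", 2)] = (w["hr_pos"] * a["endocrine_annual"]
                             + w["her2"] * a["her2_targeted_y2"] + a["bc_followup_y1_5"])
    for y in (3, 4, 5):
        state_year[("BC", y)] = w["hr_pos"] * a["endocrine_annual"] + a["bc_followup_y1_5"]
    for y in range(6, 11):
        state_year[("BC", y)] = a["bc_followup_y6_10"]

    state_year[("OC", 1)] = a["oc_surgery"] + a["oc_chemo_y1"] + a["parpi_annual"]
    state_year[("OC", 2)] = asm["parpi_y2_fraction"] * a["parpi_annual"] + a["oc_followup"]
    for y in (3, 4, 5):
        state_year[("OC", y)] = a["oc_recurrence_y3_5"] + a["oc_followup"]
    for y in range(6, 11):
        state_year[("OC", y)] = a["oc_followup"]

    mbc_annual = sum(w[s] * a[f"mbc_total_{s}"] / a[f"mbc_os_{s}"] for s in w)

    one_off = {
        "pbm_surgery": (asm["implant_fraction"] * a["pbm_surgery_implant"]
                        + (1 - asm["implant_fraction"]) * a["pbm_surgery_autologous"]
                        + asm["reshaping_fraction"] * a["breast_reshaping"]),
        "pbso_surgery": a["pbso_surgery"],
    }

    consult = a["consultation"]
    recurring: list[RecurringEntry] = []
    # disease-free follow-up by strategy
    recurring += _surveillance_recurring(a, "IS", "DF")
    recurring.append(RecurringEntry("PBM", "DF", AgeBand(0, None), 2 * consult))
    recurring += _surveillance_recurring(a, "PBSO", "DF")
    recurring.append(RecurringEntry("PBSO", "DF", AgeBand(0, 50), a["hrt_annual"]))
    recurring.append(RecurringEntry("PBM_PBSO", "DF", AgeBand(0, None), consult))
    recurring.append(RecurringEntry("PBM_PBSO", "DF", AgeBand(0, 50), a["hrt_annual"]))
    recurring += _surveillance_recurring(a, "CP", "DF")
    # post BC/CBC follow-up by strategy
    for state in ("PostBC", "PostCBC"):
        recurring.append(RecurringEntry("PBM", state, AgeBand(0, None), 2 * consult))
        recurring.append(RecurringEntry("PBM_PBSO", state, AgeBand(0, None), consult))
        for strat in ("IS", "PBSO", "CP"):
            recurring += _surveillance_recurring(a, strat, state)
    # post OC follow-up by strategy, plus a yearly vaginal ultrasound for all
    for strat in ("PBM", "PBM_PBSO"):
        recurring.append(RecurringEntry(strat, "PostOC", AgeBand(0, None),
                                        consult + a["vaginal_ultrasound"]))
    for strat in ("IS", "PBSO", "CP"):
        recurring += _surveillance_recurring(a, strat, "PostOC")
        recurring.append(RecurringEntry(strat, "PostOC", AgeBand(0, None), a["vaginal_ultrasound"]))

    return CostSchedule(
        currency="EUR",
        synthetic=True,
        one_off=one_off,
        state_year=state_year,
        mbc_annual=mbc_annual,
        recurring=tuple(recurring),
        drug_annual={"CP": a["tamoxifen_annual"] + a["vaginal_ultrasound"]},
        implant_replacement=a["implant_replacement"],
        palliative=a["palliative"],
        components={"bc_reconstruction": recon},
    )


def write_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the life-table CSV and both mutation cost schedules to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    lt_path = out_dir / "life_table_synthetic.csv"
    write_life_table(make_life_table(), lt_path)
    written["life_table"] = lt_path
    mixes = {
        "BRCA1": SubtypeMix("BRCA1", 0.20, 0.70, 0.10),
        "BRCA2": SubtypeMix("BRCA2", 0.80, 0.10, 0.10),
    }
    for mutation, mix in mixes.items():
        path = out_dir / f"synthetic_costs_{mutation.lower()}.txt"
        write_cost_schedule(make_cost_schedule(mix, CostFixtureSpec(seed=seed)), path)
        written[mutation] = path
    return written
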