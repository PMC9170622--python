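"""Shared fixtures: packaged inputs, base-case outcomes, and small synthetic
model builders used by the property tests."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from brcacua.costs import CostSchedule, RecurringEntry
from brcacua.params import (
    AgeBand,
    CohortConfig,
    LifeTable,
    ModelInputs,
    RateEntry,
    RateTable,
    SubtypeMix,
    UtilityEntry,
    UtilityTable,
    load_inputs,
)
from brcacua.engine import run_all_strategies
from brcacua.strategies import STRATEGY_ORDER


@pytest.fixture(scope="session")
def inputs_brca1() -> ModelInputs:
    return load_inputs("BRCA1")


@pytest.fixture(scope="session")
def inputs_brca2() -> ModelInputs:
    return load_inputs("BRCA2")


@pytest.fixture(scope="session")
def base_cfg() -> CohortConfig:
    return CohortConfig(mutation="BRCA1")


@pytest.fixture(scope="session")
def base_outcomes(inputs_brca1, inputs_brca2):
    """Base-case outcomes for all strategies and both mutations."""
    return {
        "BRCA1": run_all_strategies(inputs_brca1, CohortConfig(mutation="BRCA1")),
        "BRCA2": run_all_strategies(inputs_brca2, CohortConfig(mutation="BRCA2")),
    }


# ---------------------------------------------------------------------------
# synthetic model builders
# ---------------------------------------------------------------------------

def flat_rate_table(transition: str, rate: float, mutation: str = "BRCA1") -> RateTable:
    return RateTable(transition, mutation, (RateEntry(AgeBand(0, None), rate),))


def minimal_cost_schedule(
    amount: float = 0.0,
    one_off: float = 0.0,
    palliative: float = 0.0,
    annuity: float = 0.0,
) -> CostSchedule:
    """A schedule with bindings for every strategy/state at one flat amount."""
    recurring = tuple(
        RecurringEntry(strat, state, AgeBand(0, None), amount)
        for strat in STRATEGY_ORDER
        for state in ("DF", "PostBC", "PostCBC", "PostOC")
    )
    state_year = {(s, y): amount for s in ("BC", "OC") for y in range(1, 11)}
    return CostSchedule(
        currency="EUR",
        one_off={"pbm_surgery": one_off, "pbso_surgery": one_off},
        state_year=state_year,
        mbc_annual=amount,
        recurring=recurring,
        drug_annual={"CP": amount},
        implant_replacement=annuity,
        palliative=palliative,
        components={"bc_reconstruction": 0.0},
    )


def make_synthetic_inputs(
    rates: dict[str, float] | None = None,
    qx: float = 0.01,
    mutation: str = "BRCA1",
    cost_amount: float = 0.0,
    utilities: UtilityTable | None = None,
) -> ModelInputs:
    """A fully synthetic input bundle with flat single-band rate tables."""
    from brcacua.params import TRANSITIONS, load_hazard_ratios

    rates = rates or {}
    tables = {t: flat_rate_table(t, rates.get(t, 0.0), mutation) for t in TRANSITIONS}
    if utilities is None:
        utilities = UtilityTable(
            df_by_age=(UtilityEntry(AgeBand(0, None), 1.0),),
            state_multipliers={"BC": 1.0, "CBC": 1.0, "MBC": 1.0, "OC": 1.0},
            strategy_utilities={s: 1.0 for s in STRATEGY_ORDER},
        )
    return ModelInputs(
        mutation=mutation,
        rates=tables,
        hazard_ratios=load_hazard_ratios(),
        utilities=utilities,
        life_table=LifeTable(tuple([qx] * 111)),
        subtype_mix=SubtypeMix(mutation, 0.2, 0.7, 0.1),
        cost_schedule=minimal_cost_schedule(cost_amount),
        assumptions={"implant_fraction": 0.95, "implant_replacement_interval": 10,
                     "implant_replacement_stop_age": 70},
    )


def zero_disease_inputs(inputs: ModelInputs) -> ModelInputs:
    """Packaged inputs with every disease rate set to zero (DF/Dead only)."""
    tables = {}
    for trans, table in inputs.rates.items():
        entries = tuple(replace(e, rate=0.0) for e in table.entries)
        tables[trans] = replace(table, entries=entries)
    return replace(inputs, rates=tables)
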