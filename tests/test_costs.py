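"""Cost schedules: format round-trip, currency, linearity, closed forms."""

import numpy as np
import pytest

from brcacua import statespace as ss
from brcacua.costs import (
    convert_currency,
    cost_increments,
    cycle_cost,
    load_cost_schedule,
    write_cost_schedule,
)
from brcacua.engine import run_cohort, run_strategy
from brcacua.params import CohortConfig, ConfigurationError
from brcacua.strategies import get_strategy
from conftest import minimal_cost_schedule, zero_disease_inputs
from dataclasses import replace


@pytest.mark.parametrize(
    "amount, src, dst, expected",
    [(110, "CHF", "EUR", 100), (0, "CHF", "EUR", 0), (100, "EUR", "CHF", 110),
     (100_000, "CHF", "EUR", 90_909.0909), (42, "EUR", "EUR", 42)],
)
def test_convert_currency(amount, src, dst, expected):
    assert convert_currency(amount, src, dst) == pytest.approx(expected, abs=1e-4)


def test_convert_currency_rejects_unknown_pair():
    with pytest.raises(ConfigurationError):
        convert_currency(1.0, "EUR", "USD")


def test_schedule_round_trip(tmp_path, inputs_brca1):
    sched = inputs_brca1.cost_schedule
    path = tmp_path / "costs.txt"
    write_cost_schedule(sched, path)
    again = load_cost_schedule(path)
    assert again.one_off == pytest.approx(sched.one_off)
    assert again.state_year == pytest.approx(sched.state_year)
    assert again.mbc_annual == pytest.approx(sched.mbc_annual)
    assert again.palliative == pytest.approx(sched.palliative)
    assert len(again.recurring) == len(sched.recurring)
    assert again.synthetic == sched.synthetic


def test_parse_error_reports_line_number(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("currency EUR\n[one_off]\npbm_surgery not-a-number\n")
    with pytest.raises(Exception, match=r"bad\.txt:3"):
        load_cost_schedule(path)


def test_cbc_schedule_equals_bc(inputs_brca1):
    sched = inputs_brca1.cost_schedule
    for year in range(1, 11):
        assert sched.state_year_cost("CBC", year) == sched.state_year_cost("BC", year)


def test_all_zero_schedule_costs_nothing(inputs_brca1, base_cfg):
    inputs = replace(inputs_brca1, cost_schedule=minimal_cost_schedule(0.0))
    out = run_strategy("PBM_PBSO", inputs, base_cfg)
    assert out.total_cost == 0.0


def test_missing_state_year_binding_names_state_and_year(inputs_brca1, base_cfg):
    sched = inputs_brca1.cost_schedule
    sy = {k: v for k, v in sched.state_year.items() if k != ("OC", 3)}
    broken = replace(sched, state_year=sy)
    inputs = replace(inputs_brca1, cost_schedule=broken)
    with pytest.raises(ConfigurationError, match="OC year 3"):
        run_strategy("IS", inputs, base_cfg)


def test_cost_is_linear_in_each_schedule_amount(inputs_brca1, base_cfg):
    """Doubling the palliative lump exactly doubles its contribution."""
    base = run_strategy("IS", inputs_brca1, base_cfg).total_cost
    sched = inputs_brca1.cost_schedule
    doubled = replace(inputs_brca1, cost_schedule=replace(sched, palliative=2 * sched.palliative))
    zeroed = replace(inputs_brca1, cost_schedule=replace(sched, palliative=0.0))
    c2 = run_strategy("IS", doubled, base_cfg).total_cost
    c0 = run_strategy("IS", zeroed, base_cfg).total_cost
    assert c2 - base == pytest.approx(base - c0, rel=1e-9)


def test_surveillance_annuity_closed_form(inputs_brca1):
    """No cancer, no mortality: lifetime cost is the discounted sum of the
    age-dependent surveillance amounts."""
    inputs = zero_disease_inputs(inputs_brca1)
    inputs = replace(inputs, life_table=replace(inputs.life_table, qx=tuple([0.0] * 101)))
    cfg = CohortConfig()
    out = run_strategy("IS", inputs, cfg)
    sched = inputs.cost_schedule
    expected = sum(
        sched.recurring_cost("IS", "DF", 40 + t) * 1.03**-t for t in range(60)
    )
    assert out.total_cost == pytest.approx(expected, abs=1e-6)


def test_palliative_lump_charged_to_cancer_deaths(inputs_brca1, base_cfg):
    trace = run_cohort("IS", base_cfg, inputs_brca1)
    sched = minimal_cost_schedule(0.0, palliative=25_000.0)
    inc = cost_increments(trace, get_strategy("IS"), base_cfg, sched, inputs_brca1.assumptions)
    assert np.allclose(inc, 25_000.0 * trace.palliative_deaths)
    assert cycle_cost(trace, 10, get_strategy("IS"), base_cfg, sched,
                      inputs_brca1.assumptions) == pytest.approx(inc[10])


def test_one_off_surgery_charged_at_cycle_zero(inputs_brca1, base_cfg):
    trace = run_cohort("PBM_PBSO", base_cfg, inputs_brca1)
    sched = minimal_cost_schedule(0.0, one_off=10_000.0)
    inc = cost_increments(trace, get_strategy("PBM_PBSO"), base_cfg, sched,
                          inputs_brca1.assumptions)
    assert inc[0] == pytest.approx(20_000.0)  # both surgeries
    assert np.all(inc[1:] == 0.0)


def test_implant_replacement_lump_cycles(inputs_brca1, base_cfg):
    """With combined surgery the implant annuity falls at cycles 10, 20, 30
    (ages 50/60/70) and stops past age 70."""
    trace = run_cohort("PBM_PBSO", base_cfg, zero_disease_inputs(inputs_brca1))
    sched = minimal_cost_schedule(0.0, annuity=8_000.0)
    inc = cost_increments(trace, get_strategy("PBM_PBSO"), base_cfg, sched,
                          inputs_brca1.assumptions)
    hits = set(np.nonzero(inc)[0])
    assert hits == {10, 20, 30}
    alive10 = trace.occupancy[10, list(ss.ALIVE)].sum()
    assert inc[10] == pytest.approx(8_000.0 * 0.95 * alive10)


def test_reconstruction_timing_toggle_shifts_year(inputs_brca1, base_cfg):
    later_cfg = replace(base_cfg, reconstruction_timing="later")
    base = run_strategy("IS", inputs_brca1, base_cfg).total_cost
    later = run_strategy("IS", inputs_brca1, later_cfg).total_cost
    # later reconstruction defers ~17k EUR by one year per incident BC: small
    assert later < base
    assert (base - later) / base < 0.02
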