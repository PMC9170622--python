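"""Cohort engine: state space, matrix structure, conservation, limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brcacua import statespace as ss
from brcacua.engine import (
    EngineError,
    build_state_space,
    build_transition_matrices,
    competing_transitions,
    run_cohort,
    run_strategy,
)
from brcacua.params import CohortConfig
from brcacua.strategies import StrategySpec, get_strategy
from conftest import make_synthetic_inputs


# -- state space -------------------------------------------------------------

def test_state_space_has_36_states_with_tunnels():
    space = build_state_space()
    assert len(space) == 36
    assert space.aggregate("BC_y7") == "BC"
    assert space.tunnel_year("CBC_y10") == 10
    assert space.no_event_successor("OC_y10") == "PostOC"
    assert space.no_event_successor("BC_y3") == "BC_y4"
    assert space.no_event_successor("PostBC") == "PostBC"
    assert ss.STATE_NAMES[ss.DEAD] == "Dead"


# -- competing risks ---------------------------------------------------------

def test_competing_transitions_examples():
    probs, stay = competing_transitions({}, 1.0)
    assert stay == 1.0 and probs == {}
    probs, stay = competing_transitions({"a": 0.03}, 1.0)
    assert probs["a"] == pytest.approx(0.029554, abs=5e-7)
    assert stay == pytest.approx(0.970446, abs=5e-7)
    probs, stay = competing_transitions({"a": 0.02, "b": 0.02}, 1.0)
    assert probs["a"] == probs["b"] == pytest.approx(0.019605, abs=5e-7)
    assert stay == pytest.approx(0.960789, abs=5e-7)


@given(rates=st.dictionaries(st.sampled_from("abcd"), st.floats(0, 10), max_size=4))
@settings(max_examples=100, deadline=None)
def test_competing_transitions_sum_to_one(rates):
    probs, stay = competing_transitions(rates)
    assert abs(sum(probs.values()) + stay - 1.0) < 1e-12
    assert all(0 <= p <= 1 for p in probs.values())


# -- matrix structure --------------------------------------------------------

FORBIDDEN = [
    ("DF", "MBC"), ("DF", "CBC_y1"), ("DF", "PostBC"),
    ("OC_y3", "CBC_y1"), ("OC_y3", "BC_y1"), ("MBC", "BC_y1"),
    ("MBC", "OC_y1"), ("PostOC", "OC_y1"), ("Dead", "DF"),
    ("CBC_y2", "CBC_y1"), ("PostCBC", "CBC_y1"),
]


@pytest.mark.parametrize("strategy", ["IS", "PBM_PBSO", "CP"])
def test_matrix_rows_sum_to_one_and_forbid_transitions(inputs_brca1, base_cfg, strategy):
    P = build_transition_matrices(strategy, base_cfg, inputs_brca1)
    assert P.shape == (60, 36, 36)
    assert np.abs(P.sum(axis=2) - 1.0).max() < 1e-12
    assert P.min() >= 0 and P.max() <= 1
    for src, dst in FORBIDDEN:
        assert np.all(P[:, ss.IDX[src], ss.IDX[dst]] == 0.0), (src, dst)
    # death is absorbing
    assert np.all(P[:, ss.DEAD, ss.DEAD] == 1.0)


def test_df_row_composes_strategy_hazard_ratios(inputs_brca1, base_cfg):
    """At age 41 under combined surgery the DF exits use the published
    incidence rates scaled by the PBM and PBSO hazard ratios."""
    P = build_transition_matrices("PBM_PBSO", base_cfg, inputs_brca1)
    cycle = 1  # age 41
    r_bc = 0.0309 * 0.09
    r_oc = 0.0155 * 0.28
    r_other = inputs_brca1.life_table.rate(41)
    total = r_bc + r_oc + r_other
    f = -np.expm1(-total)
    assert P[cycle, ss.DF, ss.BC_Y[0]] == pytest.approx(r_bc / total * f, rel=1e-12)
    assert P[cycle, ss.DF, ss.OC_Y[0]] == pytest.approx(r_oc / total * f, rel=1e-12)


def test_mbc_row_uses_metastatic_mortality(inputs_brca1, base_cfg):
    P = build_transition_matrices("IS", base_cfg, inputs_brca1)
    cycle = 5  # age 45
    rate = 0.2033 + inputs_brca1.life_table.rate(45)
    assert P[cycle, ss.MBC, ss.DEAD] == pytest.approx(-np.expm1(-rate), rel=1e-12)
    assert P[cycle, ss.MBC, ss.MBC] == pytest.approx(np.exp(-rate), rel=1e-12)


def test_pbso_prior_bc_hazard_ratio_replaces_df_ratio(inputs_brca1, base_cfg):
    """Within the BC tunnel the stronger post-PBSO effect (0.14) applies to
    ovarian-cancer incidence instead of the disease-free 0.28."""
    P = build_transition_matrices("PBSO", base_cfg, inputs_brca1)
    row = P[0, ss.BC_Y[0]]
    exits = {
        "cbc": 0.0407,  # age 40, band 31-40
        "mbc": 0.0278,
        "oc": 0.0185 * 0.14,
        "dead": 0.0209 + inputs_brca1.life_table.rate(40),
    }
    total = sum(exits.values())
    f = -np.expm1(-total)
    assert row[ss.OC_Y[0]] == pytest.approx(exits["oc"] / total * f, rel=1e-12)


# -- cohort trace ------------------------------------------------------------

def test_zero_rates_cohort_stays_disease_free():
    inputs = make_synthetic_inputs(qx=0.0)
    cfg = CohortConfig()
    out = run_strategy("IS", inputs, cfg)
    occ = out.trace.occupancy
    assert np.all(occ[:, ss.DF] == 1.0)
    assert out.total_ly == pytest.approx(sum(1.03**-t for t in range(60)), rel=1e-12)


def test_certain_death_absorbs_cohort_after_one_cycle():
    inputs = make_synthetic_inputs(qx=1.0)
    trace = run_cohort("IS", CohortConfig(), inputs)
    assert trace.occupancy[1, ss.DEAD] == pytest.approx(1.0, abs=1e-9)
    assert trace.occupancy[60, ss.DEAD] == pytest.approx(1.0, abs=1e-9)


@given(
    data=st.fixed_dictionaries({
        t: st.floats(0, 0.5)
        for t in ("df_bc", "df_oc", "bc_cbc", "bc_mbc", "bc_oc",
                  "postoc_bc", "bc_dead", "mbc_dead", "oc_dead")
    }),
    qx=st.floats(0, 0.2),
    strategy=st.sampled_from(["IS", "PBM", "PBSO", "PBM_PBSO", "CP"]),
)
@settings(max_examples=200, deadline=None)
def test_occupancy_conservation_under_random_parameterisations(data, qx, strategy):
    """Mass is conserved to 1e-10 every cycle for arbitrary valid rates."""
    inputs = make_synthetic_inputs(rates=data, qx=qx)
    trace = run_cohort(strategy, CohortConfig(), inputs)
    sums = trace.occupancy.sum(axis=1)
    assert np.abs(sums - 1.0).max() < 1e-10
    dead = trace.occupancy[:, ss.DEAD]
    assert np.all(np.diff(dead) >= -1e-15)


def test_lower_incidence_never_reduces_life_years(inputs_brca1, base_cfg):
    base = run_strategy("IS", inputs_brca1, base_cfg).total_ly
    from brcacua.sensitivity import apply_override
    # halve breast-cancer incidence in the 41-50 band, all else fixed
    mod = apply_override(inputs_brca1, ("rate", "df_bc", 2), 0.0309 / 2)
    assert run_strategy("IS", mod, base_cfg).total_ly >= base


def test_discounted_ly_matches_geometric_closed_form(inputs_brca1):
    """DF/Dead-only model with constant qx: discounted LY is a geometric sum."""
    q = 0.02
    inputs = make_synthetic_inputs(qx=q)
    cfg = CohortConfig()
    out = run_strategy("IS", inputs, cfg)
    x = (1 - q) / 1.03
    expected = (1 - x**60) / (1 - x)
    assert out.total_ly == pytest.approx(expected, abs=1e-9)


def test_identity_strategy_reproduces_reference_bit_for_bit(inputs_brca1, base_cfg):
    """A strategy with no hazard-ratio effects, reference costs and reference
    utility is the reference strategy, exactly."""
    clone = StrategySpec(name="IS", display="clone", disutility_mode="surveillance")
    ref = run_strategy(get_strategy("IS"), inputs_brca1, base_cfg)
    alt = run_strategy(clone, inputs_brca1, base_cfg)
    assert alt.total_cost == ref.total_cost
    assert alt.total_qaly == ref.total_qaly
    assert alt.total_ly == ref.total_ly
    assert np.array_equal(alt.trace.occupancy, ref.trace.occupancy)


def test_half_cycle_correction_averages_membership():
    q = 0.1
    inputs = make_synthetic_inputs(qx=q)
    cfg = CohortConfig(half_cycle_correction=True, discount_rate_outcomes=0.0,
                       discount_rate_costs=0.0)
    out = run_strategy("IS", inputs, cfg)
    surv = (1 - q) ** np.arange(61)
    assert out.total_ly == pytest.approx(float(0.5 * (surv[:60] + surv[1:]).sum()), rel=1e-12)


def test_trace_export_has_cycle_rows(inputs_brca1, base_cfg):
    out = run_strategy("PBM", inputs_brca1, base_cfg)
    df = out.to_frame(base_cfg)
    assert len(df) == 60
    assert {"cycle", "age", "DF", "Dead", "qaly_disc", "cost_disc"} <= set(df.columns)
    assert df["age"].iloc[0] == 40


def test_row_sum_violation_reports_state_and_cycle(inputs_brca1, base_cfg, monkeypatch):
    import brcacua.engine as eng

    monkeypatch.setattr(eng, "ROW_SUM_TOL", -1.0)  # force every row to fail
    with pytest.raises(EngineError, match="cycle 0"):
        build_transition_matrices("IS", base_cfg, inputs_brca1)
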