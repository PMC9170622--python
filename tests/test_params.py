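"""Parameter tables: transcription fidelity, lookups, and rate arithmetic."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from brcacua.params import (
    AgeBand,
    ConfigurationError,
    CohortConfig,
    ParameterError,
    apply_hazard_ratio,
    cp_effective_bc_rate,
    load_rate_tables,
    load_utilities,
    load_hazard_ratios,
    rate_to_probability,
    SubtypeMix,
)


# -- transcription fidelity --------------------------------------------------

EXPECTED_DF_BC = {
    "BRCA1": {"21-30": 0.0059, "31-40": 0.0248, "41-50": 0.0309, "51-60": 0.0269, "61+": 0.0167},
    "BRCA2": {"21-30": 0.0048, "31-40": 0.0109, "41-50": 0.0330, "51-60": 0.0448, "61+": 0.0247},
}
EXPECTED_DF_OC = {
    "BRCA1": {"30-39": 0.0016, "40-49": 0.0155, "50-59": 0.0220, "60-69": 0.0165, "70+": 0.0079},
    "BRCA2": {"30-39": 0.0000, "40-49": 0.0012, "50-59": 0.0050, "60-69": 0.0135, "70+": 0.0037},
}


@pytest.mark.parametrize("mutation", ["BRCA1", "BRCA2"])
def test_incidence_tables_match_published_values(mutation):
    tables = load_rate_tables(mutation)
    got_bc = {str(e.band): e.rate for e in tables["df_bc"].entries}
    got_oc = {str(e.band): e.rate for e in tables["df_oc"].entries}
    assert got_bc == EXPECTED_DF_BC[mutation]
    assert got_oc == EXPECTED_DF_OC[mutation]


@pytest.mark.parametrize(
    "transition, mutation, age, expected",
    [
        ("df_bc", "BRCA1", 45, 0.0309),
        ("df_oc", "BRCA2", 35, 0.0000),
        ("mbc_dead", "BRCA1", 75, 0.2608),
        ("bc_dead", "BRCA2", 55, 0.0318),   # shared with BRCA1 per table footnote
        ("oc_dead", "BRCA1", 70, 0.1983),
        ("bc_oc", "BRCA1", 80, 0.0185),
        ("postoc_bc", "BRCA2", 50, 0.0095),
    ],
)
def test_rate_lookup(transition, mutation, age, expected):
    assert load_rate_tables(mutation)[transition].lookup(age) == expected


def test_mortality_tables_shared_between_mutations():
    t1, t2 = load_rate_tables("BRCA1"), load_rate_tables("BRCA2")
    for trans in ("bc_dead", "mbc_dead", "oc_dead", "bc_mbc"):
        assert t1[trans].entries == tuple(
            type(e)(e.band, e.rate, e.se, e.range) for e in t2[trans].entries
        )


def test_band_boundary_membership():
    """An age on a printed boundary belongs to the band it closes: the start
    age 40 uses the 31-40 breast-cancer incidence band."""
    table = load_rate_tables("BRCA1")["df_bc"]
    assert table.lookup(40) == 0.0248
    assert table.lookup(41) == 0.0309
    assert table.lookup(60) == 0.0269
    assert table.lookup(61) == 0.0167


def test_uncovered_age_names_table_and_age():
    table = load_rate_tables("BRCA1")["df_oc"]
    with pytest.raises(ConfigurationError, match="age 20.*df_oc|df_oc.*age 20"):
        table.lookup(20)


# -- rate arithmetic ---------------------------------------------------------

@pytest.mark.parametrize(
    "rate, dt, expected",
    [(0.0, 1.0, 0.0), (0.0209, 1.0, 0.020683), (10.0, 1.0, 0.9999546)],
)
def test_rate_to_probability_examples(rate, dt, expected):
    assert rate_to_probability(rate, dt) == pytest.approx(expected, abs=5e-7)


def test_rate_to_probability_rejects_negative_rate():
    with pytest.raises(ParameterError):
        rate_to_probability(-0.1)


@given(r1=st.floats(0, 5), r2=st.floats(0, 5))
@settings(max_examples=100, deadline=None)
def test_rate_to_probability_monotone_and_bounded(r1, r2):
    p1, p2 = rate_to_probability(r1), rate_to_probability(r2)
    assert 0 <= p1 < 1
    if r1 < r2:
        assert p1 <= p2


@pytest.mark.parametrize(
    "rate, hr, expected",
    [(0.0155, 1.0, 0.0155), (0.0155, 0.28, 0.00434), (0.0309, 0.09, 0.002781)],
)
def test_apply_hazard_ratio(rate, hr, expected):
    assert apply_hazard_ratio(rate, hr) == pytest.approx(expected, rel=1e-9)


def test_cp_effective_bc_rate_dilutes_over_subtype_mix():
    """Tamoxifen only acts on the hormone-receptor-positive fraction."""
    brca2 = SubtypeMix("BRCA2", 0.80, 0.10, 0.10)
    brca1 = SubtypeMix("BRCA1", 0.20, 0.70, 0.10)
    assert cp_effective_bc_rate(0.0330, brca2, 0.31) == pytest.approx(0.014784, rel=1e-9)
    assert cp_effective_bc_rate(0.0309, brca1, 0.31) == pytest.approx(0.026636, abs=5e-7)
    assert cp_effective_bc_rate(0.5, brca1, 1.0) == 0.5


@given(rate=st.floats(0, 1), f=st.floats(0, 1), hr=st.floats(0, 1))
@settings(max_examples=100, deadline=None)
def test_cp_effective_rate_never_exceeds_base(rate, f, hr):
    mix = SubtypeMix("BRCA1", f, (1 - f) * 0.7, (1 - f) * 0.3)
    eff = cp_effective_bc_rate(rate, mix, hr)
    assert eff <= rate + 1e-12
    if hr == 1.0 or f == 0.0:
        assert eff == pytest.approx(rate, abs=1e-12)


# -- other input objects -----------------------------------------------------

def test_hazard_ratios_cp_cbc_mutation_specific():
    hrs = load_hazard_ratios()
    assert hrs["CP_CBC_BRCA1"].value == 0.44
    assert hrs["CP_CBC_BRCA2"].value == 0.33
    assert all(0 < hr.value <= 1 for hr in hrs.values())


def test_utility_table_values_and_cbc_tie():
    ut = load_utilities()
    assert ut.df_utility(50) == 0.842
    assert ut.df_utility(85) == 0.736
    assert ut.multiplier("CBC") == ut.multiplier("BC") == 0.637
    assert ut.strategy_utilities["PBM_PBSO"] == 0.790


def test_cohort_config_validation():
    with pytest.raises(ParameterError, match="lifelong"):
        CohortConfig(start_age=50, n_cycles=40)
    with pytest.raises(ParameterError, match="discount"):
        CohortConfig(discount_rate_costs=-0.01)
    assert CohortConfig().wtp == pytest.approx(100_000 / 1.10)
    assert CohortConfig(currency="CHF").wtp == 100_000


def test_age_band_parsing_and_validation():
    assert AgeBand.parse("41-50") == AgeBand(41, 50)
    assert AgeBand.parse("70+") == AgeBand(70, None)
    assert AgeBand(70, None).contains(120)
    with pytest.raises(ParameterError):
        AgeBand(50, 40)


def test_life_table_monotone_and_valid(inputs_brca1):
    lt = inputs_brca1.life_table
    assert lt.max_age == 100
    qx40on = [lt.qx[a] for a in range(40, 101)]
    assert all(b >= a for a, b in zip(qx40on, qx40on[1:]))
    assert 0.0003 <= lt.qx[40] <= 0.002
    assert 0.02 <= lt.qx[80] <= 0.08
    # rate->probability round trip is exact for a single competing risk
    assert 1 - math.exp(-lt.rate(60)) == pytest.approx(lt.qx[60], rel=1e-12)
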