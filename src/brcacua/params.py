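"""Model input parameters: event-rate tables, hazard ratios, utilities, life table.

All printed inputs live in packaged YAML files under ``brcacua/data/params``;
this module loads and validates them and provides the small pieces of rate
arithmetic (rate->probability conversion, hazard-ratio application) used by
the cohort engine.  Rates are annual event rates per person-year; they are
converted to one-cycle probabilities exactly once, inside the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

MUTATIONS = ("BRCA1", "BRCA2")

#: transition keys of the rate tables (aggregate-state semantics)
TRANSITIONS = (
    "df_bc",      # disease-free -> breast cancer incidence
    "df_oc",      # disease-free -> ovarian cancer incidence
    "bc_cbc",     # breast cancer -> contralateral breast cancer
    "bc_mbc",     # BC/CBC -> metastatic breast cancer
    "bc_oc",      # BC/CBC -> ovarian cancer
    "postoc_bc",  # post-OC -> metachronous breast cancer
    "bc_dead",    # BC/CBC cancer-specific mortality
    "mbc_dead",   # MBC cancer-specific mortality
    "oc_dead",    # OC cancer-specific mortality
)

EUR_PER_CHF = 1.0 / 1.10  # exchange rate 1 EUR = 1.10 CHF


class ParameterError(ValueError):
    """Raised when a parameter file or value fails validation."""


class ConfigurationError(ValueError):
    """Raised when a lookup cannot be satisfied by the configured inputs."""


# ---------------------------------------------------------------------------
# age bands and rate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeBand:
    """Inclusive age interval; ``upper is None`` means unbounded above."""

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.upper is not None and self.lower > self.upper:
            raise ParameterError(f"age band lower {self.lower} > upper {self.upper}")

    def contains(self, age: float) -> bool:
        if age < self.lower:
            return False
        return self.upper is None or age <= self.upper

    @classmethod
    def parse(cls, text: str) -> "AgeBand":
        text = str(text).strip()
        if text.endswith("+"):
            return cls(int(text[:-1]), None)
        lo, _, hi = text.partition("-")
        if not hi:
            raise ParameterError(f"cannot parse age band {text!r}")
        return cls(int(lo), int(hi))

    def __str__(self) -> str:
        return f"{self.lower}+" if self.upper is None else f"{self.lower}-{self.upper}"


@dataclass(frozen=True)
class RateEntry:
    band: AgeBand
    rate: float
    se: float | None = None
    range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError(f"negative rate {self.rate} in band {self.band}")
        if self.se is not None and self.se < 0:
            raise ParameterError(f"negative SE {self.se} in band {self.band}")


@dataclass(frozen=True)
class RateTable:
    """Age-banded annual event rates for one transition and mutation."""

    transition: str
    mutation: str
    entries: tuple[RateEntry, ...]

    def __post_init__(self) -> None:
        if self.transition not in TRANSITIONS:
            raise ParameterError(f"unknown transition {self.transition!r}")
        if self.mutation not in MUTATIONS:
            raise ParameterError(f"unknown mutation {self.mutation!r}")
        bands = [e.band for e in self.entries]
        for a, b in zip(bands, bands[1:]):
            if a.upper is None or b.lower <= a.upper:
                raise ParameterError(
                    f"{self.transition}/{self.mutation}: bands {a} and {b} "
                    "overlap or are out of order"
                )

    def lookup(self, age: float) -> float:
        """Rate of the unique band containing ``age`` (inclusive bounds)."""
        for e in self.entries:
            if e.band.contains(age):
                return e.rate
        raise ConfigurationError(
            f"age {age} not covered by rate table {self.transition}/{self.mutation}"
        )

    def entry_at(self, age: float) -> RateEntry:
        for e in self.entries:
            if e.band.contains(age):
                return e
        raise ConfigurationError(
            f"age {age} not covered by rate table {self.transition}/{self.mutation}"
        )

    def with_rate(self, index: int, rate: float) -> "RateTable":
        entries = list(self.entries)
        entries[index] = replace(entries[index], rate=rate)
        return replace(self, entries=tuple(entries))


# ---------------------------------------------------------------------------
# hazard ratios, utilities, life table, cohort configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HazardRatio:
    """Multiplicative effect of a risk-reducing intervention on an event rate."""

    key: str
    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.value <= 1:
            raise ParameterError(f"hazard ratio {self.key}={self.value} outside (0, 1]")
        if self.se < 0:
            raise ParameterError(f"negative SE for hazard ratio {self.key}")


@dataclass(frozen=True)
class UtilityEntry:
    band: AgeBand
    value: float

    def __post_init__(self) -> None:
        if not 0 <= self.value <= 1:
            raise ParameterError(f"utility {self.value} outside [0, 1]")


@dataclass(frozen=True)
class UtilityTable:
    """Age-specific baseline utilities plus disease and strategy multipliers.

    ``state_multipliers`` and ``strategy_utilities`` carry a percentage
    variation used by the sensitivity module (half-range of a 95% interval by
    default).  The CBC multiplier always equals the BC multiplier.
    """

    df_by_age: tuple[UtilityEntry, ...]
    state_multipliers: Mapping[str, float]
    strategy_utilities: Mapping[str, float]
    state_variation_pct: Mapping[str, float] = field(default_factory=dict)
    strategy_variation_pct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in {**self.state_multipliers, **self.strategy_utilities}.items():
            if not 0 <= v <= 1:
                raise ParameterError(f"utility {name}={v} outside [0, 1]")
        if "CBC" in self.state_multipliers and not math.isclose(
            self.state_multipliers["CBC"], self.state_multipliers["BC"]
        ):
            raise ParameterError("CBC utility multiplier must equal BC multiplier")

    def df_utility(self, age: float) -> float:
        for e in self.df_by_age:
            if e.band.contains(age):
                return e.value
        raise ConfigurationError(f"age {age} not covered by DF utility table")

    def multiplier(self, state: str) -> float:
        if state == "CBC":
            state = "BC"
        try:
            return self.state_multipliers[state]
        except KeyError as exc:
            raise ConfigurationError(f"no utility multiplier for state {state}") from exc

    def with_state_multiplier(self, state: str, value: float) -> "UtilityTable":
        mult = dict(self.state_multipliers)
        mult[state] = value
        if state == "BC" and "CBC" in mult:
            mult["CBC"] = value
        return replace(self, state_multipliers=mult)

    def with_strategy_utility(self, strategy: str, value: float) -> "UtilityTable":
        su = dict(self.strategy_utilities)
        su[strategy] = value
        return replace(self, strategy_utilities=su)


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause probability of death qx for females, ages 0..max."""

    qx: tuple[float, ...]  # index = integer age

    def __post_init__(self) -> None:
        for age, q in enumerate(self.qx):
            if not 0 <= q <= 1:
                raise ParameterError(f"life table qx({age})={q} outside [0, 1]")

    @property
    def max_age(self) -> int:
        return len(self.qx) - 1

    def prob(self, age: float) -> float:
        a = min(int(age), self.max_age)
        return self.qx[a]

    def rate(self, age: float) -> float:
        """Continuous-time mortality rate equivalent to qx at ``age``.

        qx = 1 is clipped just below 1 so the competing-risk split stays
        finite; the resulting one-cycle death probability is 1 - 1e-12.
        """
        q = min(self.prob(age), 1.0 - 1e-12)
        return -math.log1p(-q)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        rows: dict[int, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = [p.strip() for p in line.split(",")]
                if parts[0].lower() == "age":
                    continue
                try:
                    rows[int(parts[0])] = float(parts[1])
                except (ValueError, IndexError) as exc:
                    raise ParameterError(f"{path}:{lineno}: cannot parse {line!r}") from exc
        if not rows:
            raise ParameterError(f"{path}: empty life table")
        ages = sorted(rows)
        if ages != list(range(ages[0], ages[-1] + 1)) or ages[0] != 0:
            raise ParameterError(f"{path}: life table ages must run 0..max without gaps")
        return cls(tuple(rows[a] for a in ages))


@dataclass(frozen=True)
class SubtypeMix:
    """Molecular breast-cancer subtype fractions for one mutation."""

    mutation: str
    hr_pos: float
    tnbc: float
    her2: float

    def __post_init__(self) -> None:
        total = self.hr_pos + self.tnbc + self.her2
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ParameterError(f"subtype fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class CohortConfig:
    """Run configuration: cohort, horizon, discounting, and model toggles."""

    mutation: str = "BRCA1"
    start_age: int = 40
    n_cycles: int = 60
    cycle_length: float = 1.0
    discount_rate_costs: float = 0.03
    discount_rate_outcomes: float = 0.03
    wtp_chf: float = 100_000.0
    currency: str = "EUR"
    half_cycle_correction: bool = False
    # strategy-utility handling
    is_disutility_every_year: bool = True     # IS decrement in every imaging year
    surgical_disutility_years: int = 1
    surgical_disutility_constant: bool = False  # scenario: hold multiplier flat
    cp_disutility_years: int = 5
    # intervention-effect handling
    cp_effect_years: int | None = None        # None = lifelong
    cp_value_is_rrr: bool = False             # interpret 0.31 as 1-RRR instead of HR
    # scenario toggles
    oc_mortality_multiplier: float = 1.0
    reconstruction_timing: str = "immediate"  # or "later"
    implant_mode: str = "lump"                # or "amortized"
    background_mortality_in_cancer_states: bool = True
    utility_variation_mode: str = "halfrange"  # "+-X%" => SE = X%*central/1.96

    def __post_init__(self) -> None:
        if self.mutation not in MUTATIONS:
            raise ParameterError(f"unknown mutation {self.mutation!r}")
        if self.start_age + self.n_cycles < 100:
            raise ParameterError("horizon must be lifelong: start_age + n_cycles >= 100")
        if self.discount_rate_costs < 0 or self.discount_rate_outcomes < 0:
            raise ParameterError("discount rates must be >= 0")
        if self.cycle_length != 1.0:
            raise ParameterError("cycle length is fixed at one year")
        if self.currency not in ("EUR", "CHF"):
            raise ParameterError(f"unsupported currency {self.currency!r}")

    @property
    def wtp(self) -> float:
        """Willingness-to-pay per QALY in the configured currency."""
        return self.wtp_chf if self.currency == "CHF" else self.wtp_chf * EUR_PER_CHF


# ---------------------------------------------------------------------------
# rate arithmetic
# ---------------------------------------------------------------------------

def rate_to_probability(rate: float, dt: float = 1.0) -> float:
    """Convert an event rate (events/person-year) to a probability over ``dt``.

    Uses the exponential relation p = 1 - exp(-rate * dt).
    """
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    return -math.expm1(-rate * dt)


def apply_hazard_ratio(rate: float, hr: float) -> float:
    """Scale an event rate by a hazard ratio."""
    if rate < 0:
        raise ParameterError(f"rate must be >= 0, got {rate}")
    if hr < 0:
        raise ParameterError(f"hazard ratio must be >= 0, got {hr}")
    return rate * hr


def cp_effective_bc_rate(rate: float, mix: SubtypeMix, hr_erpos: float) -> float:
    """Breast-cancer incidence under chemoprevention.

    Tamoxifen only reduces hormone-receptor-positive disease, so the hazard
    ratio applies to the HR+ fraction of the subtype mix and the remaining
    fraction is untouched:  rate * (f_HR+ * hr + (1 - f_HR+)).
    """
    factor = mix.hr_pos * hr_erpos + (1.0 - mix.hr_pos)
    return apply_hazard_ratio(rate, factor)


# ---------------------------------------------------------------------------
# packaged parameter files
# ---------------------------------------------------------------------------

def _data_path(*parts: str) -> Path:
    return Path(resources.files("brcacua").joinpath("data", *parts))  # type: ignore[arg-type]


def _load_yaml(path: Path) -> dict:
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ParameterError(f"parameter file not found: {path}") from None
    if not isinstance(doc, dict):
        raise ParameterError(f"{path}: expected a mapping at top level")
    return doc


def _rate_entry(raw: dict, where: str) -> RateEntry:
    try:
        band = AgeBand.parse(raw["ages"])
        rate = float(raw["rate"])
    except (KeyError, ValueError) as exc:
        raise ParameterError(f"{where}: bad rate entry {raw!r}") from exc
    se = float(raw["se"]) if "se" in raw and raw["se"] is not None else None
    rng = None
    if "range" in raw and raw["range"] is not None:
        lo, hi = raw["range"]
        rng = (float(lo), float(hi))
    return RateEntry(band=band, rate=rate, se=se, range=rng)


def load_rate_tables(mutation: str, path: str | Path | None = None) -> dict[str, RateTable]:
    """Load all transition rate tables for one mutation."""
    if mutation not in MUTATIONS:
        raise ParameterError(f"unknown mutation {mutation!r}")
    path = Path(path) if path else _data_path("params", f"rates_{mutation.lower()}.yaml")
    doc = _load_yaml(path)
    if doc.get("mutation") != mutation:
        raise ParameterError(f"{path}: mutation field {doc.get('mutation')!r} != {mutation}")
    tables: dict[str, RateTable] = {}
    raw_tables = doc.get("tables", {})
    for transition in TRANSITIONS:
        if transition not in raw_tables:
            raise ParameterError(f"{path}: missing table {transition!r}")
        entries = tuple(
            _rate_entry(e, f"{path}:{transition}") for e in raw_tables[transition]
        )
        tables[transition] = RateTable(transition=transition, mutation=mutation, entries=entries)
    return tables


def load_hazard_ratios(path: str | Path | None = None) -> dict[str, HazardRatio]:
    path = Path(path) if path else _data_path("params", "hazard_ratios.yaml")
    doc = _load_yaml(path)
    out = {}
    for key, raw in doc.items():
        try:
            out[key] = HazardRatio(key=key, value=float(raw["value"]), se=float(raw.get("se", 0.0)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParameterError(f"{path}: bad hazard ratio entry {key!r}") from exc
    return out


def load_utilities(path: str | Path | None = None) -> UtilityTable:
    path = Path(path) if path else _data_path("params", "utilities.yaml")
    doc = _load_yaml(path)
    try:
        df = tuple(
            UtilityEntry(AgeBand.parse(e["ages"]), float(e["value"]))
            for e in doc["df_by_age"]
        )
        states = {k: float(v["value"]) for k, v in doc["state_multipliers"].items()}
        state_var = {k: float(v.get("variation_pct", 0.0)) for k, v in doc["state_multipliers"].items()}
        strat = {k: float(v["value"]) for k, v in doc["strategy_utilities"].items()}
        strat_var = {k: float(v.get("variation_pct", 0.0)) for k, v in doc["strategy_utilities"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"{path}: malformed utility table") from exc
    states.setdefault("CBC", states["BC"])
    return UtilityTable(
        df_by_age=df,
        state_multipliers=states,
        strategy_utilities=strat,
        state_variation_pct=state_var,
        strategy_variation_pct=strat_var,
    )


def load_subtype_mix(mutation: str, path: str | Path | None = None) -> SubtypeMix:
    path = Path(path) if path else _data_path("params", "cohort.yaml")
    doc = _load_yaml(path)
    try:
        raw = doc["subtype_mix"][mutation]
        return SubtypeMix(mutation=mutation, hr_pos=float(raw["hr_pos"]),
                          tnbc=float(raw["tnbc"]), her2=float(raw["her2"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParameterError(f"{path}: missing subtype mix for {mutation}") from exc


def load_cohort_assumptions(path: str | Path | None = None) -> dict:
    """Cohort assumptions used by the cost model and fixture generator."""
    path = Path(path) if path else _data_path("params", "cohort.yaml")
    return _load_yaml(path)


def load_life_table(path: str | Path | None = None) -> LifeTable:
    path = Path(path) if path else _data_path("life_table_synthetic.csv")
    return LifeTable.from_csv(path)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelInputs:
    """Everything the engine needs for one mutation, bundled."""

    mutation: str
    rates: Mapping[str, RateTable]
    hazard_ratios: Mapping[str, HazardRatio]
    utilities: UtilityTable
    life_table: LifeTable
    subtype_mix: SubtypeMix
    cost_schedule: "object" = None  # CostSchedule; typed loosely to avoid cycle
    assumptions: Mapping[str, float] = field(default_factory=dict)

    def rate(self, transition: str, age: float) -> float:
        return self.rates[transition].lookup(age)

    def hr(self, key: str) -> float:
        return self.hazard_ratios[key].value


def load_inputs(
    mutation: str,
    params_dir: str | Path | None = None,
    life_table: str | Path | None = None,
    costs: str | Path | None = None,
) -> ModelInputs:
    """Load the full packaged input set for one mutation.

    ``params_dir``, ``life_table`` and ``costs`` override the packaged
    defaults (the synthetic life-table and cost fixtures) with user files.
    """
    from .costs import load_cost_schedule  # local import to avoid cycle

    pdir = Path(params_dir) if params_dir else None
    rates = load_rate_tables(mutation, pdir / f"rates_{mutation.lower()}.yaml" if pdir else None)
    hrs = load_hazard_ratios(pdir / "hazard_ratios.yaml" if pdir else None)
    utilities = load_utilities(pdir / "utilities.yaml" if pdir else None)
    mix = load_subtype_mix(mutation, pdir / "cohort.yaml" if pdir else None)
    lt = load_life_table(life_table)
    if costs is None:
        costs = _data_path("costs", f"synthetic_costs_{mutation.lower()}.txt")
    schedule = load_cost_schedule(costs)
    assumptions = load_cohort_assumptions(pdir / "cohort.yaml" if pdir else None).get(
        "assumptions", {}
    )
    return ModelInputs(
        mutation=mutation,
        rates=rates,
        hazard_ratios=hrs,
        utilities=utilities,
        life_table=lt,
        subtype_mix=mix,
        cost_schedule=schedule,
        assumptions=assumptions,
    )
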