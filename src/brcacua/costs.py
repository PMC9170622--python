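"""Strategy- and state-dependent cost schedules and per-cycle cost increments.

A :class:`CostSchedule` is a pure data artifact read from a sectioned text
file: one-off surgery costs, per-year-since-diagnosis treatment costs for
BC/CBC and OC, an annual metastatic treatment cost, recurring
surveillance/follow-up costs by strategy, state and age band, an
implant-replacement annuity, drug costs while on chemoprevention, and a
palliative lump sum charged to mass dying out of a cancer state.

The packaged schedules are synthetic fixtures with plausible Swiss
magnitudes (the real tariff schedules are not public data); every schedule
carries a ``synthetic`` flag that downstream reports surface as a watermark.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .params import CohortConfig, ConfigurationError, ParameterError, AgeBand
from . import statespace as ss

if TYPE_CHECKING:  # pragma: no cover
    from .engine import CohortTrace
    from .strategies import StrategySpec

CHF_PER_EUR = 1.10


def convert_currency(amount: float, source: str, target: str) -> float:
    """Convert between EUR and CHF at the fixed study exchange rate."""
    pairs = {("EUR", "EUR"): 1.0, ("CHF", "CHF"): 1.0,
             ("EUR", "CHF"): CHF_PER_EUR, ("CHF", "EUR"): 1.0 / CHF_PER_EUR}
    try:
        return amount * pairs[(source, target)]
    except KeyError as exc:
        raise ConfigurationError(f"unsupported currency pair {source}->{target}") from exc


@dataclass(frozen=True)
class RecurringEntry:
    strategy: str
    state: str
    band: AgeBand
    amount: float


@dataclass(frozen=True)
class CostSchedule:
    currency: str = "EUR"
    synthetic: bool = False
    one_off: Mapping[str, float] = field(default_factory=dict)
    state_year: Mapping[tuple[str, int], float] = field(default_factory=dict)
    mbc_annual: float = 0.0
    recurring: tuple[RecurringEntry, ...] = ()
    drug_annual: Mapping[str, float] = field(default_factory=dict)
    implant_replacement: float = 0.0
    palliative: float = 0.0
    components: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        amounts = [*self.one_off.values(), *self.state_year.values(), self.mbc_annual,
                   *(e.amount for e in self.recurring), *self.drug_annual.values(),
                   self.implant_replacement, self.palliative]
        for a in amounts:
            if a < 0:
                raise ParameterError(f"negative cost amount {a}")

    # -- lookups ----------------------------------------------------------
    def state_year_cost(self, state: str, year: int) -> float:
        if state == "CBC":  # same costs as primary BC
            state = "BC"
        try:
            return self.state_year[(state, year)]
        except KeyError as exc:
            raise ConfigurationError(
                f"cost schedule has no state-year amount for {state} year {year}"
            ) from exc

    def recurring_cost(self, strategy: str, state: str, age: float) -> float:
        entries = [e for e in self.recurring if e.strategy == strategy and e.state == state]
        if not entries:
            raise ConfigurationError(
                f"cost schedule has no recurring binding for strategy {strategy}, state {state}"
            )
        matches = [e.amount for e in entries if e.band.contains(age)]
        if not matches:
            raise ConfigurationError(
                f"age {age} uncovered by recurring bindings for {strategy}/{state}"
            )
        return float(sum(matches))

    # -- derived schedules -------------------------------------------------
    def with_reconstruction_timing(self, timing: str) -> "CostSchedule":
        """Move the breast-reconstruction amount between year 1 and year 2 of
        the BC schedule (immediate vs later reconstruction scenario)."""
        if timing == "immediate":
            return self
        if timing != "later":
            raise ConfigurationError(f"unknown reconstruction timing {timing!r}")
        amount = self.components.get("bc_reconstruction", 0.0)
        sy = dict(self.state_year)
        if amount > sy.get(("BC", 1), 0.0):
            raise ConfigurationError("reconstruction component exceeds BC year-1 cost")
        sy[("BC", 1)] = sy[("BC", 1)] - amount
        sy[("BC", 2)] = sy.get(("BC", 2), 0.0) + amount
        return replace(self, state_year=sy)

    def scaled_group(self, group: str, factor: float) -> "CostSchedule":
        """Multiply a coherent group of amounts by ``factor`` (for sensitivity)."""
        if factor < 0:
            raise ParameterError("scale factor must be >= 0")
        if group == "bc_treatment":
            sy = {k: (v * factor if k[0] == "BC" else v) for k, v in self.state_year.items()}
            comp = {k: (v * factor if k == "bc_reconstruction" else v)
                    for k, v in self.components.items()}
            return replace(self, state_year=sy, components=comp)
        if group == "oc_treatment":
            sy = {k: (v * factor if k[0] == "OC" else v) for k, v in self.state_year.items()}
            return replace(self, state_year=sy)
        if group == "mbc_treatment":
            return replace(self, mbc_annual=self.mbc_annual * factor)
        if group == "surveillance":
            rec = tuple(replace(e, amount=e.amount * factor) for e in self.recurring)
            return replace(self, recurring=rec)
        raise ConfigurationError(f"unknown cost group {group!r}")

    def with_one_off(self, key: str, amount: float) -> "CostSchedule":
        if key not in self.one_off:
            raise ConfigurationError(f"unknown one-off cost key {key!r}")
        return replace(self, one_off={**self.one_off, key: amount})

    def in_currency(self, target: str) -> float:
        return convert_currency(1.0, self.currency, target)


# ---------------------------------------------------------------------------
# sectioned text format
# ---------------------------------------------------------------------------

_SECTIONS = ("one_off", "state_year", "recurring", "drug", "annuity", "palliative", "components")


def load_cost_schedule(path: str | Path) -> CostSchedule:
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"cost schedule file not found: {path}")
    currency = "EUR"
    synthetic = False
    one_off: dict[str, float] = {}
    state_year: dict[tuple[str, int], float] = {}
    mbc_annual = 0.0
    recurring: list[RecurringEntry] = []
    drug: dict[str, float] = {}
    annuity = 0.0
    palliative = 0.0
    components: dict[str, float] = {}
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            where = f"{path}:{lineno}"
            if line.startswith("[") and line.endswith("]"):
                section = line[1:-1]
                if section not in _SECTIONS:
                    raise ParameterError(f"{where}: unknown section [{section}]")
                continue
            parts = line.split()
            try:
                if section is None:
                    key, value = parts
                    if key == "currency":
                        if value not in ("EUR", "CHF"):
                            raise ValueError(value)
                        currency = value
                    elif key == "synthetic":
                        synthetic = value.lower() in ("true", "yes", "1")
                    else:
                        raise ValueError(key)
                elif section in ("one_off", "components"):
                    key, amount = parts
                    (one_off if section == "one_off" else components)[key] = float(amount)
                elif section == "state_year":
                    state, year, amount = parts
                    if state == "MBC":
                        mbc_annual = float(amount)
                    else:
                        state_year[(state, int(year))] = float(amount)
                elif section == "recurring":
                    strat, state, band, amount = parts
                    recurring.append(RecurringEntry(strat, state, AgeBand.parse(band), float(amount)))
                elif section == "drug":
                    strat, amount = parts
                    drug[strat] = float(amount)
                elif section == "annuity":
                    key, amount = parts
                    if key != "implant_replacement":
                        raise ValueError(key)
                    annuity = float(amount)
                elif section == "palliative":
                    key, amount = parts
                    palliative = float(amount)
            except (ValueError, KeyError) as exc:
                raise ParameterError(f"{where}: cannot parse {line!r}") from exc
    return CostSchedule(
        currency=currency, synthetic=synthetic, one_off=one_off, state_year=state_year,
        mbc_annual=mbc_annual, recurring=tuple(recurring), drug_annual=drug,
        implant_replacement=annuity, palliative=palliative, components=components,
    )


def write_cost_schedule(schedule: CostSchedule, path: str | Path) -> None:
    lines = [f"currency {schedule.currency}", f"synthetic {str(schedule.synthetic).lower()}"]
    lines.append("[one_off]")
    lines += [f"{k} {v:.6f}" for k, v in schedule.one_off.items()]
    lines.append("[state_year]")
    for (state, year), v in sorted(schedule.state_year.items()):
        lines.append(f"{state} {year} {v:.6f}")
    if schedule.mbc_annual:
        lines.append(f"MBC 0 {schedule.mbc_annual:.6f}")
    lines.append("[recurring]")
    for e in schedule.recurring:
        lines.append(f"{e.strategy} {e.state} {e.band} {e.amount:.6f}")
    lines.append("[drug]")
    lines += [f"{k} {v:.6f}" for k, v in schedule.drug_annual.items()]
    lines.append("[annuity]")
    lines.append(f"implant_replacement {schedule.implant_replacement:.6f}")
    lines.append("[palliative]")
    lines.append(f"all {schedule.palliative:.6f}")
    lines.append("[components]")
    lines += [f"{k} {v:.6f}" for k, v in schedule.components.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-cycle cost increments
# ---------------------------------------------------------------------------

def cost_increments(
    trace: "CohortTrace",
    strategy: "StrategySpec",
    cfg: CohortConfig,
    schedule: CostSchedule,
    assumptions: Mapping[str, float],
) -> np.ndarray:
    """Undiscounted cost per cycle attributable to the cohort, model currency.

    Sums occupancy-weighted state-year and recurring amounts, cycle-0 one-off
    interventions, implant-replacement annuities, chemoprevention drug costs,
    and palliative lump sums on cancer-state deaths.
    """
    n = cfg.n_cycles
    occ = trace.occupancy
    ages = cfg.start_age + np.arange(n)
    implant_frac = float(assumptions.get("implant_fraction", 0.95))
    interval = int(assumptions.get("implant_replacement_interval", 10))
    stop_age = float(assumptions.get("implant_replacement_stop_age", 70))

    sched = schedule.with_reconstruction_timing(cfg.reconstruction_timing)

    # per-state, per-cycle cost matrix
    C = np.zeros((n, ss.N_STATES))
    for k in range(1, ss.TUNNEL_LENGTH + 1):
        C[:, ss.BC_Y[k - 1]] = sched.state_year_cost("BC", k)
        C[:, ss.CBC_Y[k - 1]] = sched.state_year_cost("CBC", k)
        C[:, ss.OC_Y[k - 1]] = sched.state_year_cost("OC", k)
    C[:, ss.MBC] = sched.mbc_annual
    for t in range(n):
        age = ages[t]
        C[t, ss.DF] = sched.recurring_cost(strategy.name, "DF", age)
        C[t, ss.POST_BC] = sched.recurring_cost(strategy.name, "PostBC", age)
        C[t, ss.POST_CBC] = sched.recurring_cost(strategy.name, "PostCBC", age)
        C[t, ss.POST_OC] = sched.recurring_cost(strategy.name, "PostOC", age)
    if strategy.drug_years:
        drug = sched.drug_annual.get(strategy.name, 0.0)
        C[: strategy.drug_years, ss.DF] += drug

    inc = np.einsum("ts,ts->t", occ[:n], C)

    # one-off prophylactic interventions at the start of cycle 0
    for key in strategy.one_off:
        try:
            inc[0] += sched.one_off[key]
        except KeyError as exc:
            raise ConfigurationError(f"cost schedule has no one-off amount {key!r}") from exc

    # implant-replacement annuity
    amount = sched.implant_replacement
    if amount > 0:
        post_entry_states = {"BC": ss.POST_BC, "CBC": ss.POST_CBC}
        if cfg.implant_mode == "lump":
            if strategy.implant_replacement:
                for c in range(interval, n, interval):
                    if ages[c] <= stop_age:
                        alive = occ[c, list(ss.ALIVE)].sum()
                        inc[c] += amount * implant_frac * alive
            # breast reconstructions after cancer: replacement due when the
            # ten-year tunnel completes (entry into a post state)
            for t in range(1, n):
                if ages[t] <= stop_age:
                    entry = trace.entry_flows[t, ss.POST_BC] + trace.entry_flows[t, ss.POST_CBC]
                    inc[t] += amount * implant_frac * entry
        elif cfg.implant_mode == "amortized":
            annual = amount / interval
            mask = ages <= stop_age
            if strategy.implant_replacement:
                alive = occ[:n, list(ss.ALIVE)].sum(axis=1)
                inc[mask] += annual * implant_frac * alive[mask]
            cancer_cols = list(ss.BC_Y + ss.CBC_Y + (ss.POST_BC, ss.POST_CBC))
            recon_mass = occ[:n, cancer_cols].sum(axis=1)
            inc[mask] += annual * implant_frac * recon_mass[mask]
        else:
            raise ConfigurationError(f"unknown implant mode {cfg.implant_mode!r}")

    # palliative lump sums on deaths out of cancer states
    inc += sched.palliative * trace.palliative_deaths[:n]

    # express in the configured currency
    return inc * convert_currency(1.0, sched.currency, cfg.currency)


def cycle_cost(
    trace: "CohortTrace",
    cycle: int,
    strategy: "StrategySpec",
    cfg: CohortConfig,
    schedule: CostSchedule,
    assumptions: Mapping[str, float],
) -> float:
    """Undiscounted cost attributable to one cycle (see :func:`cost_increments`)."""
    return float(cost_increments(trace, strategy, cfg, schedule, assumptions)[cycle])
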