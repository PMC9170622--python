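"""Markov cohort engine: cycle-indexed transition matrices, cohort trace,
and discounted life-year / QALY / cost accumulation.

The cohort starts fully disease-free at the configured start age and is
propagated through 60 annual cycles (extended automatically for earlier
start ages) over the 36-state expanded tunnel space.  Within a cycle,
competing events are resolved with the proportional exponential split

    p_event = (rate_event / R) * (1 - exp(-R)),   p_stay = exp(-R),

with R the sum of all exit rates, which normalises every row exactly.
Cancer-specific mortality acts during the ten tunnel years after diagnosis;
all-cause (life-table) mortality acts everywhere, also inside cancer states
unless switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import statespace as ss
from .costs import cost_increments
from .params import CohortConfig, ModelInputs, rate_to_probability
from .qol import utility_matrix
from .statespace import build_state_space  # re-exported
from .strategies import StrategySpec, effective_rates, get_strategy

__all__ = [
    "CohortTrace", "StrategyOutcome", "build_state_space", "competing_transitions",
    "build_transition_matrices", "build_transition_matrix", "run_cohort",
    "accumulate_outcomes", "run_strategy", "run_all_strategies",
]

ROW_SUM_TOL = 1e-12
OCCUPANCY_TOL = 1e-10


class EngineError(RuntimeError):
    """A transition matrix or trace violated a structural invariant."""


def competing_transitions(rates: dict[str, float], dt: float = 1.0) -> tuple[dict[str, float], float]:
    """Resolve competing exit rates into one-cycle probabilities.

    Returns ``(probabilities per event, stay probability)``; the proportional
    exponential split guarantees they sum to one exactly.
    """
    for k, r in rates.items():
        if r < 0:
            raise ValueError(f"negative rate for event {k!r}")
    total = sum(rates.values())
    if total == 0:
        return ({k: 0.0 for k in rates}, 1.0)
    f = rate_to_probability(total, dt)
    return ({k: (r / total) * f for k, r in rates.items()}, 1.0 - f)


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------

def _strategy_rate_arrays(
    strategy: StrategySpec, cfg: CohortConfig, inputs: ModelInputs
) -> dict[str, np.ndarray]:
    """Per-cycle effective rate arrays after strategy and scenario adjustment."""
    n = cfg.n_cycles
    ages = cfg.start_age + np.arange(n)
    base = {t: np.array([inputs.rate(t, a) for a in ages], dtype=float)
            for t in ("df_bc", "df_oc", "bc_cbc", "bc_mbc", "bc_oc", "postoc_bc",
                      "bc_dead", "mbc_dead", "oc_dead")}
    base["oc_dead"] = base["oc_dead"] * cfg.oc_mortality_multiplier
    out = {k: v.copy() for k, v in base.items()}
    for c in range(n):
        eff = effective_rates(
            {k: base[k][c] for k in ("df_bc", "df_oc", "bc_cbc", "postoc_bc")},
            strategy, inputs, cfg, cycle=c,
        )
        for k, v in eff.items():
            out[k][c] = v
        out.setdefault("bc_oc_prior", np.empty(n))
        out["bc_oc_prior"][c] = effective_rates(
            {"bc_oc": base["bc_oc"][c]}, strategy, inputs, cfg, cycle=c, prior_bc=True
        )["bc_oc"]
    out["other"] = np.array([inputs.life_table.rate(a) for a in ages])
    return out


def build_transition_matrices(
    strategy: StrategySpec | str, cfg: CohortConfig, inputs: ModelInputs
) -> np.ndarray:
    """All cycle-indexed one-cycle transition matrices, shape (n, 36, 36)."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    n = cfg.n_cycles
    r = _strategy_rate_arrays(strategy, cfg, inputs)
    bg = r["other"] if cfg.background_mortality_in_cancer_states else np.zeros(n)
    P = np.zeros((n, ss.N_STATES, ss.N_STATES))

    def set_rows(rows: list[int], exits: dict[int, np.ndarray], stay: list[int]) -> None:
        total = np.sum(list(exits.values()), axis=0)
        f = -np.expm1(-total * cfg.cycle_length)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, f / np.where(total > 0, total, 1.0), 0.0)
        stay_p = 1.0 - f
        for row, stay_col in zip(rows, stay):
            for col, rate in exits.items():
                P[:, row, col] += rate * frac
            P[:, row, stay_col] += stay_p

    # disease-free
    set_rows([ss.DF], {ss.BC_Y[0]: r["df_bc"], ss.OC_Y[0]: r["df_oc"],
                       ss.DEAD: r["other"]}, [ss.DF])
    # breast-cancer tunnel (fresh CBC tunnel on contralateral disease)
    bc_rows = list(ss.BC_Y)
    bc_stay = list(ss.BC_Y[1:]) + [ss.POST_BC]
    set_rows(bc_rows, {ss.CBC_Y[0]: r["bc_cbc"], ss.MBC: r["bc_mbc"],
                       ss.OC_Y[0]: r["bc_oc_prior"], ss.DEAD: r["bc_dead"] + bg}, bc_stay)
    # contralateral tunnel
    cbc_rows = list(ss.CBC_Y)
    cbc_stay = list(ss.CBC_Y[1:]) + [ss.POST_CBC]
    set_rows(cbc_rows, {ss.MBC: r["bc_mbc"], ss.OC_Y[0]: r["bc_oc_prior"],
                        ss.DEAD: r["bc_dead"] + bg}, cbc_stay)
    # metastatic disease: terminal
    set_rows([ss.MBC], {ss.DEAD: r["mbc_dead"] + bg}, [ss.MBC])
    # post-cancer breast states: age-adjusted mortality only
    set_rows([ss.POST_BC], {ss.CBC_Y[0]: r["bc_cbc"], ss.MBC: r["bc_mbc"],
                            ss.OC_Y[0]: r["bc_oc_prior"], ss.DEAD: r["other"]}, [ss.POST_BC])
    set_rows([ss.POST_CBC], {ss.MBC: r["bc_mbc"], ss.OC_Y[0]: r["bc_oc_prior"],
                             ss.DEAD: r["other"]}, [ss.POST_CBC])
    # ovarian-cancer tunnel
    oc_rows = list(ss.OC_Y)
    oc_stay = list(ss.OC_Y[1:]) + [ss.POST_OC]
    set_rows(oc_rows, {ss.DEAD: r["oc_dead"] + bg}, oc_stay)
    # post-OC: metachronous breast cancer possible
    set_rows([ss.POST_OC], {ss.BC_Y[0]: r["postoc_bc"], ss.DEAD: r["other"]}, [ss.POST_OC])
    # absorbing death
    P[:, ss.DEAD, ss.DEAD] = 1.0

    sums = P.sum(axis=2)
    bad = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_TOL)
    if bad.size:
        c, i = bad[0]
        raise EngineError(
            f"transition row {ss.STATE_NAMES[i]} at cycle {c} sums to {sums[c, i]!r}"
        )
    return P


def build_transition_matrix(
    cycle: int, strategy: StrategySpec | str, cfg: CohortConfig, inputs: ModelInputs
) -> np.ndarray:
    """One cycle's 36x36 transition matrix."""
    return build_transition_matrices(strategy, cfg, inputs)[cycle]


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Per-cycle occupancy over the expanded states plus flow bookkeeping."""

    occupancy: np.ndarray          # (n_cycles+1, 36)
    matrices: np.ndarray           # (n_cycles, 36, 36)
    entry_flows: np.ndarray        # (n_cycles+1, 36): mass entering from other states
    palliative_deaths: np.ndarray  # (n_cycles,): cancer-state mass dying this cycle

    @property
    def n_cycles(self) -> int:
        return self.matrices.shape[0]


def run_cohort(
    strategy: StrategySpec | str, cfg: CohortConfig, inputs: ModelInputs
) -> CohortTrace:
    """Propagate the cohort (100% disease-free at start) through all cycles."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    P = build_transition_matrices(strategy, cfg, inputs)
    n = cfg.n_cycles
    occ = np.zeros((n + 1, ss.N_STATES))
    occ[0, ss.DF] = 1.0
    entry = np.zeros((n + 1, ss.N_STATES))
    pall = np.zeros(n)
    pall_rows = list(ss.PALLIATIVE_STATES)
    for t in range(n):
        nxt = occ[t] @ P[t]
        entry[t + 1] = nxt - occ[t] * np.diag(P[t])
        pall[t] = occ[t, pall_rows] @ P[t, pall_rows, ss.DEAD]
        occ[t + 1] = nxt
        total = occ[t + 1].sum()
        if abs(total - 1.0) > OCCUPANCY_TOL:
            raise EngineError(f"occupancy sums to {total!r} after cycle {t}")
    return CohortTrace(occupancy=occ, matrices=P, entry_flows=entry, palliative_deaths=pall)


# ---------------------------------------------------------------------------
# outcome accumulation
# ---------------------------------------------------------------------------

@dataclass
class StrategyOutcome:
    """Discounted lifetime totals and per-cycle increments for one strategy."""

    strategy: str
    mutation: str
    total_cost: float
    total_qaly: float
    total_ly: float
    ly: np.ndarray            # undiscounted per-cycle life years
    qaly: np.ndarray
    cost: np.ndarray
    ly_disc: np.ndarray
    qaly_disc: np.ndarray
    cost_disc: np.ndarray
    currency: str = "EUR"
    synthetic_costs: bool = False
    trace: CohortTrace | None = field(default=None, repr=False)

    def to_frame(self, cfg: CohortConfig) -> pd.DataFrame:
        """Per-cycle trace export: occupancy columns plus discounted increments."""
        n = len(self.ly)
        df = pd.DataFrame(self.trace.occupancy[:n], columns=list(ss.STATE_NAMES))
        df.insert(0, "age", cfg.start_age + np.arange(n))
        df.insert(0, "cycle", np.arange(n))
        df["ly_disc"] = self.ly_disc
        df["qaly_disc"] = self.qaly_disc
        df["cost_disc"] = self.cost_disc
        return df


def accumulate_outcomes(
    trace: CohortTrace,
    strategy: StrategySpec | str,
    cfg: CohortConfig,
    inputs: ModelInputs,
) -> StrategyOutcome:
    """Discounted LY/QALY/cost totals from a completed cohort trace.

    Cycle 0 is undiscounted; cycle t is discounted by (1+d)^-t.  With the
    half-cycle correction enabled, state membership is averaged between the
    beginning and end of each cycle for the LY and QALY rewards.
    """
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    n = trace.n_cycles
    occ = trace.occupancy
    occw = 0.5 * (occ[:n] + occ[1:]) if cfg.half_cycle_correction else occ[:n]

    alive_cols = list(ss.ALIVE)
    ly = occw[:, alive_cols].sum(axis=1) * cfg.cycle_length
    U = utility_matrix(strategy, inputs, cfg, ss.STATE_NAMES, ss.AGGREGATE_OF, ss.TUNNEL_YEAR_OF)
    qaly = np.einsum("ts,ts->t", occw, U) * cfg.cycle_length
    cost = cost_increments(trace, strategy, cfg, inputs.cost_schedule, inputs.assumptions)

    t = np.arange(n)
    vo = (1.0 + cfg.discount_rate_outcomes) ** -t
    vc = (1.0 + cfg.discount_rate_costs) ** -t
    out = StrategyOutcome(
        strategy=strategy.name,
        mutation=cfg.mutation,
        total_cost=float(cost @ vc),
        total_qaly=float(qaly @ vo),
        total_ly=float(ly @ vo),
        ly=ly, qaly=qaly, cost=cost,
        ly_disc=ly * vo, qaly_disc=qaly * vo, cost_disc=cost * vc,
        currency=cfg.currency,
        synthetic_costs=bool(getattr(inputs.cost_schedule, "synthetic", False)),
        trace=trace,
    )
    return out


def run_strategy(
    strategy: StrategySpec | str, inputs: ModelInputs, cfg: CohortConfig
) -> StrategyOutcome:
    """Run one strategy end to end: trace plus discounted totals."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    trace = run_cohort(strategy, cfg, inputs)
    return accumulate_outcomes(trace, strategy, cfg, inputs)


def run_all_strategies(
    inputs: ModelInputs, cfg: CohortConfig, names: tuple[str, ...] | None = None
) -> dict[str, StrategyOutcome]:
    from .strategies import STRATEGY_ORDER

    return {name: run_strategy(name, inputs, cfg) for name in (names or STRATEGY_ORDER)}
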