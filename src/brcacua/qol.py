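"""Age-adjusted, time-since-diagnosis-dependent utilities.

Utilities follow the multiplicative age-adjustment: the age-specific
disease-free utility is multiplied by a disease-state or intervention
factor.  Cancer states carry their decrement for the first five years after
diagnosis with a linear recovery back to the age-adjusted baseline from
year six on; metastatic disease keeps its constant multiplier until death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CohortConfig, ConfigurationError, ModelInputs, ParameterError
from .strategies import StrategySpec, strategy_utility_multiplier

RECOVERY_YEARS = 5  # years over which disease utility recovers linearly


@dataclass(frozen=True)
class UtilityContext:
    """Everything needed to assign a utility to one expanded state-cycle."""

    age: float
    state: str                    # aggregate state name
    tunnel_year: int | None = None  # 1-10 for BC/CBC/OC, else None
    strategy: StrategySpec | None = None
    cycle: int = 0

    def __post_init__(self) -> None:
        in_tunnel = self.state in ("BC", "CBC", "OC")
        if in_tunnel != (self.tunnel_year is not None):
            raise ParameterError("tunnel_year must be given iff state is BC/CBC/OC")


def recovery_multiplier(base: float, tunnel_year: int) -> float:
    """Disease multiplier in ``tunnel_year`` (1-based) with linear recovery.

    m(1) = base, rising linearly to 1 at year 6: m(t) = base + (1-base)(t-1)/5.
    """
    if tunnel_year < 1:
        raise ParameterError(f"tunnel year must be >= 1, got {tunnel_year}")
    if tunnel_year > RECOVERY_YEARS:
        return 1.0
    return base + (1.0 - base) * (tunnel_year - 1) / RECOVERY_YEARS


def oc_utility_constant(components: list[float]) -> float:
    """Average of the five yearly ovarian-cancer utility components."""
    if len(components) != RECOVERY_YEARS:
        raise ParameterError(f"expected {RECOVERY_YEARS} components, got {len(components)}")
    return float(np.mean(components))


def age_adjusted_utility(ctx: UtilityContext, inputs: ModelInputs, cfg: CohortConfig) -> float:
    """Utility for one expanded state at one age under one strategy."""
    if ctx.state == "Dead":
        return 0.0
    u_age = inputs.utilities.df_utility(ctx.age)
    if ctx.state == "DF":
        if ctx.strategy is None:
            return u_age
        return u_age * strategy_utility_multiplier(
            ctx.strategy, cfg, ctx.cycle, inputs.utilities
        )
    if ctx.state == "MBC":
        return u_age * inputs.utilities.multiplier("MBC")
    if ctx.state in ("PostBC", "PostCBC", "PostOC"):
        return u_age
    if ctx.state in ("BC", "CBC", "OC"):
        base = inputs.utilities.multiplier(ctx.state)
        return u_age * recovery_multiplier(base, ctx.tunnel_year)
    raise ConfigurationError(f"no utility defined for state {ctx.state!r}")


def utility_matrix(
    strategy: StrategySpec, inputs: ModelInputs, cfg: CohortConfig, state_names: tuple[str, ...],
    aggregate_of: dict[str, str], tunnel_year_of: dict[str, int | None],
) -> np.ndarray:
    """Vectorised utilities, shape (n_cycles, n_states).

    Single source of truth is :func:`age_adjusted_utility`; this builds the
    same values cycle-by-cycle using precomputed age and multiplier vectors
    (the scalar function is cross-checked against it in the test suite).
    """
    n = cfg.n_cycles
    ages = cfg.start_age + np.arange(n)
    u_age = np.array([inputs.utilities.df_utility(a) for a in ages])
    strat_mult = np.array([
        strategy_utility_multiplier(strategy, cfg, c, inputs.utilities) for c in range(n)
    ])
    U = np.zeros((n, len(state_names)))
    for j, name in enumerate(state_names):
        agg = aggregate_of[name]
        if agg == "Dead":
            continue
        if agg == "DF":
            U[:, j] = u_age * strat_mult
        elif agg == "MBC":
            U[:, j] = u_age * inputs.utilities.multiplier("MBC")
        elif agg in ("PostBC", "PostCBC", "PostOC"):
            U[:, j] = u_age
        else:  # BC/CBC/OC tunnel year
            base = inputs.utilities.multiplier(agg)
            U[:, j] = u_age * recovery_multiplier(base, tunnel_year_of[name])
    return U
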