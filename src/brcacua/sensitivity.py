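"""One-way (tornado) and probabilistic sensitivity analysis.

Every uncertain input is registered with its central value and spread as
printed (SE, 95% CI converted to SE via width/4, range, or +-% variation)
and a distribution family by parameter class: gamma for rates and costs,
lognormal for hazard ratios, beta for utilities; range-only spreads sample
uniformly.  Samplers are moment-matched (mean = central, sd = SE) on the
natural scale.  Draws are applied to the model truncated to the admissible
support (rates and costs >= 0, hazard ratios and utilities in (0, 1]); the
samplers themselves are left untruncated so their moments stay exact.

In the probabilistic analysis all parameters are drawn jointly and
independently, and the same draw is applied to every strategy within an
iteration (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .economics import net_monetary_benefit, incremental
from .engine import run_strategy
from .params import (
    CohortConfig,
    ConfigurationError,
    HazardRatio,
    ModelInputs,
    ParameterError,
)
from .strategies import STRATEGY_ORDER

# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sampler:
    """Moment-matched sampler for one uncertain parameter."""

    family: str  # gamma | lognormal | beta | uniform | point
    mean: float
    sd: float
    frozen: object | None = None  # scipy frozen distribution, None for point

    def draw(self, rng: np.random.Generator, size: int | None = None):
        if self.frozen is None:
            return np.full(size, self.mean) if size is not None else self.mean
        return self.frozen.rvs(size=size, random_state=rng)


@dataclass(frozen=True)
class UncertainParameter:
    """One uncertain input: where it lives, its central value and spread."""

    name: str
    path: tuple
    central: float
    family: str                       # gamma | lognormal | beta | uniform
    se: float = 0.0
    range: tuple[float, float] | None = None
    support: tuple[float, float] = (0.0, math.inf)

    def bounds(self) -> tuple[float, float]:
        """Low/high values for one-way analysis (central +- 1.96 SE or the
        stated range), truncated to the admissible support."""
        if self.range is not None:
            lo, hi = self.range
        else:
            lo = self.central - 1.96 * self.se
            hi = self.central + 1.96 * self.se
        lo = max(lo, self.support[0])
        hi = min(hi, self.support[1])
        return lo, hi


def fit_distribution(param: UncertainParameter) -> Sampler:
    """Method-of-moments sampler for a parameter (see module docstring)."""
    m, s = param.central, param.se
    if param.family == "uniform":
        if param.range is None:
            raise ParameterError(f"{param.name}: uniform family needs a range")
        lo, hi = param.range
        mean = 0.5 * (lo + hi)
        sd = (hi - lo) / math.sqrt(12.0)
        return Sampler("uniform", mean, sd, stats.uniform(loc=lo, scale=hi - lo))
    if s == 0:
        return Sampler("point", m, 0.0, None)
    if param.family == "gamma":
        if m <= 0:
            raise ParameterError(f"{param.name}: gamma needs a positive mean")
        shape = (m / s) ** 2
        scale = s**2 / m
        return Sampler("gamma", m, s, stats.gamma(a=shape, scale=scale))
    if param.family == "lognormal":
        if m <= 0:
            raise ParameterError(f"{param.name}: lognormal needs a positive mean")
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        return Sampler("lognormal", m, s, stats.lognorm(s=math.sqrt(sigma2), scale=math.exp(mu)))
    if param.family == "beta":
        if not 0 < m < 1:
            raise ParameterError(f"{param.name}: beta needs mean in (0, 1)")
        if s**2 >= m * (1 - m):
            raise ParameterError(f"{param.name}: SE {s} incompatible with beta support")
        nu = m * (1 - m) / s**2 - 1.0
        return Sampler("beta", m, s, stats.beta(a=m * nu, b=(1 - m) * nu))
    raise ParameterError(f"{param.name}: unknown family {param.family!r}")


# ---------------------------------------------------------------------------
# parameter registry and overrides
# ---------------------------------------------------------------------------

def _utility_se(central: float, pct: float, cfg: CohortConfig) -> float:
    if cfg.utility_variation_mode == "halfrange":  # +-X% read as a 95% half-range
        return pct / 100.0 * central / 1.96
    return pct / 100.0 * central


def uncertain_parameters(inputs: ModelInputs, cfg: CohortConfig) -> list[UncertainParameter]:
    """All uncertain inputs of one mutation's model run."""
    params: list[UncertainParameter] = []
    for trans, table in inputs.rates.items():
        for i, e in enumerate(table.entries):
            name = f"rate:{trans}:{e.band}"
            if e.range is not None:
                params.append(UncertainParameter(name, ("rate", trans, i), e.rate,
                                                 "uniform", range=e.range))
            elif e.se and e.rate > 0:
                params.append(UncertainParameter(name, ("rate", trans, i), e.rate,
                                                 "gamma", se=e.se))
    used_keys = {"PBSO_OC", "PBSO_OC_prior_BC", "PBM_BC", "CP_ERpos_BC",
                 f"CP_CBC_{inputs.mutation}"}
    for key in sorted(used_keys):
        hr = inputs.hazard_ratios[key]
        if hr.se:
            params.append(UncertainParameter(f"hr:{key}", ("hr", key), hr.value,
                                             "lognormal", se=hr.se, support=(0.0, 1.0)))
    ut = inputs.utilities
    for state in ("BC", "MBC", "OC"):
        pct = ut.state_variation_pct.get(state, 0.0)
        if pct:
            c = ut.state_multipliers[state]
            params.append(UncertainParameter(f"utility:{state}", ("util_state", state), c,
                                             "beta", se=_utility_se(c, pct, cfg),
                                             support=(0.0, 1.0)))
    for strat in STRATEGY_ORDER:
        pct = ut.strategy_variation_pct.get(strat, 0.0)
        if pct:
            c = ut.strategy_utilities[strat]
            params.append(UncertainParameter(f"utility:{strat}", ("util_strategy", strat), c,
                                             "beta", se=_utility_se(c, pct, cfg),
                                             support=(0.0, 1.0)))
    sched = inputs.cost_schedule
    pct = 20.0  # cost spread of the fixture schedule: +-20% half-range
    for key, amount in sched.one_off.items():
        if amount > 0:
            params.append(UncertainParameter(f"cost:{key}", ("cost_one_off", key), amount,
                                             "gamma", se=pct / 100 * amount / 1.96))
    if sched.implant_replacement > 0:
        a = sched.implant_replacement
        params.append(UncertainParameter("cost:implant_replacement", ("cost_annuity",), a,
                                         "gamma", se=pct / 100 * a / 1.96))
    if sched.palliative > 0:
        a = sched.palliative
        params.append(UncertainParameter("cost:palliative", ("cost_palliative",), a,
                                         "gamma", se=pct / 100 * a / 1.96))
    for strat, amount in sched.drug_annual.items():
        if amount > 0:
            params.append(UncertainParameter(f"cost:drug:{strat}", ("cost_drug", strat), amount,
                                             "gamma", se=pct / 100 * amount / 1.96))
    for group in ("bc_treatment", "oc_treatment", "mbc_treatment", "surveillance"):
        params.append(UncertainParameter(f"cost_scale:{group}", ("cost_scale", group), 1.0,
                                         "gamma", se=pct / 100 / 1.96))
    return params


def apply_override(inputs: ModelInputs, path: tuple, value: float) -> ModelInputs:
    """A copy of ``inputs`` with one parameter replaced (clipped to support)."""
    kind = path[0]
    if kind == "rate":
        _, trans, idx = path
        rates = dict(inputs.rates)
        rates[trans] = rates[trans].with_rate(idx, max(float(value), 0.0))
        return replace(inputs, rates=rates)
    if kind == "hr":
        _, key = path
        v = min(max(float(value), 1e-12), 1.0)
        hrs = dict(inputs.hazard_ratios)
        hrs[key] = HazardRatio(key=key, value=v, se=hrs[key].se)
        return replace(inputs, hazard_ratios=hrs)
    if kind == "util_state":
        v = min(max(float(value), 0.0), 1.0)
        return replace(inputs, utilities=inputs.utilities.with_state_multiplier(path[1], v))
    if kind == "util_strategy":
        v = min(max(float(value), 0.0), 1.0)
        return replace(inputs, utilities=inputs.utilities.with_strategy_utility(path[1], v))
    sched = inputs.cost_schedule
    v = max(float(value), 0.0)
    if kind == "cost_one_off":
        return replace(inputs, cost_schedule=sched.with_one_off(path[1], v))
    if kind == "cost_annuity":
        return replace(inputs, cost_schedule=replace(sched, implant_replacement=v))
    if kind == "cost_palliative":
        return replace(inputs, cost_schedule=replace(sched, palliative=v))
    if kind == "cost_drug":
        drug = {**sched.drug_annual, path[1]: v}
        return replace(inputs, cost_schedule=replace(sched, drug_annual=drug))
    if kind == "cost_scale":
        return replace(inputs, cost_schedule=sched.scaled_group(path[1], v))
    raise ConfigurationError(f"unknown override path {path!r}")


# ---------------------------------------------------------------------------
# one-way sensitivity (tornado)
# ---------------------------------------------------------------------------

def tornado(
    inputs: ModelInputs,
    cfg: CohortConfig,
    pair: tuple[str, str] = ("IS", "PBM_PBSO"),
    params: Sequence[UncertainParameter] | None = None,
) -> pd.DataFrame:
    """One-way sensitivity of the incremental comparison ``pair[1]`` vs
    ``pair[0]``: each parameter in turn is set to its low and high bound with
    all others central.  Returns one row per parameter with the incremental
    net monetary benefit at both bounds, sorted by bar width descending."""
    if params is None:
        params = uncertain_parameters(inputs, cfg)
    a_name, b_name = pair
    wtp = cfg.wtp
    rows = []
    for p in params:
        lo, hi = p.bounds()
        out = {}
        for tag, value in (("low", lo), ("high", hi)):
            if value == p.central:
                mod = inputs
            else:
                mod = apply_override(inputs, p.path, value)
            ra = run_strategy(a_name, mod, cfg)
            rb = run_strategy(b_name, mod, cfg)
            d_cost, d_qaly, _, icer = incremental(ra, rb)
            out[f"nmb_diff_{tag}"] = net_monetary_benefit(rb, wtp) - net_monetary_benefit(ra, wtp)
            out[f"icer_{tag}"] = icer if isinstance(icer, str) else float(icer)
        rows.append({
            "parameter": p.name, "low": lo, "high": hi,
            **out,
            "width": abs(out["nmb_diff_high"] - out["nmb_diff_low"]),
        })
    df = pd.DataFrame(rows).sort_values("width", ascending=False, kind="stable")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSAOutput:
    """Per-iteration cost/QALY pairs per strategy plus derived summaries."""

    strategies: tuple[str, ...]
    costs: np.ndarray   # (n_iterations, n_strategies)
    qalys: np.ndarray
    lys: np.ndarray
    seed: int
    n_iterations: int
    param_names: tuple[str, ...]
    flagged: tuple[int, ...] = ()   # iterations with non-finite model output
    wtp: float = 0.0

    def _valid(self) -> np.ndarray:
        mask = np.ones(self.n_iterations, dtype=bool)
        mask[list(self.flagged)] = False
        return mask

    def prob_optimal(self, wtp: float | None = None) -> dict[str, float]:
        """Probability each strategy maximises net monetary benefit."""
        wtp = self.wtp if wtp is None else wtp
        mask = self._valid()
        nmb = wtp * self.qalys[mask] - self.costs[mask]
        best = np.argmax(nmb, axis=1)
        return {s: float(np.mean(best == j)) for j, s in enumerate(self.strategies)}

    def ceac(self, wtp_grid: Iterable[float]) -> pd.DataFrame:
        """Cost-effectiveness acceptability curves over a willingness-to-pay grid."""
        rows = []
        for w in wtp_grid:
            probs = self.prob_optimal(w)
            rows.append({"wtp": w, **probs})
        return pd.DataFrame(rows)

    def scatter(self, reference: str = "IS") -> pd.DataFrame:
        """Incremental cost/QALY scatter of every strategy against the reference."""
        j0 = self.strategies.index(reference)
        mask = self._valid()
        frames = []
        for j, s in enumerate(self.strategies):
            if j == j0:
                continue
            frames.append(pd.DataFrame({
                "strategy": s,
                "d_qaly": self.qalys[mask, j] - self.qalys[mask, j0],
                "d_cost": self.costs[mask, j] - self.costs[mask, j0],
            }))
        return pd.concat(frames, ignore_index=True)

    def mean_outcomes(self) -> pd.DataFrame:
        mask = self._valid()
        return pd.DataFrame({
            "strategy": self.strategies,
            "mean_cost": self.costs[mask].mean(axis=0),
            "mean_qaly": self.qalys[mask].mean(axis=0),
            "mean_ly": self.lys[mask].mean(axis=0),
        })


def run_psa(
    inputs: ModelInputs,
    cfg: CohortConfig,
    seed: int,
    n: int = 10_000,
    strategies: Sequence[str] = STRATEGY_ORDER,
    params: Sequence[UncertainParameter] | None = None,
) -> PSAOutput:
    """Joint Monte-Carlo resampling of all uncertain parameters.

    Reproducible given ``seed``; each iteration applies one joint draw to
    every strategy.  Iterations producing non-finite outputs are flagged and
    excluded from the summaries but the run continues.
    """
    if n <= 0:
        raise ConfigurationError("PSA iteration count must be positive")
    if params is None:
        params = uncertain_parameters(inputs, cfg)
    rng = np.random.default_rng(seed)
    draws = np.column_stack([fit_distribution(p).draw(rng, n) for p in params])

    S = len(strategies)
    costs = np.empty((n, S))
    qalys = np.empty((n, S))
    lys = np.empty((n, S))
    flagged: list[int] = []
    for i in range(n):
        mod = inputs
        for p, v in zip(params, draws[i]):
            mod = apply_override(mod, p.path, v)
        ok = True
        for j, name in enumerate(strategies):
            r = run_strategy(name, mod, cfg)
            costs[i, j], qalys[i, j], lys[i, j] = r.total_cost, r.total_qaly, r.total_ly
            if not (math.isfinite(costs[i, j]) and math.isfinite(qalys[i, j])):
                ok = False
        if not ok:
            flagged.append(i)
    return PSAOutput(
        strategies=tuple(strategies), costs=costs, qalys=qalys, lys=lys,
        seed=seed, n_iterations=n, param_names=tuple(p.name for p in params),
        flagged=tuple(flagged), wtp=cfg.wtp,
    )
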