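"""The five risk-reducing strategies as declarative specifications.

A :class:`StrategySpec` binds hazard-ratio effects, a disease-free utility
decrement with its duration rule, one-off intervention costs, and cost
bindings (hormone replacement, implant replacement) to the cohort engine.
Definitions are shipped as a YAML data file so scenario edits need no code
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .params import (
    ConfigurationError,
    CohortConfig,
    ModelInputs,
    ParameterError,
    apply_hazard_ratio,
    cp_effective_bc_rate,
)

STRATEGY_ORDER = ("IS", "PBM", "PBSO", "PBM_PBSO", "CP")


@dataclass(frozen=True)
class StrategySpec:
    """One risk-reducing strategy, declaratively."""

    name: str
    display: str
    hr_effects: Mapping[str, str] = field(default_factory=dict)
    disutility_mode: str = "first_year"  # first_year | drug_years | surveillance
    drug_years: int = 0
    one_off: tuple[str, ...] = ()
    hrt: bool = False
    implant_replacement: bool = False

    def __post_init__(self) -> None:
        if self.disutility_mode not in ("first_year", "drug_years", "surveillance"):
            raise ParameterError(f"unknown disutility mode {self.disutility_mode!r}")
        if self.name == "IS" and (self.hr_effects or self.one_off):
            raise ParameterError("IS is the reference strategy: no effects, no surgery")

    def hr_key(self, effect: str, mutation: str) -> str | None:
        key = self.hr_effects.get(effect)
        return key.format(mutation=mutation) if key else None


def load_strategies(path: str | Path | None = None) -> dict[str, StrategySpec]:
    if path is None:
        path = Path(resources.files("brcacua").joinpath("data", "strategies.yaml"))  # type: ignore[arg-type]
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = {}
    for name, raw in doc.items():
        specs[name] = StrategySpec(
            name=name,
            display=raw.get("display", name),
            hr_effects=raw.get("hr_effects", {}) or {},
            disutility_mode=raw.get("disutility_mode", "first_year"),
            drug_years=int(raw.get("drug_years", 0)),
            one_off=tuple(raw.get("one_off", []) or []),
            hrt=bool(raw.get("hrt", False)),
            implant_replacement=bool(raw.get("implant_replacement", False)),
        )
    return specs


_STRATEGIES: dict[str, StrategySpec] | None = None


def get_strategy(name: str) -> StrategySpec:
    global _STRATEGIES
    if _STRATEGIES is None:
        _STRATEGIES = load_strategies()
    try:
        return _STRATEGIES[name]
    except KeyError as exc:
        raise ConfigurationError(f"unknown strategy {name!r}") from exc


def all_strategies() -> list[StrategySpec]:
    return [get_strategy(n) for n in STRATEGY_ORDER]


# ---------------------------------------------------------------------------
# rate adjustment
# ---------------------------------------------------------------------------

def _effect_active(strategy: StrategySpec, cfg: CohortConfig, cycle: int) -> bool:
    """Whether the strategy's hazard-ratio effects apply during ``cycle``.

    Surgical risk reduction is anatomical and lifelong.  Chemoprevention is
    lifelong in the base case; the 5-year-effect scenario truncates it after
    the drug intake window.
    """
    if strategy.name != "CP" or cfg.cp_effect_years is None:
        return True
    return cycle < cfg.cp_effect_years


def effective_rates(
    base_rates: Mapping[str, float],
    strategy: StrategySpec,
    inputs: ModelInputs,
    cfg: CohortConfig,
    cycle: int = 0,
    prior_bc: bool = False,
) -> dict[str, float]:
    """Apply a strategy's hazard-ratio effects to a dict of base rates.

    Recognised keys: ``df_bc``, ``df_oc``, ``bc_cbc``, ``postoc_bc``,
    ``bc_oc``.  ``prior_bc`` selects the stronger post-PBSO effect on ovarian
    cancer incidence for women with a breast-cancer history (it replaces, not
    multiplies, the disease-free-state hazard ratio).
    """
    out = dict(base_rates)
    if not _effect_active(strategy, cfg, cycle):
        return out
    mutation = inputs.mutation

    bc_key = strategy.hr_key("bc_incidence", mutation)
    erpos_key = strategy.hr_key("erpos_bc_incidence", mutation)
    for trans in ("df_bc", "postoc_bc"):
        if trans not in out:
            continue
        if bc_key:
            out[trans] = apply_hazard_ratio(out[trans], inputs.hr(bc_key))
        elif erpos_key:
            hr = inputs.hr(erpos_key)
            if cfg.cp_value_is_rrr:
                hr = 1.0 - hr
            out[trans] = cp_effective_bc_rate(out[trans], inputs.subtype_mix, hr)

    oc_key = strategy.hr_key("oc_incidence", mutation)
    oc_prior_key = strategy.hr_key("oc_incidence_prior_bc", mutation)
    if "df_oc" in out and oc_key:
        out["df_oc"] = apply_hazard_ratio(out["df_oc"], inputs.hr(oc_key))
    if "bc_oc" in out:
        key = oc_prior_key if prior_bc else None
        if key:
            out["bc_oc"] = apply_hazard_ratio(out["bc_oc"], inputs.hr(key))

    cbc_key = strategy.hr_key("cbc_incidence", mutation)
    if "bc_cbc" in out and cbc_key:
        out["bc_cbc"] = apply_hazard_ratio(out["bc_cbc"], inputs.hr(cbc_key))
    return out


# ---------------------------------------------------------------------------
# disease-free utility decrement
# ---------------------------------------------------------------------------

def imaging_year(age: int) -> bool:
    """Whether surveillance imaging takes place at ``age`` (NICE-164 pattern:
    annual below 70, every second year from 70 on)."""
    if age < 70:
        return True
    return (age - 70) % 2 == 0


def strategy_utility_multiplier(
    strategy: StrategySpec,
    cfg: CohortConfig,
    cycle: int,
    utilities=None,
) -> float:
    """Multiplier on the disease-free utility in ``cycle`` under ``strategy``.

    Surgical strategies carry their decrement for one year after surgery
    (``surgical_disutility_years`` in the duration scenarios), Tamoxifen for
    the 5-year intake, and intensified surveillance in every imaging year
    (switchable to first-year-only via ``cfg.is_disutility_every_year``).
    """
    if utilities is None:
        from .params import load_utilities
        utilities = load_utilities()
    value = utilities.strategy_utilities[strategy.name]
    if strategy.disutility_mode == "surveillance":
        if cfg.is_disutility_every_year:
            return value if imaging_year(cfg.start_age + cycle) else 1.0
        return value if cycle == 0 else 1.0
    if strategy.disutility_mode == "drug_years":
        return value if cycle < max(strategy.drug_years, cfg.cp_disutility_years) else 1.0
    # surgical: decrement for surgical_disutility_years starting at surgery
    dur = cfg.surgical_disutility_years
    if cycle >= dur:
        return 1.0
    if cfg.surgical_disutility_constant or dur <= 1:
        return value
    # optional linear recovery towards 1 over the scenario duration
    return value + (1.0 - value) * cycle / dur


# ---------------------------------------------------------------------------
# uptake blending
# ---------------------------------------------------------------------------

def uptake_mix(results: Mapping[str, "object"], weights: Mapping[str, float]):
    """Blend per-strategy totals by uptake fractions (weighted means).

    ``results`` maps strategy name to any object with ``total_cost``,
    ``total_qaly`` and ``total_ly`` attributes; returns a plain dict of
    blended totals.
    """
    import math

    wsum = sum(weights.values())
    if any(w < 0 for w in weights.values()) or not math.isclose(wsum, 1.0, abs_tol=1e-9):
        raise ParameterError(f"uptake weights must be >= 0 and sum to 1, got {wsum}")
    blended = {"total_cost": 0.0, "total_qaly": 0.0, "total_ly": 0.0}
    for name, w in weights.items():
        if name not in results:
            raise ConfigurationError(f"no result for strategy {name!r} in uptake mix")
        r = results[name]
        blended["total_cost"] += w * r.total_cost
        blended["total_qaly"] += w * r.total_qaly
        blended["total_ly"] += w * r.total_ly
    return blended
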