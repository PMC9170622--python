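"""Scenario analyses as declarative overrides of the base configuration.

Each scenario replaces a handful of configuration fields and leaves
everything else at the base value; an all-base scenario reproduces the base
case bit for bit.  Earlier start ages extend the cycle count so the horizon
still reaches age 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .engine import run_all_strategies
from .params import CohortConfig, ConfigurationError, ModelInputs
from .strategies import uptake_mix


@dataclass(frozen=True)
class ScenarioSpec:
    """A named bundle of configuration overrides."""

    name: str
    start_age: int | None = None
    disutility_years: int | None = None        # surgical strategies, held constant
    disutility_linear_recovery: bool = False
    tamoxifen_effect_years: int | None = None  # None keeps the lifelong base case
    oc_mortality_multiplier: float | None = None
    reconstruction_timing: str | None = None
    uptake_weights: Mapping[str, float] | None = None


SCENARIOS: dict[str, ScenarioSpec] = {
    "base": ScenarioSpec("base"),
    "start_age_30": ScenarioSpec("start_age_30", start_age=30),
    "start_age_35": ScenarioSpec("start_age_35", start_age=35),
    "disutility_5y": ScenarioSpec("disutility_5y", disutility_years=5),
    "disutility_10y": ScenarioSpec("disutility_10y", disutility_years=10),
    "tamoxifen_5y": ScenarioSpec("tamoxifen_5y", tamoxifen_effect_years=5),
    "oc_mortality_minus30": ScenarioSpec("oc_mortality_minus30", oc_mortality_multiplier=0.70),
    "reconstruction_later": ScenarioSpec("reconstruction_later", reconstruction_timing="later"),
    # uptake pattern reported for women at risk internationally:
    # surveillance only / PBSO / PBM
    "uptake_mix": ScenarioSpec("uptake_mix",
                               uptake_weights={"IS": 0.33, "PBSO": 0.49, "PBM": 0.18}),
}


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
        ) from exc


def apply_scenario(cfg: CohortConfig, spec: ScenarioSpec) -> CohortConfig:
    """Base configuration with the scenario's overrides applied."""
    changes: dict = {}
    if spec.start_age is not None:
        changes["start_age"] = spec.start_age
        # keep a lifelong horizon to age 100
        changes["n_cycles"] = max(cfg.n_cycles, 100 - spec.start_age)
    if spec.disutility_years is not None:
        changes["surgical_disutility_years"] = spec.disutility_years
        changes["surgical_disutility_constant"] = not spec.disutility_linear_recovery
    if spec.tamoxifen_effect_years is not None:
        changes["cp_effect_years"] = spec.tamoxifen_effect_years
    if spec.oc_mortality_multiplier is not None:
        changes["oc_mortality_multiplier"] = spec.oc_mortality_multiplier
    if spec.reconstruction_timing is not None:
        changes["reconstruction_timing"] = spec.reconstruction_timing
    return replace(cfg, **changes) if changes else cfg


def run_scenario(name: str, inputs: ModelInputs, cfg: CohortConfig):
    """Run every strategy under a named scenario.

    Returns ``(outcomes, blended)`` where ``blended`` is the uptake-weighted
    totals when the scenario defines uptake weights, else ``None``.
    """
    spec = get_scenario(name)
    scfg = apply_scenario(cfg, spec)
    outcomes = run_all_strategies(inputs, scfg)
    blended = uptake_mix(outcomes, spec.uptake_weights) if spec.uptake_weights else None
    return outcomes, blended
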