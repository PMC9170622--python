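"""Comparative cost-effectiveness: league table, ICERs, dominance, NMB.

Dominance vocabulary: a strategy is *absolutely dominated* if some other
strategy is at least as cheap and at least as effective (one strictly);
*extendedly dominated* if it lies above the convex cost-effectiveness
frontier (a mix of two other strategies would beat it); *dominant* if it
absolutely dominates every comparator.  ICERs are only reported as numbers
for more-costly-and-more-effective comparisons; dominated comparisons get a
label, never a negative ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import StrategyOutcome
from .params import ConfigurationError

REFERENCE = "IS"


@dataclass(frozen=True)
class CUAResult:
    """Per-strategy totals plus increments against the reference strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    total_ly: float
    d_cost: float = 0.0
    d_qaly: float = 0.0
    d_ly: float = 0.0
    icer: float | str = "reference"
    dominance: str = "nondominated"


def incremental(a: StrategyOutcome | CUAResult, b: StrategyOutcome | CUAResult):
    """Differences b - a and the ICER (or a dominance label).

    The ICER d_cost/d_qaly is only a meaningful number when b is both more
    costly and more effective; otherwise a label is returned.
    """
    d_cost = b.total_cost - a.total_cost
    d_qaly = b.total_qaly - a.total_qaly
    d_ly = b.total_ly - a.total_ly
    if d_cost == 0 and d_qaly == 0:
        icer: float | str = "reference"
    elif d_qaly > 0 and d_cost > 0:
        icer = d_cost / d_qaly
    elif d_qaly >= 0 and d_cost <= 0:
        icer = "dominant"
    elif d_qaly <= 0 and d_cost >= 0:
        icer = "dominated"
    else:  # cheaper and less effective: a ratio would be ambiguous
        icer = "less costly, less effective"
    return d_cost, d_qaly, d_ly, icer


def net_monetary_benefit(result: StrategyOutcome | CUAResult, wtp: float) -> float:
    """wtp * QALY - cost, in the currency of the result."""
    if wtp < 0:
        raise ConfigurationError("willingness-to-pay must be >= 0")
    return wtp * result.total_qaly - result.total_cost


def _absolutely_dominated(i: int, costs: Sequence[float], qalys: Sequence[float]) -> bool:
    for j in range(len(costs)):
        if j == i:
            continue
        if costs[j] <= costs[i] and qalys[j] >= qalys[i] and (
            costs[j] < costs[i] or qalys[j] > qalys[i]
        ):
            return True
    return False


def dominance_frontier(results: Sequence[StrategyOutcome | CUAResult]) -> list[str]:
    """Dominance label per input result (same order).

    Labels: ``dominant`` (beats every comparator on both axes),
    ``absolutely_dominated``, ``extendedly_dominated``, ``nondominated``.
    """
    if len(results) < 2:
        raise ConfigurationError("dominance analysis needs at least two strategies")
    costs = [r.total_cost for r in results]
    qalys = [r.total_qaly for r in results]
    n = len(results)
    labels = ["nondominated"] * n

    for i in range(n):
        if _absolutely_dominated(i, costs, qalys):
            labels[i] = "absolutely_dominated"

    # extended dominance: a nondominated point beaten by a convex combination
    # of two others (it lies above the lower-right convex hull)
    for i in range(n):
        if labels[i] != "nondominated":
            continue
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k):
                    continue
                dq = qalys[k] - qalys[j]
                if dq == 0:
                    continue
                lam = (qalys[i] - qalys[j]) / dq
                if not 0.0 <= lam <= 1.0:
                    continue
                mix_cost = costs[j] + lam * (costs[k] - costs[j])
                if mix_cost < costs[i] - 1e-12:
                    labels[i] = "extendedly_dominated"
                    break
            if labels[i] == "extendedly_dominated":
                break

    for i in range(n):
        if labels[i] != "nondominated":
            continue
        if all(
            costs[i] <= costs[j] and qalys[i] >= qalys[j]
            and (costs[i] < costs[j] or qalys[i] > qalys[j])
            for j in range(n) if j != i
        ):
            labels[i] = "dominant"
    return labels


def league_table(
    outcomes: Mapping[str, StrategyOutcome], reference: str = REFERENCE
) -> pd.DataFrame:
    """Comparative league table: one row per strategy, sorted by cost
    descending (reference-first ordering of the printed tables), with
    increments against the reference and dominance labels."""
    if reference not in outcomes:
        raise ConfigurationError(f"reference strategy {reference!r} missing from results")
    ref = outcomes[reference]
    names = list(outcomes)
    labels = dominance_frontier([outcomes[n] for n in names])
    rows = []
    for name, label in zip(names, labels):
        r = outcomes[name]
        d_cost, d_qaly, d_ly, icer = incremental(ref, r)
        rows.append({
            "strategy": name,
            "cost": r.total_cost,
            "qaly": r.total_qaly,
            "ly": r.total_ly,
            "d_cost": d_cost if name != reference else 0.0,
            "d_qaly": d_qaly if name != reference else 0.0,
            "d_ly": d_ly if name != reference else 0.0,
            "icer": "reference" if name == reference else icer,
            "dominance": label.replace("absolutely_dominated", "abs. dominated")
                              .replace("extendedly_dominated", "ext. dominated"),
        })
    df = pd.DataFrame(rows).sort_values("cost", ascending=False, kind="stable")
    return df.reset_index(drop=True)


def nmb_ranking(outcomes: Mapping[str, StrategyOutcome], wtp: float) -> pd.DataFrame:
    rows = [
        {"strategy": name, "nmb": net_monetary_benefit(r, wtp)}
        for name, r in outcomes.items()
    ]
    return pd.DataFrame(rows).sort_values("nmb", ascending=False).reset_index(drop=True)
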