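"""The nine aggregate health states unrolled into a 36-state tunnel space.

Aggregate states: DF, BC, CBC, MBC, PostBC, PostCBC, OC, PostOC, Dead.
BC, CBC and OC are expanded into ten one-year tunnel states tracking time
since diagnosis, so that cancer-specific mortality, utility recovery and
year-specific treatment costs can depend on it.  After ten event-free years
the cohort moves to the corresponding post-cancer state.
"""

from __future__ import annotations

from dataclasses import dataclass

TUNNEL_LENGTH = 10

AGGREGATE_STATES = ("DF", "BC", "CBC", "MBC", "PostBC", "PostCBC", "OC", "PostOC", "Dead")


def _expand() -> tuple[tuple[str, ...], dict[str, str], dict[str, int | None]]:
    names: list[str] = ["DF"]
    agg: dict[str, str] = {"DF": "DF"}
    tyear: dict[str, int | None] = {"DF": None}
    for base in ("BC", "CBC"):
        for k in range(1, TUNNEL_LENGTH + 1):
            nm = f"{base}_y{k}"
            names.append(nm)
            agg[nm] = base
            tyear[nm] = k
        if base == "BC":
            names.append("MBC"); agg["MBC"] = "MBC"; tyear["MBC"] = None
            names.append("PostBC"); agg["PostBC"] = "PostBC"; tyear["PostBC"] = None
        else:
            names.append("PostCBC"); agg["PostCBC"] = "PostCBC"; tyear["PostCBC"] = None
    for k in range(1, TUNNEL_LENGTH + 1):
        nm = f"OC_y{k}"
        names.append(nm)
        agg[nm] = "OC"
        tyear[nm] = k
    names.append("PostOC"); agg["PostOC"] = "PostOC"; tyear["PostOC"] = None
    names.append("Dead"); agg["Dead"] = "Dead"; tyear["Dead"] = None
    return tuple(names), agg, tyear


STATE_NAMES, AGGREGATE_OF, TUNNEL_YEAR_OF = _expand()
N_STATES = len(STATE_NAMES)
IDX = {name: i for i, name in enumerate(STATE_NAMES)}

DEAD = IDX["Dead"]
DF = IDX["DF"]
MBC = IDX["MBC"]
POST_BC, POST_CBC, POST_OC = IDX["PostBC"], IDX["PostCBC"], IDX["PostOC"]
BC_Y = tuple(IDX[f"BC_y{k}"] for k in range(1, TUNNEL_LENGTH + 1))
CBC_Y = tuple(IDX[f"CBC_y{k}"] for k in range(1, TUNNEL_LENGTH + 1))
OC_Y = tuple(IDX[f"OC_y{k}"] for k in range(1, TUNNEL_LENGTH + 1))

#: states whose transition to death triggers the palliative lump sum
PALLIATIVE_STATES = BC_Y + CBC_Y + (MBC,) + OC_Y
ALIVE = tuple(i for i in range(N_STATES) if i != DEAD)


@dataclass(frozen=True)
class ExpandedStateSpace:
    """The expanded state space with projection helpers."""

    states: tuple[str, ...] = STATE_NAMES

    def __len__(self) -> int:
        return len(self.states)

    def aggregate(self, state: str) -> str:
        return AGGREGATE_OF[state]

    def tunnel_year(self, state: str) -> int | None:
        return TUNNEL_YEAR_OF[state]

    def no_event_successor(self, state: str) -> str:
        """Where the cohort mass goes when no event occurs during a cycle."""
        agg = AGGREGATE_OF[state]
        k = TUNNEL_YEAR_OF[state]
        if k is not None:
            if k < TUNNEL_LENGTH:
                return f"{agg}_y{k + 1}"
            return {"BC": "PostBC", "CBC": "PostCBC", "OC": "PostOC"}[agg]
        return state


def build_state_space() -> ExpandedStateSpace:
    """Construct the 36-state expanded space (1 DF + 10 BC + 10 CBC + 1 MBC
    + 1 PostBC + 1 PostCBC + 10 OC + 1 PostOC + 1 Dead)."""
    return ExpandedStateSpace()
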