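"""Health-state alphabet and the legal one-year transition topology.

Ten states: Health, three single-risk-factor states (hypertension,
hyperlipidemia, diabetes), three double-risk-factor states, one
triple-risk-factor state, CAD and Death.  Progression is strictly
monotone in the risk-factor set: a level-m state may move only to a
level-(m+1) superset, to CAD, to Death, or stay put.  CAD exits only
to Death; Death is terminal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "State",
    "HEALTH",
    "HT",
    "HYPERLIP",
    "DM",
    "HT_HYPERLIP",
    "HT_DM",
    "DM_HYPERLIP",
    "HT_HYPERLIP_DM",
    "CAD",
    "DEATH",
    "STATES",
    "STATE_BY_LABEL",
    "NONABSORBING_STATES",
    "RF_CONDITIONS",
    "TRANSITIONS",
    "allowed",
    "successor_states",
    "state_for_rf_set",
    "export_topology",
]

#: canonical risk-factor ordering used when composing labels
RF_CONDITIONS = ("Ht", "HyperLip", "Dm")


@dataclass(frozen=True)
class State:
    """One health state: a label, its risk-factor set, and absorption flags."""

    label: str
    rf_set: frozenset = field(default_factory=frozenset)
    absorbing: bool = False

    @property
    def level(self) -> int:
        """Number of accumulated risk factors (0 for Health/CAD/Death)."""
        return len(self.rf_set)

    def __repr__(self) -> str:  # keep error messages short
        return f"State({self.label!r})"

    def __str__(self) -> str:
        return self.label


def _rf(*conds: str) -> frozenset:
    return frozenset(conds)


HEALTH = State("Health")
HT = State("Ht", _rf("Ht"))
HYPERLIP = State("HyperLip", _rf("HyperLip"))
DM = State("Dm", _rf("Dm"))
HT_HYPERLIP = State("Ht&HyperLip", _rf("Ht", "HyperLip"))
HT_DM = State("Ht&Dm", _rf("Ht", "Dm"))
DM_HYPERLIP = State("Dm&HyperLip", _rf("Dm", "HyperLip"))
HT_HYPERLIP_DM = State("Ht&HyperLip&Dm", _rf("Ht", "HyperLip", "Dm"))
# CAD is quasi-absorbing: its only exit is to Death.
CAD = State("CAD")
DEATH = State("Death", absorbing=True)

STATES: tuple[State, ...] = (
    HEALTH,
    HT,
    HYPERLIP,
    DM,
    HT_HYPERLIP,
    HT_DM,
    DM_HYPERLIP,
    HT_HYPERLIP_DM,
    CAD,
    DEATH,
)

STATE_BY_LABEL: dict[str, State] = {s.label: s for s in STATES}

#: states that can still move somewhere else next year
NONABSORBING_STATES: tuple[State, ...] = tuple(s for s in STATES if not s.absorbing)

_RF_STATES = tuple(s for s in STATES if s not in (CAD, DEATH))
_STATE_BY_RF = {s.rf_set: s for s in _RF_STATES}


def state_for_rf_set(conditions: Iterable[str]) -> State:
    """Map a set of diagnosed risk-factor conditions to its state.

    Raises ``KeyError`` naming any unknown condition.
    """
    conds = frozenset(conditions)
    unknown = conds - frozenset(RF_CONDITIONS)
    if unknown:
        raise KeyError(f"unknown risk-factor condition(s): {sorted(unknown)}")
    return _STATE_BY_RF[conds]


def _build_transitions() -> tuple[tuple[State, State], ...]:
    pairs: list[tuple[State, State]] = []
    for j in _RF_STATES:
        pairs.append((j, j))  # self-loop
        for k in _RF_STATES:
            if k.level == j.level + 1 and j.rf_set < k.rf_set:
                pairs.append((j, k))
        pairs.append((j, CAD))
        pairs.append((j, DEATH))
    pairs.append((CAD, CAD))
    pairs.append((CAD, DEATH))
    return tuple(pairs)


#: ordered list of legal one-year (from, to) pairs, self-loops included
TRANSITIONS: tuple[tuple[State, State], ...] = _build_transitions()

_TRANSITION_SET = frozenset(TRANSITIONS)


def _coerce(state: "State | str") -> State:
    if isinstance(state, State):
        if state.label not in STATE_BY_LABEL:
            raise KeyError(f"unknown state label: {state.label!r}")
        return state
    try:
        return STATE_BY_LABEL[state]
    except KeyError:
        raise KeyError(f"unknown state label: {state!r}") from None


def allowed(from_state: "State | str", to_state: "State | str") -> bool:
    """True iff ``from_state -> to_state`` is a legal one-year transition."""
    return (_coerce(from_state), _coerce(to_state)) in _TRANSITION_SET


def successor_states(from_state: "State | str") -> list[State]:
    """All legal destinations of ``from_state`` (self-loop included).

    Death has no successors and yields an empty list.
    """
    j = _coerce(from_state)
    return [k for (f, k) in TRANSITIONS if f == j]


def destination_states(from_state: "State | str") -> list[State]:
    """Non-self destinations of ``from_state``, in canonical order."""
    j = _coerce(from_state)
    return [k for k in successor_states(j) if k != j]


def export_topology(path) -> None:
    """Write the transition topology as delimited text (from_state,to_state)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("from_state,to_state\n")
        for j, k in TRANSITIONS:
            fh.write(f"{j.label},{k.label}\n")
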