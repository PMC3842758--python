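"""Extended Petri-net data model and local firing semantics.

Places carry integer token counts that represent discrete activity levels of
molecular species.  Transitions represent interactions and come in three
classes: ``stochastic`` (Gillespie-sampled, optionally delayed), ``immediate``
(fire in zero time whenever their propensity is positive) and ``continuous``
(move tokens at a rate equal to their propensity).  Pre-edges may be
``standard`` (consume tokens), ``read`` (require but do not consume, i.e.
catalysis) or ``inhibitor`` (force the propensity to zero above a cut-off).

The propensity of a transition is

    P_t = c_t * prod_i mu(x_i)

where ``c_t`` is the rate constant and ``mu`` is a piecewise-constant activity
looked up per pre-place from an :class:`ActivityTable` of (threshold,
activity) pairs: the activity of the entry with the largest threshold not
exceeding the token count applies.  Inhibition is expressed uniformly through
tables that drop to zero at the cut-off, keeping the propensity a pure
product.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

PLACE_KINDS = ("regular", "logical", "constraint", "objective")
TRANSITION_KLASSES = ("stochastic", "immediate", "continuous")
EDGE_KINDS = ("standard", "read", "inhibitor")


class ValidationError(ValueError):
    """A model element violates a structural invariant."""


class FiringError(RuntimeError):
    """A transition was fired while disabled."""


@dataclass(frozen=True)
class ActivityTable:
    """Piecewise-constant threshold -> activity lookup.

    ``entries`` is an ordered tuple of ``(threshold, activity)`` pairs with
    strictly increasing non-negative integer thresholds, the first of which
    must be 0 so that every token count maps to an activity.  Intervals are
    left-closed: activity ``a_i`` applies for token counts in
    ``[t_i, t_{i+1})``.
    """

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple((int(t), float(a)) for t, a in self.entries))

    def check(self) -> list[str]:
        """Return a list of structural problems (empty if well formed)."""
        problems: list[str] = []
        if not self.entries:
            problems.append("activity table has no entries")
            return problems
        if self.entries[0][0] != 0:
            problems.append(f"first threshold must be 0, got {self.entries[0][0]}")
        thresholds = [t for t, _ in self.entries]
        if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
            problems.append(f"thresholds not strictly increasing: {thresholds}")
        if any(t < 0 for t in thresholds):
            problems.append(f"negative threshold in {thresholds}")
        if any(a < 0 for _, a in self.entries):
            problems.append("negative activity value")
        return problems

    def activity(self, tokens: int) -> float:
        """Activity of the entry with the largest threshold <= ``tokens``."""
        if tokens < 0:
            raise ValidationError(f"negative token count {tokens}")
        problems = self.check()
        if problems:
            raise ValidationError("; ".join(problems))
        idx = bisect_right([t for t, _ in self.entries], tokens) - 1
        return self.entries[idx][1]

    # Common table shapes ---------------------------------------------------

    @staticmethod
    def step(threshold: int = 1, low: float = 0.0, high: float = 1.0) -> "ActivityTable":
        """0 below ``threshold``, ``high`` at and above it (substrate/activator)."""
        if threshold == 0:
            return ActivityTable(((0, high),))
        return ActivityTable(((0, low), (threshold, high)))

    @staticmethod
    def inhibitor(cutoff: int = 1, active: float = 1.0) -> "ActivityTable":
        """``active`` below ``cutoff``, 0 at and above it."""
        return ActivityTable(((0, active), (cutoff, 0.0)))

    @staticmethod
    def linear(capacity: int) -> "ActivityTable":
        """Activity equal to the token count up to ``capacity`` (mass-action-like)."""
        return ActivityTable(tuple((i, float(i)) for i in range(capacity + 1)))


def place_activity(tokens: int, table: ActivityTable) -> float:
    """Evaluate the pre-place activity mu(tokens) for a lookup table."""
    return table.activity(tokens)


@dataclass
class Place:
    """Token-bearing node.

    ``capacity=None`` means unbounded.  ``logical`` places are aliases sharing
    one counter: token state is keyed by id, so every edge naming the same id
    sees the same count.  ``constraint``/``objective`` places are the coupling
    interface to the metabolic part.
    """

    id: str
    name: str = ""
    kind: str = "regular"
    tokens: int = 0
    capacity: int | None = None


@dataclass(frozen=True)
class Edge:
    """Arc between a place and a transition.

    ``kind`` applies to pre-edges; post-edges are always standard.  ``weight``
    is the number of tokens consumed/produced per firing on standard edges.
    ``table`` gives the pre-place activity; when omitted a default is derived:
    standard/read edges use a 0/1 step at ``weight`` (resp. 1), inhibitor
    edges a cut-off at 1.
    """

    place: str
    kind: str = "standard"
    weight: int = 1
    table: ActivityTable | None = None

    def effective_table(self) -> ActivityTable:
        if self.table is not None:
            return self.table
        if self.kind == "inhibitor":
            return ActivityTable.inhibitor(1)
        return ActivityTable.step(self.weight if self.kind == "standard" else 1)


@dataclass
class Transition:
    id: str
    klass: str = "stochastic"
    rate: float = 1.0
    delay: float = 0.0
    pre: tuple[Edge, ...] = ()
    post: tuple[Edge, ...] = ()


@dataclass
class NetState:
    """Marking of the net plus simulation clock (arbitrary units)."""

    tokens: dict[str, int]
    time: float = 0.0

    def copy(self) -> "NetState":
        return NetState(dict(self.tokens), self.time)


class PetriNet:
    """Container for places and transitions with id-keyed lookup."""

    def __init__(self, places: list[Place] | None = None,
                 transitions: list[Transition] | None = None) -> None:
        self.places: dict[str, Place] = {}
        self.transitions: dict[str, Transition] = {}
        for p in places or []:
            self.add_place(p)
        for t in transitions or []:
            self.add_transition(t)

    def add_place(self, place: Place) -> Place:
        if place.id in self.places:
            raise ValidationError(f"duplicate place id {place.id!r}")
        self.places[place.id] = place
        return place

    def add_transition(self, t: Transition) -> Transition:
        if t.id in self.transitions:
            raise ValidationError(f"duplicate transition id {t.id!r}")
        self.transitions[t.id] = t
        return t

    def capacity(self, place_id: str) -> int | None:
        return self.places[place_id].capacity

    def initial_state(self) -> NetState:
        return NetState({p.id: p.tokens for p in self.places.values()}, 0.0)

    def transitions_of_klass(self, klass: str) -> list[Transition]:
        return [t for t in self.transitions.values() if t.klass == klass]

    def copy(self) -> "PetriNet":
        net = PetriNet()
        for p in self.places.values():
            net.add_place(replace(p))
        for t in self.transitions.values():
            net.add_transition(replace(t))
        return net


def transition_propensity(state: NetState, t: Transition) -> float:
    """P_t = c_t * product of pre-place activities (empty product = 1)."""
    p = t.rate
    for edge in t.pre:
        if p == 0.0:
            return 0.0
        p *= edge.effective_table().activity(state.tokens[edge.place])
    return p


def is_enabled(state: NetState, t: Transition, multiplicity: int = 1) -> bool:
    """Enabled = positive propensity and enough tokens on standard pre-edges."""
    if transition_propensity(state, t) <= 0.0:
        return False
    for edge in t.pre:
        if edge.kind == "standard" and state.tokens[edge.place] < edge.weight * multiplicity:
            return False
    return True


def fire(state: NetState, t: Transition, net: PetriNet, multiplicity: int = 1) -> NetState:
    """Fire ``t`` ``multiplicity`` times atomically, returning a new state.

    Standard pre-places lose ``weight * multiplicity`` tokens; post-places
    gain the same, clamped at capacity (clamping is logged — inhibitory rules,
    not capacity, are expected to gate firing).  Read/inhibitor pre-places are
    untouched.  The input state is not mutated.
    """
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if not is_enabled(state, t, multiplicity):
        raise FiringError(f"transition {t.id!r} fired while disabled")
    new = state.copy()
    for edge in t.pre:
        if edge.kind == "standard":
            new.tokens[edge.place] -= edge.weight * multiplicity
    for edge in t.post:
        cap = net.capacity(edge.place)
        raised = new.tokens[edge.place] + edge.weight * multiplicity
        if cap is not None and raised > cap:
            log.debug("clamping %s at capacity %d after firing %s", edge.place, cap, t.id)
            raised = cap
        new.tokens[edge.place] = raised
    return new


def validate_net(net: PetriNet) -> list[str]:
    """Structural validation; returns human-readable violations (empty = OK)."""
    violations: list[str] = []
    for p in net.places.values():
        if p.kind not in PLACE_KINDS:
            violations.append(f"place {p.id!r}: unknown kind {p.kind!r}")
        if p.tokens < 0:
            violations.append(f"place {p.id!r}: negative token count {p.tokens}")
        if p.capacity is not None:
            if p.capacity < 1:
                violations.append(f"place {p.id!r}: capacity must be positive")
            elif p.tokens > p.capacity:
                violations.append(f"place {p.id!r}: tokens {p.tokens} exceed capacity {p.capacity}")
    for t in net.transitions.values():
        if t.klass not in TRANSITION_KLASSES:
            violations.append(f"transition {t.id!r}: unknown class {t.klass!r}")
        if t.rate < 0:
            violations.append(f"transition {t.id!r}: negative rate")
        if t.delay < 0:
            violations.append(f"transition {t.id!r}: negative delay")
        if t.delay > 0 and t.klass != "stochastic":
            violations.append(f"transition {t.id!r}: delay on non-stochastic transition")
        for edge in t.pre:
            violations.extend(_check_edge(net, t, edge, pre=True))
        for edge in t.post:
            violations.extend(_check_edge(net, t, edge, pre=False))
    return violations


def _check_edge(net: PetriNet, t: Transition, edge: Edge, pre: bool) -> list[str]:
    where = f"transition {t.id!r} {'pre' if pre else 'post'}-edge to {edge.place!r}"
    out: list[str] = []
    if edge.place not in net.places:
        out.append(f"{where}: unknown place")
    if edge.kind not in EDGE_KINDS:
        out.append(f"{where}: unknown edge kind {edge.kind!r}")
    if not pre and edge.kind != "standard":
        out.append(f"{where}: {edge.kind} edges are not allowed as post-edges")
    if edge.kind == "standard" and edge.weight < 1:
        out.append(f"{where}: standard edge weight must be >= 1")
    if edge.table is not None:
        out.extend(f"{where}: {p}" for p in edge.table.check())
    return out
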