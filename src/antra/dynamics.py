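"""Update schemes and the global transition relation.

A local transition is *playable* in a global state when its origin level
and every level in its condition are active.  A global step plays an
*update set* of playable transitions:

* asynchronous scheme: exactly one playable transition fires, so each
  global step changes exactly one automaton;
* synchronous scheme: every automaton with at least one playable
  transition fires exactly one of them (empty steps are forbidden in both
  schemes, so no state is ever its own successor).

Both schemes are non-deterministic in general.  Under the synchronous
scheme the only source of non-determinism is a pair of *in-conflict*
transitions: same automaton, same origin, different destinations, jointly
playable in some state.  In a Boolean network (all automata two-valued)
in-conflict pairs cannot exist and the synchronous dynamics is
deterministic.

The :class:`SuccessorProvider` contract is the seam between AN semantics
and the graph algorithms downstream (cycle enumeration, terminal-SCC
oracle): anything with an enumerable finite state set and a successor
function can be analysed, which allows explicit transition systems with no
AN realisation (e.g. the packaged star graph).
"""

from __future__ import annotations

from itertools import product
from typing import Hashable, Iterable, Iterator, Protocol, runtime_checkable

from .model import AutomataNetwork, GlobalState, LocalTransition, ModelError

__all__ = [
    "ASYNCHRONOUS",
    "SYNCHRONOUS",
    "SCHEMES",
    "normalize_scheme",
    "playable",
    "update_sets",
    "apply",
    "successors",
    "in_conflict",
    "SuccessorProvider",
    "AnDynamics",
    "ExplicitTransitionSystem",
    "as_provider",
]

ASYNCHRONOUS = "asynchronous"
SYNCHRONOUS = "synchronous"
SCHEMES = (ASYNCHRONOUS, SYNCHRONOUS)

_ALIASES = {
    "asynchronous": ASYNCHRONOUS,
    "asyn": ASYNCHRONOUS,
    "async": ASYNCHRONOUS,
    "synchronous": SYNCHRONOUS,
    "syn": SYNCHRONOUS,
    "sync": SYNCHRONOUS,
}


def normalize_scheme(scheme: str) -> str:
    """Map a scheme name or alias (asyn/syn) to its canonical spelling."""
    try:
        return _ALIASES[scheme.lower()]
    except (KeyError, AttributeError):
        raise ValueError(
            f"unknown update scheme {scheme!r}; expected one of {SCHEMES}"
        ) from None


def playable(net: AutomataNetwork, state: GlobalState) -> frozenset[LocalTransition]:
    """The playable set P_state: origin active and condition satisfied."""
    return frozenset(
        t
        for t in net.transitions
        if state[t.automaton] == t.origin and all(ls in state for ls in t.condition)
    )


def update_sets(
    net: AutomataNetwork, state: GlobalState, scheme: str
) -> frozenset[frozenset[LocalTransition]]:
    """All update sets playable in ``state`` under the given scheme.

    Asynchronous: one singleton per playable transition.  Synchronous: the
    Cartesian product, over each automaton with at least one playable
    transition, of its playable transitions (exponential in the number of
    simultaneously non-deterministic automata, which is fine at desk
    scale).  Empty iff nothing is playable, i.e. at a fixed point.
    """
    scheme = normalize_scheme(scheme)
    p = playable(net, state)
    if scheme == ASYNCHRONOUS:
        return frozenset(frozenset([t]) for t in p)
    by_automaton: dict[str, list[LocalTransition]] = {}
    for t in sorted(p, key=lambda t: t.label):
        by_automaton.setdefault(t.automaton, []).append(t)
    if not by_automaton:
        return frozenset()
    return frozenset(
        frozenset(combo) for combo in product(*by_automaton.values())
    )


def apply(
    net: AutomataNetwork, state: GlobalState, u: Iterable[LocalTransition]
) -> GlobalState:
    """Play update set ``u`` in ``state`` (the substitution operator).

    Levels of automata named in ``u`` are replaced by the transitions'
    destinations; all others are unchanged.  Because update sets are
    non-empty and every member strictly changes its automaton, the result
    always differs from ``state``.
    """
    u = frozenset(u)
    if not u:
        raise ModelError("empty update sets are not allowed")
    updates: dict[str, int] = {}
    for t in u:
        if state[t.automaton] != t.origin or not all(ls in state for ls in t.condition):
            raise ModelError(f"transition {t.label} ({t}) is not playable in {state}")
        if t.automaton in updates:
            raise ModelError(f"two transitions of automaton {t.automaton!r} in one update set")
        updates[t.automaton] = t.destination
    return state.replace(updates)


def successors(
    net: AutomataNetwork, state: GlobalState, scheme: str
) -> frozenset[GlobalState]:
    """Deduplicated image of the update sets under :func:`apply`."""
    return frozenset(apply(net, state, u) for u in update_sets(net, state, scheme))


def in_conflict(net: AutomataNetwork, t1: LocalTransition, t2: LocalTransition) -> bool:
    """Whether two transitions of one automaton are in-conflict.

    True iff they share their origin, have different destinations, and some
    global state makes both playable at once.  The witness existence check
    merges the two conditions and verifies no automaton is assigned two
    different levels (conditions never constrain the own automaton, whose
    origin levels are equal by hypothesis), so no state enumeration is
    needed.
    """
    if t1.automaton != t2.automaton:
        raise ModelError("in-conflict is defined for transitions of one automaton")
    if t1.origin != t2.origin or t1.destination == t2.destination:
        return False
    required: dict[str, int] = {}
    for ls in t1.condition | t2.condition:
        if required.setdefault(ls.automaton, ls.level) != ls.level:
            return False
    return True


# ---------------------------------------------------------------------------
# Successor providers
# ---------------------------------------------------------------------------

@runtime_checkable
class SuccessorProvider(Protocol):
    """A finite transition system: enumerable states plus a successor map."""

    def states(self) -> Iterable[Hashable]: ...

    def successors(self, state: Hashable) -> frozenset: ...


class AnDynamics:
    """Successor provider backed by an automata network under one scheme."""

    def __init__(self, net: AutomataNetwork, scheme: str):
        self.net = net
        self.scheme = normalize_scheme(scheme)
        self._cache: dict[GlobalState, frozenset[GlobalState]] = {}

    def states(self) -> Iterator[GlobalState]:
        return self.net.states()

    def successors(self, state: GlobalState) -> frozenset[GlobalState]:
        try:
            return self._cache[state]
        except KeyError:
            succ = successors(self.net, state, self.scheme)
            self._cache[state] = succ
            return succ

    def __repr__(self) -> str:
        return f"AnDynamics({self.net!r}, {self.scheme})"


class ExplicitTransitionSystem:
    """Successor provider over an explicit state list and edge list."""

    def __init__(self, states: Iterable[Hashable], edges: Iterable[tuple]):
        self._states = list(states)
        state_set = set(self._states)
        self._succ: dict[Hashable, set] = {s: set() for s in self._states}
        for src, dst in edges:
            if src not in state_set or dst not in state_set:
                raise ModelError(f"edge ({src!r}, {dst!r}) references an unknown state")
            self._succ[src].add(dst)
        self.scheme = None

    def states(self) -> list:
        return list(self._states)

    def successors(self, state: Hashable) -> frozenset:
        return frozenset(self._succ[state])

    def edges(self) -> list[tuple]:
        return [(s, d) for s in self._states for d in sorted(self._succ[s], key=repr)]

    def __repr__(self) -> str:
        n_edges = sum(len(v) for v in self._succ.values())
        return f"ExplicitTransitionSystem({len(self._states)} states, {n_edges} edges)"


def as_provider(obj, scheme: str | None = None) -> SuccessorProvider:
    """Coerce an AutomataNetwork (+ scheme) or pass through a provider."""
    if isinstance(obj, AutomataNetwork):
        if scheme is None:
            raise ValueError("an update scheme is required for an AutomataNetwork")
        return AnDynamics(obj, scheme)
    if isinstance(obj, SuccessorProvider):
        return obj
    raise TypeError(f"cannot interpret {obj!r} as a transition system")
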