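"""Exhaustive enumeration of fixed points (steady states).

A fixed point is a global state in which no local transition is playable;
it is the same set of states under the asynchronous and the synchronous
scheme, so no scheme argument appears here.

The enumeration mirrors a prefilter + generate + constraint structure:

1. *prefilter* — a level that is the origin of a transition with an empty
   condition (a self-transition, playable whenever its origin is active)
   can never be stable and is excluded from the candidate levels;
2. *generate* — iterate the Cartesian product of the surviving candidate
   levels lazily, so large fixed-point sets stay memory-bounded;
3. *constraint* — keep exactly the states whose playable set is empty.
"""

from __future__ import annotations

from itertools import product
from typing import Iterator

from .model import AutomataNetwork, GlobalState
from .dynamics import playable

__all__ = ["stable_candidates", "iter_fixed_points", "enumerate_fixed_points"]


def stable_candidates(net: AutomataNetwork) -> dict[str, tuple[int, ...]]:
    """Per automaton, the levels that are not the origin of any
    empty-condition transition.  An automaton whose every level is excluded
    yields an empty tuple, in which case the network has no fixed point.
    """
    unstable: dict[str, set[int]] = {a: set() for a in net.automata}
    for t in net.transitions:
        if not t.condition:
            unstable[t.automaton].add(t.origin)
    return {
        a: tuple(i for i in range(count) if i not in unstable[a])
        for a, count in net.automata.items()
    }


def iter_fixed_points(
    net: AutomataNetwork, prefilter: bool = True
) -> Iterator[GlobalState]:
    """Lazily yield the fixed points in lexicographic order.

    ``prefilter=False`` disables the candidate-level prefilter (a pure
    optimisation) and scans the full state space; the result is identical.
    """
    if prefilter:
        candidates = stable_candidates(net)
        ranges = [candidates[a] for a in net.names]
        if any(not r for r in ranges):
            return
        space: Iterator = (
            GlobalState(net.names, combo) for combo in product(*ranges)
        )
    else:
        space = net.states()
    for state in space:
        if not playable(net, state):
            yield state


def enumerate_fixed_points(
    net: AutomataNetwork, prefilter: bool = True
) -> list[GlobalState]:
    """All fixed points, in deterministic lexicographic order."""
    return list(iter_fixed_points(net, prefilter=prefilter))
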