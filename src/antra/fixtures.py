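"""Packaged example models and a seeded random-network generator.

Everything the test-suite exercises is generated here, with no downloads:
the four-component multi-valued toy network, the four-state "star"
transition system (an explicit graph, since no automata-network
realisation of it is given — the successor-provider seam exists for
exactly this case), and a reproducible random network generator used by
the property/oracle-equivalence suites.
"""

from __future__ import annotations

import random
from importlib import resources
from itertools import combinations

from .model import AutomataNetwork, LocalState, LocalTransition, parse_an
from .dynamics import ExplicitTransitionSystem

__all__ = ["toy_model", "star_model", "random_an"]


def toy_model() -> AutomataNetwork:
    """The packaged four-automaton example network.

    Four automata (a, c Boolean; b, d three-valued), 12 local transitions,
    36 global states.  Its long-term behaviour: three fixed points, one
    asynchronous attractor of size 2 and one of size 4, and two synchronous
    attractors of size 2.
    """
    text = resources.files("antra").joinpath("data/toy.an").read_text()
    return parse_an(text)


def star_model() -> ExplicitTransitionSystem:
    """The four-state star transition system.

    Its unique attractor is the whole state set {s0, s1, s2, s3}: every
    covering cycle must pass through the hub s1 at least three times, so
    the shortest covering cycle (length 6) is strictly longer than the
    trace (size 4).
    """
    states = ["s0", "s1", "s2", "s3"]
    edges = [
        ("s0", "s1"),
        ("s1", "s0"),
        ("s1", "s2"),
        ("s1", "s3"),
        ("s2", "s1"),
        ("s3", "s1"),
    ]
    return ExplicitTransitionSystem(states, edges)


def _possible_transitions(names: list[str], levels: dict[str, int]):
    """All valid (automaton, origin, destination, condition) combinations
    with conditions of at most two local states of other automata."""
    out = []
    for a in names:
        others = [b for b in names if b != a]
        conds: list[frozenset[LocalState]] = [frozenset()]
        for size in (1, 2):
            if size > min(2, len(others)):
                break
            for subset in combinations(others, size):
                for combo_levels in _level_products([levels[b] for b in subset]):
                    conds.append(
                        frozenset(
                            LocalState(b, l) for b, l in zip(subset, combo_levels)
                        )
                    )
        for origin in range(levels[a]):
            for dest in range(levels[a]):
                if origin == dest:
                    continue
                for cond in conds:
                    out.append((a, origin, dest, cond))
    return out


def _level_products(counts: list[int]):
    if not counts:
        yield ()
        return
    for lvl in range(counts[0]):
        for rest in _level_products(counts[1:]):
            yield (lvl,) + rest


def random_an(
    n_automata: int, max_levels: int, n_transitions: int, seed: int
) -> AutomataNetwork:
    """A reproducible random automata network.

    Level counts are drawn uniformly from 2..max_levels, condition sizes
    uniformly from 0..min(2, n_automata - 1), and the requested number of
    distinct valid transitions is sampled without replacement.  The same
    seed always yields the same network.
    """
    if n_automata < 1:
        raise ValueError("n_automata must be >= 1")
    if max_levels < 2:
        raise ValueError("max_levels must be >= 2")
    rng = random.Random(seed)
    names = [f"a{i}" for i in range(n_automata)] if n_automata > 26 else [
        chr(ord("a") + i) for i in range(n_automata)
    ]
    levels = {a: rng.randint(2, max_levels) for a in names}
    pool = _possible_transitions(names, levels)
    # group by condition size so sizes are drawn uniformly from 0..min(2, n-1)
    by_size: dict[int, list] = {}
    for item in pool:
        by_size.setdefault(len(item[3]), []).append(item)
    if n_transitions > len(pool):
        raise ValueError(
            f"cannot draw {n_transitions} distinct transitions; only "
            f"{len(pool)} exist for this configuration"
        )
    chosen: list = []
    chosen_ids: set[int] = set()
    while len(chosen) < n_transitions:
        available = {
            s: [item for item in lst if id(item) not in chosen_ids]
            for s, lst in by_size.items()
        }
        available = {s: lst for s, lst in available.items() if lst}
        size = rng.choice(sorted(available))
        item = rng.choice(available[size])
        chosen_ids.add(id(item))
        chosen.append(item)
    transitions = [
        LocalTransition(i + 1, a, ori, dest, cond)
        for i, (a, ori, dest, cond) in enumerate(chosen)
    ]
    return AutomataNetwork(levels, transitions)
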