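"""Enumeration of length-n attractors.

An attractor is a minimal trap domain: a set of at least two global states
closed under the successor relation with no proper closed subset.
Equivalently, attractors are exactly the traces of *trap cycles* — cycles
(paths looping back to their first state) whose trace no transition can
escape — and exactly the non-singleton terminal SCCs of the
state-transition graph.  The enumeration for a given cycle length ``n``
follows a generate-and-test structure:

1. enumerate all cycles of length ``n`` (depth-first extension from every
   start state, pruned on cycle feasibility: a branch is abandoned as soon
   as the start state is unreachable within the remaining step budget);
2. drop cycles whose trace can be escaped (not trap domains);
3. drop non-minimal covering cycles: a trap cycle of length ``n`` is kept
   iff ``n`` equals the length of the shortest closed walk covering its
   trace.  This single criterion subsumes repeated sub-cycles, shortcuts
   and successive repetitions, while still admitting complex ("star")
   attractors whose shortest covering walk is strictly longer than their
   trace.

A path of length ``n`` visits up to ``n + 1`` states; its trace size is
``n + 1 - k`` where ``k`` is the number of repeated visits, so complex
attractors are reported with their true trace size rather than ``n``.

Iterating ``n`` upwards (:func:`enumerate_all_attractors`) yields every
attractor together with the smallest covering cycle length, deduplicated
by canonical trace so each attractor is reported once regardless of the
witnessing cycle's start state or traversal.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator

from .model import ModelError
from .dynamics import AnDynamics, SuccessorProvider, as_provider, update_sets, apply

__all__ = [
    "Path",
    "Attractor",
    "path_from_states",
    "repetitions",
    "trace_size",
    "enumerate_cycles",
    "is_trap_cycle",
    "is_minimal_cycle",
    "shortest_covering_cycle_length",
    "enumerate_attractors",
    "enumerate_all_attractors",
]


@dataclass(frozen=True)
class Path:
    """A sequence of ``n + 1`` global states linked by ``n`` global steps.

    ``played``, when available (AN-backed paths), holds the update set
    fired at each step.  Paths must have strictly positive length.
    """

    states: tuple
    scheme: str | None = None
    played: tuple | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ModelError("a path must have strictly positive length")
        if self.played is not None and len(self.played) != len(self.states) - 1:
            raise ModelError("one update set per step is required")

    @property
    def length(self) -> int:
        return len(self.states) - 1

    @property
    def is_cycle(self) -> bool:
        return self.states[0] == self.states[-1]

    def trace(self) -> frozenset:
        return frozenset(self.states)


def path_from_states(obj, states: Iterable, scheme: str | None = None) -> Path:
    """Build a validated path from a state sequence.

    Every consecutive pair must be a global transition of the system.  For
    AN-backed systems the update set played at each step is reconstructed
    (the smallest matching one, by transition labels, when several produce
    the same successor).
    """
    provider = as_provider(obj, scheme)
    seq = tuple(states)
    if len(seq) < 2:
        raise ModelError("a path must have strictly positive length")
    for i in range(len(seq) - 1):
        if seq[i + 1] not in provider.successors(seq[i]):
            raise ModelError(
                f"step {i}: {seq[i + 1]} is not a successor of {seq[i]}"
            )
    played = None
    if isinstance(provider, AnDynamics):
        played_list = []
        for i in range(len(seq) - 1):
            matches = [
                u
                for u in update_sets(provider.net, seq[i], provider.scheme)
                if apply(provider.net, seq[i], u) == seq[i + 1]
            ]
            matches.sort(key=lambda u: sorted(t.label for t in u))
            played_list.append(matches[0])
        played = tuple(played_list)
    return Path(seq, provider.scheme, played)


def repetitions(path: Path) -> frozenset[int]:
    """Indices ``i in [1..n]`` whose state already occurs at some ``j < i``."""
    out = set()
    for i in range(1, len(path.states)):
        if path.states[i] in path.states[:i]:
            out.add(i)
    return frozenset(out)


def trace_size(path: Path) -> int:
    """Number of distinct states visited; equals ``n + 1 - |repetitions|``."""
    return len(set(path.states))


# ---------------------------------------------------------------------------
# Materialised successor graph with feasibility pruning
# ---------------------------------------------------------------------------

def _sorted_states(states: Iterable) -> list:
    try:
        return sorted(states)
    except TypeError:
        return sorted(states, key=repr)


class _Graph:
    """Explicit, deterministically ordered view of a successor provider."""

    def __init__(self, provider: SuccessorProvider):
        self.states = _sorted_states(provider.states())
        self.rank = {s: i for i, s in enumerate(self.states)}
        self.succ = {s: _sorted_states(provider.successors(s)) for s in self.states}
        self.succ_sets = {s: frozenset(v) for s, v in self.succ.items()}
        self.pred: dict[Hashable, list] = {s: [] for s in self.states}
        for s, targets in self.succ.items():
            for t in targets:
                self.pred[t].append(s)

    def dist_to(self, target: Hashable) -> dict:
        """Shortest forward distance from every state to ``target``."""
        dist = {target: 0}
        queue = deque([target])
        while queue:
            cur = queue.popleft()
            for p in self.pred[cur]:
                if p not in dist:
                    dist[p] = dist[cur] + 1
                    queue.append(p)
        return dist


def _closed_walks(
    g: _Graph, start: Hashable, n: int, dist: dict, restrict: bool
) -> Iterator[tuple]:
    """All closed walks ``start -> ... -> start`` of exactly ``n`` steps.

    A branch is pruned as soon as ``start`` is no longer reachable within
    the remaining budget.  With ``restrict`` set, only walks whose every
    state ranks at or above ``start`` are produced (used when each
    attractor is wanted once, anchored at its smallest state).
    """
    if dist.get(start) is None:
        return
    walk = [start]

    def extend() -> Iterator[tuple]:
        remaining = n - (len(walk) - 1)
        if remaining == 0:
            if walk[-1] == start:
                yield tuple(walk)
            return
        for nxt in g.succ[walk[-1]]:
            if dist.get(nxt, n + 1) > remaining - 1:
                continue
            if restrict and g.rank[nxt] < g.rank[start]:
                continue
            walk.append(nxt)
            yield from extend()
            walk.pop()

    yield from extend()


def enumerate_cycles(obj, n: int, scheme: str | None = None) -> Iterator[Path]:
    """All cycles of length ``n``, each exactly once, in deterministic order.

    Cycles that differ only by their start state or traversal are distinct
    here (they are distinct closed walks); deduplication by trace happens
    at the attractor level.
    """
    provider = as_provider(obj, scheme)
    if n < 1:
        raise ValueError(
            "cycle length must be >= 1; steady states are enumerated by the "
            "fixed-point search"
        )
    g = _Graph(provider)
    for start in g.states:
        dist = g.dist_to(start)
        for walk in _closed_walks(g, start, n, dist, restrict=False):
            yield Path(walk, provider.scheme)


def is_trap_cycle(obj, path: Path, scheme: str | None = None) -> bool:
    """Whether the trace of a cycle is a trap domain.

    True iff every successor of every trace state lies inside the trace;
    successors reached through transitions not on the path itself are
    allowed as long as they stay inside (shortcuts within the cycle).
    """
    provider = as_provider(obj, scheme)
    if not path.is_cycle:
        raise ModelError("is_trap_cycle requires a cycle (states[0] == states[n])")
    trace = path.trace()
    return all(provider.successors(s) <= trace for s in trace)


def shortest_covering_cycle_length(obj, trace: Iterable, scheme: str | None = None) -> int | None:
    """Length of the shortest closed walk visiting every state of ``trace``.

    The walk is restricted to trace-internal transitions.  Because a
    covering closed walk passes through every trace state, its length does
    not depend on the anchor, so the search starts from the smallest state
    only.  Returns None when no covering closed walk exists.
    """
    provider = as_provider(obj, scheme)
    states = _sorted_states(set(trace))
    index = {s: i for i, s in enumerate(states)}
    full = (1 << len(states)) - 1
    s0 = states[0]
    seen = {(s0, 1)}
    queue = deque([(s0, 1, 0)])
    while queue:
        cur, mask, d = queue.popleft()
        for nxt in provider.successors(cur):
            if nxt not in index:
                continue
            nmask = mask | (1 << index[nxt])
            if nxt == s0 and nmask == full:
                return d + 1
            if (nxt, nmask) not in seen:
                seen.add((nxt, nmask))
                queue.append((nxt, nmask, d + 1))
    return None


def is_minimal_cycle(obj, path: Path, scheme: str | None = None) -> bool:
    """Whether a trap cycle's length equals its trace's shortest covering
    closed walk, i.e. no shorter cycle covers the same attractor."""
    provider = as_provider(obj, scheme)
    if not path.is_cycle:
        raise ModelError("is_minimal_cycle requires a cycle")
    return shortest_covering_cycle_length(provider, path.trace()) == path.length


# ---------------------------------------------------------------------------
# Attractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A canonical attractor: its trace, scheme and covering cycle length."""

    trace: frozenset
    scheme: str | None
    cycle_length: int
    witness: Path = field(compare=False, repr=False)

    @property
    def size(self) -> int:
        return len(self.trace)

    @property
    def states(self) -> tuple:
        """The trace, sorted (canonical presentation order)."""
        return tuple(_sorted_states(self.trace))


def _attractors_at(
    g: _Graph,
    provider: SuccessorProvider,
    n: int,
    dedupe: bool,
    skip: frozenset = frozenset(),
    cover_cache: dict | None = None,
) -> Iterator[Attractor]:
    cover_cache = {} if cover_cache is None else cover_cache
    seen_traces: set[frozenset] = set()
    for start in g.states:
        if start in skip:
            continue
        dist = g.dist_to(start)
        for walk in _closed_walks(g, start, n, dist, restrict=dedupe):
            trace = frozenset(walk)
            if dedupe and trace in seen_traces:
                continue
            if not all(g.succ_sets[s] <= trace for s in trace):
                continue  # the cycle can be escaped: not a trap domain
            if trace not in cover_cache:
                cover_cache[trace] = shortest_covering_cycle_length(provider, trace)
            if cover_cache[trace] != n:
                continue  # a shorter cycle covers the same trace
            yield Attractor(trace, provider.scheme, n, Path(walk, provider.scheme))
            if dedupe:
                seen_traces.add(trace)


def enumerate_attractors(
    obj, n: int, scheme: str | None = None, dedupe: bool = True
) -> list[Attractor]:
    """All attractors covered by a minimal trap cycle of length ``n``.

    With ``dedupe=True`` (default) each attractor appears once, anchored at
    its smallest state.  With ``dedupe=False`` one result is produced per
    witnessing cycle, so the same attractor may be listed several times
    (one per start state and traversal), mirroring raw exhaustive output.
    """
    provider = as_provider(obj, scheme)
    if n < 1:
        raise ValueError(
            "attractor cycle length must be >= 1; steady states are "
            "enumerated by the fixed-point search"
        )
    g = _Graph(provider)
    return list(_attractors_at(g, provider, n, dedupe))


def enumerate_all_attractors(
    obj, max_n: int, scheme: str | None = None
) -> list[Attractor]:
    """All attractors whose shortest covering cycle has length <= ``max_n``.

    Each attractor is reported once with its smallest covering cycle
    length.  States already inside a found attractor are skipped as cycle
    anchors: attractors are pairwise disjoint and trap cycles through such
    states can only re-cover the attractor already found.
    """
    provider = as_provider(obj, scheme)
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    g = _Graph(provider)
    found: list[Attractor] = []
    covered: set = set()
    cover_cache: dict = {}
    for n in range(1, max_n + 1):
        for att in _attractors_at(
            g, provider, n, dedupe=True, skip=frozenset(covered),
            cover_cache=cover_cache,
        ):
            found.append(att)
            covered.update(att.trace)
    return found
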