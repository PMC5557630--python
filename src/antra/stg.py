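"""Explicit state-transition graph and the brute-force terminal-SCC oracle.

The state-transition graph (STG) has one node per global state and one
edge per global transition under the chosen update scheme.  Because the
traces of cycles are exactly the strongly connected components, and
attractors are exactly the trap cycles, the attractors of a finite system
are exactly the terminal SCCs (no edge leaving the component) of its full
STG: singleton terminal SCCs are the fixed points (no self-edges exist),
larger ones the non-singleton attractors.  This module is the independent
brute-force authority the enumeration machinery is checked against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Hashable, Iterable

import networkx as nx

from .model import AutomataNetwork, GlobalState, ModelError
from .dynamics import as_provider

__all__ = [
    "StateTransitionGraph",
    "build_stg",
    "oracle_attractors",
    "export_graph",
    "import_graph",
    "parse_state",
]

#: refuse to materialise graphs above this many nodes
DEFAULT_STATE_GUARD = 10**6


@dataclass
class StateTransitionGraph:
    """A directed graph over global states plus the scheme that produced it."""

    graph: nx.DiGraph
    scheme: str | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        return list(self.graph.edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, StateTransitionGraph)
            and self.scheme == other.scheme
            and set(self.graph.nodes) == set(other.graph.nodes)
            and set(self.graph.edges) == set(other.graph.edges)
        )


def build_stg(
    obj,
    scheme: str | None = None,
    roots: Iterable[Hashable] | None = None,
    max_states: int = DEFAULT_STATE_GUARD,
) -> StateTransitionGraph:
    """Materialise the STG of a network or explicit transition system.

    With ``roots`` given, only the forward-reachable subgraph from those
    states is built; otherwise the full graph over all states.  Refuses
    state spaces larger than ``max_states`` nodes.
    """
    provider = as_provider(obj, scheme)
    g = nx.DiGraph()
    if roots is None:
        frontier = list(provider.states())
        if len(frontier) > max_states:
            raise ModelError(
                f"state space has {len(frontier)} states, above the guard of "
                f"{max_states}; pass roots= for a reachable subgraph"
            )
        g.add_nodes_from(frontier)
        for s in frontier:
            g.add_edges_from((s, t) for t in provider.successors(s))
    else:
        frontier = list(roots)
        g.add_nodes_from(frontier)
        seen = set(frontier)
        while frontier:
            s = frontier.pop()
            for t in provider.successors(s):
                g.add_edge(s, t)
                if t not in seen:
                    if len(seen) >= max_states:
                        raise ModelError(
                            f"reachable subgraph exceeds the guard of {max_states} states"
                        )
                    seen.add(t)
                    frontier.append(t)
    return StateTransitionGraph(g, getattr(provider, "scheme", scheme))


def oracle_attractors(
    stg: StateTransitionGraph,
) -> tuple[frozenset, frozenset]:
    """Terminal-SCC analysis of an STG.

    Returns ``(fixed_points, attractors)``: the terminal strongly connected
    components partitioned by size — singletons are fixed points (the
    dynamics has no self-edges), components of two or more states are the
    non-singleton attractors.  Meaningful on the full graph, or on a
    reachable subgraph when only reachable long-term behaviours are wanted.
    """
    g = stg.graph
    fixed: set = set()
    attractors: set[frozenset] = set()
    for comp in nx.strongly_connected_components(g):
        if any(t not in comp for s in comp for t in g.successors(s)):
            continue  # an escaping edge: not terminal
        if len(comp) == 1:
            fixed.add(next(iter(comp)))
        else:
            attractors.add(frozenset(comp))
    return frozenset(fixed), frozenset(attractors)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _node_str(node) -> str:
    if isinstance(node, GlobalState):
        return ",".join(f"{a}:{i}" for a, i in zip(node.automata, node.levels))
    return str(node)


def parse_state(net: AutomataNetwork, literal: str) -> GlobalState:
    """Parse the command-line state literal ``a:1,b:2,c:0,d:1``."""
    assignment: dict[str, int] = {}
    for item in literal.split(","):
        name, _, level = item.strip().partition(":")
        if not level:
            raise ModelError(f"malformed state element {item.strip()!r}")
        assignment[name] = int(level)
    return net.state(assignment)


def _sorted_nodes(nodes) -> list:
    return sorted(nodes, key=_node_str)


def export_graph(
    stg: StateTransitionGraph,
    format: str = "dot",
    highlight: Iterable[frozenset] | None = None,
) -> str:
    """Render the STG as DOT or as an edge-list JSON document.

    Node order is deterministic.  ``highlight`` may give attractor traces
    to colour (fixed points and attractor members are filled), mirroring
    the usual presentation of STG figures.
    """
    colored: dict = {}
    if highlight is not None:
        palette = ["gold", "skyblue", "palegreen", "salmon", "orchid", "gray"]
        for k, comp in enumerate(sorted(highlight, key=lambda c: _node_str(min(c, key=_node_str)))):
            for node in comp:
                colored[node] = palette[k % len(palette)]
    if format == "dot":
        lines = ["digraph stg {"]
        for node in _sorted_nodes(stg.graph.nodes):
            attrs = f' [style=filled, fillcolor={colored[node]}]' if node in colored else ""
            lines.append(f'  "{_node_str(node)}"{attrs};')
        for src, dst in sorted(stg.graph.edges, key=lambda e: (_node_str(e[0]), _node_str(e[1]))):
            lines.append(f'  "{_node_str(src)}" -> "{_node_str(dst)}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    if format == "json":
        doc = {
            "scheme": stg.scheme,
            "nodes": [_node_str(n) for n in _sorted_nodes(stg.graph.nodes)],
            "edges": [
                [_node_str(s), _node_str(d)]
                for s, d in sorted(
                    stg.graph.edges, key=lambda e: (_node_str(e[0]), _node_str(e[1]))
                )
            ],
        }
        return json.dumps(doc, indent=1)
    raise ValueError(f"unknown export format {format!r}; expected 'dot' or 'json'")


def import_graph(text: str, net: AutomataNetwork | None = None) -> StateTransitionGraph:
    """Parse an edge-list JSON document produced by :func:`export_graph`.

    With ``net`` given, node literals are parsed back into global states of
    that network; otherwise nodes stay strings.
    """
    doc = json.loads(text)
    decode = (lambda s: parse_state(net, s)) if net is not None else (lambda s: s)
    g = nx.DiGraph()
    g.add_nodes_from(decode(n) for n in doc["nodes"])
    g.add_edges_from((decode(s), decode(d)) for s, d in doc["edges"])
    return StateTransitionGraph(g, doc.get("scheme"))
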