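"""Static model of a multi-valued automata network (AN).

An automata network is a triple (Sigma, S, T): a finite set of automata,
each with a finite number of discrete local levels, and a set of local
transitions ``a_i --l--> a_j`` that switch automaton ``a`` from level ``i``
to level ``j`` whenever the condition ``l`` (a set of local states of
*other* automata) holds in the current global state.  Exactly one level per
automaton is active at any time; the vector of active levels is a global
state.  The formalism generalises Boolean networks to multi-valued levels
and encompasses Thomas-style logical models.

This module defines the (immutable, value-semantic) data model, validates
it, and reads/writes the two plain-text formats used by the package:

* the AN format (one ``automaton``/``trans`` statement per line), and
* a logic-facts dialect built on the predicates ``automatonLevel/2``,
  ``automaton/1``, ``localTrans/1``, ``condition/3`` and ``target/3``,
  where the origin of a transition is serialised as the condition element
  on the transition's own automaton.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ModelError",
    "ANSyntaxError",
    "ValidationError",
    "LocalState",
    "LocalTransition",
    "AutomataNetwork",
    "GlobalState",
    "parse_an",
    "write_an",
    "parse_asp_facts",
    "write_asp_facts",
    "network_to_json",
    "network_from_json",
    "state_space_size",
]


class ModelError(ValueError):
    """Base class for model parsing/validation failures."""


class ANSyntaxError(ModelError):
    """Malformed document; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ValidationError(ModelError):
    """Structurally well-formed input that violates a model invariant."""


@dataclass(frozen=True, order=True)
class LocalState:
    """A discrete activity level ``a_i`` of one automaton."""

    automaton: str
    level: int


@dataclass(frozen=True)
class LocalTransition:
    """A local transition ``a_i --l--> a_j``.

    ``condition`` holds local states of *other* automata, at most one per
    automaton, that must all be active for the transition to be playable.
    ``label`` is the positive integer identifier used by the facts format.
    """

    label: int
    automaton: str
    origin: int
    destination: int
    condition: frozenset[LocalState] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", frozenset(self.condition))

    def __str__(self) -> str:
        cond = ", ".join(
            f"{ls.automaton}:{ls.level}" for ls in sorted(self.condition)
        )
        return (
            f"{self.automaton}:{self.origin} -> {self.destination} "
            f"when {cond or '-'}"
        )

    def _sort_key(self):
        return (self.automaton, self.origin, self.destination, sorted(self.condition))


def _as_condition(condition) -> frozenset[LocalState]:
    """Accept ``{'a': 1}`` mappings or iterables of LocalState/(name, level)."""
    if isinstance(condition, Mapping):
        return frozenset(LocalState(a, i) for a, i in condition.items())
    out = set()
    for item in condition:
        if isinstance(item, LocalState):
            out.add(item)
        else:
            a, i = item
            out.add(LocalState(a, i))
    return frozenset(out)


def transition(
    label: int, automaton: str, origin: int, destination: int, condition=()
) -> LocalTransition:
    """Convenience constructor; ``condition`` may be a ``{name: level}`` mapping."""
    return LocalTransition(label, automaton, origin, destination, _as_condition(condition))


@dataclass(frozen=True, order=True)
class GlobalState:
    """One active local state per automaton, in declaration order.

    Value semantics: two states are equal iff all per-automaton levels are
    equal, so states are usable as set members and dictionary keys.
    """

    automata: tuple[str, ...]
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.automata) != len(self.levels):
            raise ValidationError("one level per automaton is required")

    def __getitem__(self, automaton: str) -> int:
        try:
            return self.levels[self.automata.index(automaton)]
        except ValueError:
            raise KeyError(automaton) from None

    def __contains__(self, local_state: LocalState) -> bool:
        return self[local_state.automaton] == local_state.level

    def replace(self, updates: Mapping[str, int]) -> "GlobalState":
        """The substitution operator: levels in ``updates`` override, others stay."""
        levels = tuple(
            updates.get(a, lvl) for a, lvl in zip(self.automata, self.levels)
        )
        return GlobalState(self.automata, levels)

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.automata, self.levels))

    def __str__(self) -> str:
        return " ".join(f"{a}:{i}" for a, i in zip(self.automata, self.levels))


class AutomataNetwork:
    """A validated automata network ``(Sigma, S, T)``.

    ``automata`` maps each automaton name to its level count (>= 2); the
    declaration order is significant and fixes the serialisation order of
    global states.  Transition labels must be unique and contiguous from 1.
    """

    def __init__(
        self,
        automata: Mapping[str, int] | Iterable[tuple[str, int]],
        transitions: Iterable[LocalTransition] = (),
    ):
        self.automata: dict[str, int] = dict(automata)
        self.transitions: tuple[LocalTransition, ...] = tuple(
            sorted(transitions, key=lambda t: t.label)
        )
        self._names = tuple(self.automata)
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        for name, count in self.automata.items():
            if not isinstance(count, int) or count < 2:
                raise ValidationError(
                    f"automaton {name!r} must have at least 2 levels, got {count}"
                )
        labels = [t.label for t in self.transitions]
        if labels != list(range(1, len(labels) + 1)):
            raise ValidationError(
                f"transition labels must be unique and contiguous from 1, got {labels}"
            )
        for t in self.transitions:
            where = f"transition {t.label} ({t})"
            if t.automaton not in self.automata:
                raise ValidationError(f"{where}: unknown automaton {t.automaton!r}")
            count = self.automata[t.automaton]
            if not (0 <= t.origin < count and 0 <= t.destination < count):
                raise ValidationError(f"{where}: level out of range for {t.automaton!r}")
            if t.origin == t.destination:
                raise ValidationError(f"{where}: origin equals destination")
            seen: set[str] = set()
            for ls in t.condition:
                if ls.automaton == t.automaton:
                    raise ValidationError(
                        f"{where}: condition references its own automaton"
                    )
                if ls.automaton not in self.automata:
                    raise ValidationError(
                        f"{where}: unknown automaton {ls.automaton!r} in condition"
                    )
                if not 0 <= ls.level < self.automata[ls.automaton]:
                    raise ValidationError(
                        f"{where}: condition level {ls.automaton}:{ls.level} out of range"
                    )
                if ls.automaton in seen:
                    # two required levels of one automaton can never hold at once:
                    # they are structurally unplayable; reject at load.
                    raise ValidationError(
                        f"{where}: two condition levels for automaton {ls.automaton!r}"
                    )
                seen.add(ls.automaton)

    # -- states -------------------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def state(self, levels: Mapping[str, int] | None = None, **kw: int) -> GlobalState:
        """Build a global state from a full ``{automaton: level}`` assignment."""
        assignment = dict(levels or {})
        assignment.update(kw)
        if set(assignment) != set(self._names):
            raise ValidationError(
                f"state must assign exactly the automata {list(self._names)}"
            )
        st = GlobalState(self._names, tuple(assignment[a] for a in self._names))
        for a, i in zip(st.automata, st.levels):
            if not 0 <= i < self.automata[a]:
                raise ValidationError(f"level {a}:{i} out of range")
        return st

    def states(self) -> Iterator[GlobalState]:
        """All global states, in lexicographic (declaration) order."""
        for combo in product(*(range(self.automata[a]) for a in self._names)):
            yield GlobalState(self._names, combo)

    # -- value semantics ----------------------------------------------------

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AutomataNetwork)
            and self.automata == other.automata
            and list(self.automata) == list(other.automata)
            and self.transitions == other.transitions
        )

    def __hash__(self):  # pragma: no cover - not used as dict key internally
        return hash((tuple(self.automata.items()), self.transitions))

    def __repr__(self) -> str:
        return (
            f"AutomataNetwork({len(self.automata)} automata, "
            f"{len(self.transitions)} transitions)"
        )


def state_space_size(net: AutomataNetwork) -> int:
    """Number of global states: the product of the level counts."""
    return math.prod(net.automata.values())


# ---------------------------------------------------------------------------
# AN text format
# ---------------------------------------------------------------------------

_AUTOMATON_RE = re.compile(r"^automaton\s+(\w+)\s+(\d+)$")
_TRANS_RE = re.compile(
    r"^trans\s+(\w+)\s+(\d+)\s*->\s*(\d+)\s+when\s+(.+)$"
)
_COND_ITEM_RE = re.compile(r"^(\w+):(\d+)$")


def parse_an(text: str) -> AutomataNetwork:
    """Parse the line-oriented AN format.

    Grammar (one statement per line, ``#`` starts a comment)::

        automaton <name> <levelCount>
        trans <name> <origin> -> <destination> when <name>:<level>[, ...]
        trans <name> <origin> -> <destination> when -

    Transition labels are assigned in file order starting at 1.
    """
    automata: dict[str, int] = {}
    transitions: list[LocalTransition] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if m := _AUTOMATON_RE.match(line):
            name, count = m.group(1), int(m.group(2))
            if name in automata:
                raise ANSyntaxError(f"duplicate automaton {name!r}", lineno)
            automata[name] = count
        elif m := _TRANS_RE.match(line):
            name, ori, dest, cond_text = m.groups()
            condition: set[LocalState] = set()
            if cond_text.strip() != "-":
                for item in cond_text.split(","):
                    cm = _COND_ITEM_RE.match(item.strip())
                    if not cm:
                        raise ANSyntaxError(
                            f"malformed condition element {item.strip()!r}", lineno
                        )
                    condition.add(LocalState(cm.group(1), int(cm.group(2))))
            transitions.append(
                LocalTransition(
                    len(transitions) + 1, name, int(ori), int(dest),
                    frozenset(condition),
                )
            )
        else:
            raise ANSyntaxError(f"unrecognised statement {line!r}", lineno)
    return AutomataNetwork(automata, transitions)


def write_an(net: AutomataNetwork) -> str:
    """Serialise to the AN format; ``parse_an`` round-trips it."""
    lines = [f"automaton {a} {k}" for a, k in net.automata.items()]
    for t in net.transitions:
        cond = ", ".join(f"{ls.automaton}:{ls.level}" for ls in sorted(t.condition))
        lines.append(
            f"trans {t.automaton} {t.origin} -> {t.destination} when {cond or '-'}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Logic-facts format (automatonLevel/2, automaton/1, localTrans/1,
# condition/3, target/3)
# ---------------------------------------------------------------------------

_FACT_RE = re.compile(r"(\w+)\(([^()]*)\)\s*\.")
_RANGE_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def write_asp_facts(net: AutomataNetwork) -> str:
    """Emit the facts dialect.

    Automaton names are double-quoted so downstream grounders treat them as
    constants.  For each transition ``L``, the origin is serialised as the
    ``condition(L, A, I)`` fact on the transition's own automaton, alongside
    one fact per condition element, plus exactly one ``target(L, A, J)``.
    """
    out: list[str] = []
    for a, k in net.automata.items():
        out.append(f'automatonLevel("{a}",0..{k - 1}).')
    for a in net.automata:
        out.append(f'automaton("{a}").')
    for t in net.transitions:
        out.append(f"localTrans({t.label}).")
    for t in net.transitions:
        parts = [f'condition({t.label},"{t.automaton}",{t.origin}).']
        for ls in sorted(t.condition):
            parts.append(f'condition({t.label},"{ls.automaton}",{ls.level}).')
        parts.append(f'target({t.label},"{t.automaton}",{t.destination}).')
        out.append(" ".join(parts))
    return "\n".join(out) + "\n"


def _unquote(token: str) -> str:
    token = token.strip()
    if token.startswith('"') and token.endswith('"') and len(token) >= 2:
        return token[1:-1]
    return token


def parse_asp_facts(text: str) -> AutomataNetwork:
    """Parse the facts dialect back into a network.

    The ``I..J`` range sugar in ``automatonLevel`` is expanded.  The origin
    of each transition is recovered as the condition element whose automaton
    equals the target's automaton; a transition with zero or several such
    elements is rejected.
    """
    stripped = re.sub(r"%[^\n]*", "", text)  # % comments
    levels: dict[str, set[int]] = {}
    declared: set[str] = set()
    trans_labels: list[int] = []
    conditions: dict[int, list[LocalState]] = {}
    targets: dict[int, LocalState] = {}
    for m in _FACT_RE.finditer(stripped):
        pred, args_text = m.group(1), m.group(2)
        args = [a.strip() for a in args_text.split(",")] if args_text.strip() else []
        if pred == "automatonLevel":
            if len(args) != 2:
                raise ANSyntaxError(f"automatonLevel expects 2 arguments: {m.group(0)}")
            name = _unquote(args[0])
            if rm := _RANGE_RE.match(args[1]):
                lo, hi = int(rm.group(1)), int(rm.group(2))
                if lo > hi:
                    raise ANSyntaxError(f"empty range {args[1]} for automaton {name!r}")
                vals = range(lo, hi + 1)
            else:
                vals = [int(args[1])]
            levels.setdefault(name, set()).update(vals)
        elif pred == "automaton":
            declared.add(_unquote(args[0]))
        elif pred == "localTrans":
            trans_labels.append(int(args[0]))
        elif pred == "condition":
            label, name, lvl = int(args[0]), _unquote(args[1]), int(args[2])
            conditions.setdefault(label, []).append(LocalState(name, lvl))
        elif pred == "target":
            label, name, lvl = int(args[0]), _unquote(args[1]), int(args[2])
            if label in targets:
                raise ANSyntaxError(f"several target facts for transition {label}")
            targets[label] = LocalState(name, lvl)
        else:
            raise ANSyntaxError(f"unknown predicate {pred!r}")
    automata: dict[str, int] = {}
    for name, lvls in levels.items():
        if lvls != set(range(len(lvls))):
            raise ANSyntaxError(
                f"levels of automaton {name!r} are not contiguous from 0: {sorted(lvls)}"
            )
        automata[name] = len(lvls)
    if declared - set(automata):
        raise ANSyntaxError(
            f"automaton facts without levels: {sorted(declared - set(automata))}"
        )
    transitions: list[LocalTransition] = []
    for label in sorted(set(trans_labels) | set(targets) | set(conditions)):
        if label not in targets:
            raise ANSyntaxError(f"transition {label} has no target fact")
        tgt = targets[label]
        elems = conditions.get(label, [])
        own = [ls for ls in elems if ls.automaton == tgt.automaton]
        if len(own) != 1:
            raise ANSyntaxError(
                f"transition {label} needs exactly one condition fact on its own "
                f"automaton {tgt.automaton!r} (the origin), found {len(own)}"
            )
        cond = frozenset(ls for ls in elems if ls.automaton != tgt.automaton)
        transitions.append(
            LocalTransition(label, tgt.automaton, own[0].level, tgt.level, cond)
        )
    return AutomataNetwork(automata, transitions)


# ---------------------------------------------------------------------------
# JSON export
# ---------------------------------------------------------------------------

def network_to_json(net: AutomataNetwork) -> str:
    """Machine-readable JSON rendering of a network."""
    doc = {
        "automata": dict(net.automata),
        "transitions": [
            {
                "label": t.label,
                "automaton": t.automaton,
                "origin": t.origin,
                "destination": t.destination,
                "condition": {ls.automaton: ls.level for ls in sorted(t.condition)},
            }
            for t in net.transitions
        ],
    }
    return json.dumps(doc, indent=1)


def network_from_json(text: str) -> AutomataNetwork:
    doc = json.loads(text)
    return AutomataNetwork(
        doc["automata"],
        [
            transition(
                t["label"], t["automaton"], t["origin"], t["destination"],
                t.get("condition", {}),
            )
            for t in doc["transitions"]
        ],
    )
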