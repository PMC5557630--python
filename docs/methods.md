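# Methods

## Model and semantics

An automata network (AN) is a set of finite automata `a ∈ Σ`, each with
levels `0..k_a−1` (`k_a ≥ 2`), and local transitions
`a_i --ℓ--> a_j` with `i ≠ j` and `ℓ` a set of local states of other
automata, at most one per automaton. A transition whose condition names
two levels of one automaton could never fire; such transitions are
rejected at load time rather than silently carried. A global state holds
one active level per automaton; transitions are *playable* when their
origin and whole condition are active.

Two update schemes define the global step relation:

* **asynchronous** — exactly one playable transition fires;
* **synchronous** — every automaton with at least one playable transition
  fires exactly one of them (one transition per automaton, no empty step).

Both relations are non-deterministic in general; neither ever maps a
state to itself. Fixed points (states with nothing playable) coincide
under the two schemes. Synchronous non-determinism arises only from
*in-conflict* pairs: same automaton, same origin, different destinations,
jointly playable in some state. Conflict is decided without state
enumeration: two same-origin transitions are jointly playable iff the
union of their conditions assigns no automaton two different levels
(conditions never constrain the transitions' own automaton, and every
condition level is in range by validation). A subtlety worth recording:
two transitions may share origin *and* destination with different
conditions, in which case a state can admit several synchronous update
sets that all produce the same successor — so "Boolean implies
synchronous-deterministic" is a statement about successors, not about
update-set counts, and that is what the tests assert.

## Fixed-point enumeration

Prefilter, generate, constrain:

1. a level that is the origin of an empty-condition transition is
   excluded (such a transition is playable whenever its origin is, so the
   level can never be stable); an automaton losing all its levels proves
   the model has no fixed point;
2. the Cartesian product of surviving levels is iterated as a lazy
   generator, in lexicographic declaration order, so models whose
   fixed-point count is large (thousands among billions of states) stay
   memory-bounded;
3. states with a non-empty playable set are dropped.

The prefilter is a pure optimisation: enumeration with and without it is
asserted identical on random networks.

## Attractor enumeration at cycle length n

Attractors (minimal trap domains of ≥ 2 states) are exactly the traces of
cycles that are trap domains, and exactly the non-singleton terminal SCCs
of the state-transition graph. For a given `n` the enumeration is
generate-and-test over an abstract *successor provider* (an AN under one
scheme, or any explicit finite transition system):

1. **cycles** — depth-first extension from every start state produces all
   closed walks of exactly `n` steps. Branches are pruned on cycle
   feasibility only: a branch is abandoned as soon as the start state is
   unreachable within the remaining step budget (distances by reverse BFS
   on the materialised successor graph). Escape from the eventual trace
   is *not* used for pruning — whether a successor leaves the trace can
   only be judged once the trace is complete.
2. **trap check** — a cycle is kept iff every successor of every trace
   state lies inside the trace. Successors that re-enter the trace via
   transitions not on the path are allowed (shortcuts inside complex
   attractors).
3. **minimality** — a trap cycle is kept iff `n` equals the length of the
   shortest closed walk covering its trace (computed by BFS over
   (state, visited-subset) pairs restricted to trace-internal edges; a
   covering walk passes through every trace state, so anchoring the
   search at the smallest trace state loses no generality). This single
   criterion discards repeated sub-cycles, shortcut-shortenable cycles,
   and wholly repeated cycles, while still admitting complex ("star")
   attractors whose covering walk is strictly longer than their trace —
   a length-n path with k repeated visits covers n + 1 − k states, which
   is the size reported.

The minimality rule is deliberately a single exact criterion rather than
a battery of necessary conditions: it provably removes *every*
non-minimal covering cycle, at the cost of one covering-walk search per
trap cycle (cached per trace). Exactness, not speed, is the design goal
here; the covering-walk BFS is exponential in trace size in the worst
case, which is acceptable at the attractor sizes this tool targets.

Duplicate reporting is resolved by canonical traces: with deduplication
on (the default), cycle starts are restricted to the smallest state of
their trace (every covering cycle rotates to one anchored there, with the
same length), and each trace is emitted once. `dedupe=False` restores
one result per witnessing cycle — the raw multiplicity an exhaustive
answer-by-answer enumeration would print.

`enumerate_all_attractors` iterates `n = 1..max_n`, records each
attractor at its smallest covering length, and skips cycle anchors inside
already-found attractors (attractors are pairwise disjoint, and any trap
cycle through such a state can only re-cover the attractor already
found).

## Brute-force oracle

`build_stg` materialises the explicit state-transition graph (refusing
state spaces above a guard of 10^6 nodes, or building only the
forward-reachable subgraph from given roots). `oracle_attractors`
computes SCCs with networkx's linear-time algorithm and keeps components
with no outgoing edge: singletons are fixed points, larger components
attractors. The oracle implements the definitions directly and is the
authority the enumeration machinery is tested against; on every fixture
and on batches of seeded random networks the two routes are asserted
equal.

## Random-network generator

`random_an(n_automata, max_levels, n_transitions, seed)` draws level
counts uniformly from `2..max_levels`, condition sizes uniformly from
`0..min(2, n_automata−1)`, and samples the requested number of distinct
valid transitions without replacement; the same seed always reproduces
the same network. The test batches cycle through 2–5 automata, 2–3
levels and between `n` and `2n` transitions — small enough that the full
state space (≤ 243 states) can be cross-checked against the brute-force
oracle in milliseconds per network, while covering Boolean-only and
multi-valued cases, deterministic and conflicted synchronous dynamics,
and networks with zero to many attractors. What these instances do *not*
emulate is the scale and topological structure of curated literature
models (tens of automata, hub-dominated regulation); passing the
equivalence suites demonstrates correctness of the semantics and the
enumeration, not performance at genome scale.

## Numerical and determinism choices

* Levels are 0-based consecutive integers; automaton order is declaration
  order and fixes the serialisation of states (`a:1 b:2 c:0 d:1`).
* Transition labels are unique and contiguous from 1 in file order; the
  facts writer serialises the origin inside the `condition/3` facts (one
  fact per element of {origin} ∪ condition plus one `target/3`), and the
  reader splits it back out as the condition element on the target's own
  automaton.
* All enumeration output is canonically ordered (states lexicographic,
  cycles by anchor then DFS order), so repeated runs and JSON exports are
  byte-identical.
* The synchronous update-set construction materialises the full Cartesian
  product over non-deterministic automata — exponential in the number of
  simultaneously conflicted automata, fine at desk scale.
* Cycle length `n = 0` is rejected with a pointer to the fixed-point
  search; steady states are handled by a dedicated, cheaper path.

## Known limitations

* Attractor enumeration is inherently exponential: cycle generation
  explores the closed-walk space and the covering-walk check is
  exponential in trace size. The tool targets exact desk-scale analysis
  and small attractors of larger models, not symbolic (BDD) scale.
* Only the two pure schemes are implemented; block-sequential or priority
  schemes are out of scope.
* Basins of attraction, gardens of Eden and model reduction are out of
  scope; GINML/SBML-qual import is delegated to external converters
  (see README).
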