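# antra

Exhaustive enumeration of **fixed points** and **attractors** in
multi-valued biological regulatory networks modelled as **automata
networks** (AN), under the non-deterministic **asynchronous** and
**synchronous** update schemes.

## Who this is for

Modellers of gene/protein regulatory networks who work with qualitative,
multi-valued logical models (Thomas-style networks, Boolean networks and
their multi-valued generalisations) and need the complete list of a
model's long-term behaviours: the steady states it can get stuck in and
the cyclic attractors it can oscillate in forever. Comparing these with
experimentally observed phenotypes is a standard way to validate or debug
a model.

## The model and the objects computed

An automata network is a triple (Σ, S, T): automata a ∈ Σ with local
states a_0 … a_k (discrete expression levels), and local transitions
a_i --ℓ--> a_j that move automaton a from level i to level j whenever the
condition ℓ — a set of local states of *other* automata, at most one per
automaton — holds. A global state ζ activates exactly one level per
automaton; P_ζ is the set of transitions playable in ζ.

* **Asynchronous scheme** U^asyn: one playable transition fires per step.
* **Synchronous scheme** U^syn: every automaton with a playable
  transition fires exactly one of them. Empty steps are forbidden, so no
  state is its own successor. The only synchronous non-determinism comes
  from *in-conflict* transitions (same origin, different destinations,
  jointly playable); Boolean models are therefore synchronous-deterministic.

The long-term structures:

* a **fixed point** is a state with P_ζ = ∅ (the same set under both
  schemes);
* an **attractor** is a minimal trap domain of ≥ 2 states — equivalently
  the trace of a cycle that is a trap domain, equivalently a non-singleton
  terminal SCC of the state-transition graph.

Attractors covered by a cycle of length n are found by a
generate-and-test enumeration: generate all length-n cycles, discard
those whose trace can be escaped, and keep only cycles whose length
equals the shortest closed walk covering their trace (so each attractor
is reported at its minimal covering length, including "star" attractors
whose covering walk is strictly longer than their trace: a length-n path
with k repeated visits covers n + 1 − k states). An independent
brute-force oracle (terminal SCCs of the explicit state-transition graph)
cross-checks every result.

## Worked example

The packaged four-component model (automata `a`, `c` Boolean, `b`, `d`
three-valued; 12 local transitions; 36 global states):

```python
>>> import antra
>>> net = antra.toy_model()
>>> for s in antra.enumerate_fixed_points(net): print(s)
a:0 b:0 c:0 d:1
a:1 b:1 c:0 d:0
a:1 b:1 c:1 d:0
>>> for a in antra.enumerate_all_attractors(net, 6, "asynchronous"):
...     print(a.size, a.cycle_length, [str(s) for s in a.states])
2 2 ['a:0 b:1 c:0 d:0', 'a:0 b:1 c:0 d:2']
4 4 ['a:0 b:2 c:1 d:0', 'a:0 b:2 c:1 d:1', 'a:1 b:2 c:1 d:0', 'a:1 b:2 c:1 d:1']
>>> for a in antra.enumerate_all_attractors(net, 6, "synchronous"):
...     print(a.size, a.cycle_length, [str(s) for s in a.states])
2 2 ['a:0 b:1 c:0 d:0', 'a:0 b:1 c:0 d:2']
2 2 ['a:0 b:2 c:1 d:0', 'a:1 b:2 c:1 d:1']
```

The model has three steady states (identical under both schemes), an
asynchronous attractor of size 2 and a complex one of size 4, and two
synchronous attractors of size 2. `size` is the number of distinct
states in the attractor; `cycle_length` the length of its shortest
covering cycle (for the packaged 4-state star system these differ:
size 4, cycle length 6, because the hub state must be revisited).

The same analyses from the shell:

```sh
antra fixed-points model.an
antra attractors model.an --scheme synchronous --length 2 --format json
antra attractors model.an --scheme asyn --length 6 --up-to
antra stg model.an --scheme asynchronous --format dot --color-attractors
antra facts model.an            # logic-facts rendering of the model
antra random-model --seed 7     # reproducible random AN
```

Models are plain text, either the `automaton`/`trans` format shown in
`src/antra/data/toy.an` or the facts dialect
(`automatonLevel/2`, `automaton/1`, `localTrans/1`, `condition/3`,
`target/3`).

## Literature models

Published multi-valued models (e.g. the T-helper differentiation or FGF
pathway networks) are distributed in GINML by the GINsim model
repository.  They are not packaged here; to analyse one, export it from
GINsim to SBML-qual, convert it to an automata-network description with
the bioLQM/LogicalModel toolchain, and write it in either text format
above (the conversions preserve the asynchronous dynamics).  At that
scale the fixed-point enumerator remains practical (it iterates the
prefiltered candidate product lazily), while full attractor enumeration
is bounded by the requested cycle length.
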