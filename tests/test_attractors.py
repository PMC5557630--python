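"""Paths, cycles, trap/minimality filters, attractor enumeration."""

import random

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antra import (
    AnDynamics,
    ModelError,
    Path,
    build_stg,
    enumerate_all_attractors,
    enumerate_attractors,
    enumerate_cycles,
    enumerate_fixed_points,
    is_minimal_cycle,
    is_trap_cycle,
    oracle_attractors,
    path_from_states,
    random_an,
    repetitions,
    shortest_covering_cycle_length,
    trace_size,
)
from conftest import random_sweep_cases


@pytest.fixture(scope="module")
def example_path(toy_net, example_path_states):
    return path_from_states(toy_net, example_path_states, "asynchronous")


class TestPath:
    def test_printed_path_is_valid_asynchronous(self, example_path):
        assert example_path.length == 6
        assert example_path.is_cycle
        assert example_path.played is not None and len(example_path.played) == 6

    def test_invalid_step_rejected(self, toy_net):
        good = toy_net.state(a=1, b=2, c=0, d=1)
        bad = toy_net.state(a=0, b=0, c=1, d=2)
        with pytest.raises(ModelError, match="not a successor"):
            path_from_states(toy_net, [good, bad], "asynchronous")

    def test_zero_length_rejected(self, toy_net):
        with pytest.raises(ModelError, match="positive length"):
            Path((toy_net.state(a=0, b=0, c=0, d=0),))


class TestRepetitionsAndTraceSize:
    def test_printed_path_repetitions(self, example_path):
        assert repetitions(example_path) == {2, 5, 6}
        assert trace_size(example_path) == 6 + 1 - 3 == 4

    def test_distinct_states_have_no_repetitions(self, toy_net):
        states = [
            toy_net.state(a=1, b=2, c=0, d=1),
            toy_net.state(a=1, b=2, c=0, d=0),
        ]
        p = path_from_states(toy_net, states, "asynchronous")
        assert repetitions(p) == frozenset()
        assert trace_size(p) == p.length + 1 == 2

    def test_two_cycle_repeats_once(self, toy_net):
        s, t = toy_net.state(a=1, b=2, c=0, d=1), toy_net.state(a=1, b=2, c=0, d=0)
        p = path_from_states(toy_net, [s, t, s], "asynchronous")
        assert repetitions(p) == {2}
        assert trace_size(p) == 2

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 12))
    def test_trace_size_formula_on_random_walks(self, toy_net, seed, n):
        """|trace| == n + 1 - |repetitions| on arbitrary random walks."""
        rng = random.Random(seed)
        dyn = AnDynamics(toy_net, "asynchronous")
        state = rng.choice(sorted(toy_net.states()))
        walk = [state]
        for _ in range(n):
            nxt = sorted(dyn.successors(walk[-1]))
            if not nxt:
                break
            walk.append(rng.choice(nxt))
        if len(walk) < 2:
            return
        p = path_from_states(toy_net, walk, "asynchronous")
        assert trace_size(p) == p.length + 1 - len(repetitions(p))


class TestEnumerateCycles:
    def test_no_self_loops_so_no_length_one_cycles(self, toy_net):
        for scheme in ("asynchronous", "synchronous"):
            assert list(enumerate_cycles(toy_net, 1, scheme)) == []

    def test_length_two_cycles_include_escapable_one(self, toy_net):
        target = {toy_net.state(a=1, b=2, c=0, d=1), toy_net.state(a=1, b=2, c=0, d=0)}
        traces = [set(p.states) for p in enumerate_cycles(toy_net, 2, "asynchronous")]
        assert target in traces

    def test_zero_length_rejected(self, toy_net):
        with pytest.raises(ValueError, match="fixed-point"):
            list(enumerate_cycles(toy_net, 0, "asynchronous"))

    @pytest.mark.parametrize("seed,n_auto,max_lv,n_tr", random_sweep_cases(12))
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_count_matches_closed_walk_oracle(self, seed, n_auto, max_lv, n_tr, n):
        """Cycle count equals the trace of the n-th adjacency-matrix power."""
        net = random_an(min(n_auto, 3), max_lv, n_tr, seed)  # keep graphs tiny
        stg = build_stg(net, "asynchronous")
        nodes = sorted(stg.graph.nodes)
        a = nx.to_numpy_array(stg.graph, nodelist=nodes, dtype=np.int64)
        expected = int(np.trace(np.linalg.matrix_power(a, n)))
        assert sum(1 for _ in enumerate_cycles(net, n, "asynchronous")) == expected


class TestTrapCycle:
    def test_escapable_two_cycle_is_not_trap(self, toy_net):
        s, t = toy_net.state(a=1, b=2, c=0, d=1), toy_net.state(a=1, b=2, c=0, d=0)
        p = path_from_states(toy_net, [s, t, s], "asynchronous")
        assert not is_trap_cycle(toy_net, p, "asynchronous")

    def test_size_four_cycle_is_trap(self, toy_net):
        states = [
            toy_net.state(a=0, b=2, c=1, d=0),
            toy_net.state(a=0, b=2, c=1, d=1),
            toy_net.state(a=1, b=2, c=1, d=1),
            toy_net.state(a=1, b=2, c=1, d=0),
            toy_net.state(a=0, b=2, c=1, d=0),
        ]
        p = path_from_states(toy_net, states, "asynchronous")
        assert is_trap_cycle(toy_net, p, "asynchronous")

    def test_size_two_attractor_is_trap_in_both_schemes(self, toy_net):
        s, t = toy_net.state(a=0, b=1, c=0, d=0), toy_net.state(a=0, b=1, c=0, d=2)
        for scheme in ("asynchronous", "synchronous"):
            p = path_from_states(toy_net, [s, t, s], scheme)
            assert is_trap_cycle(toy_net, p, scheme)

    def test_non_cycle_rejected(self, toy_net):
        s, t = toy_net.state(a=1, b=2, c=0, d=1), toy_net.state(a=1, b=2, c=0, d=0)
        p = path_from_states(toy_net, [s, t], "asynchronous")
        with pytest.raises(ModelError, match="cycle"):
            is_trap_cycle(toy_net, p, "asynchronous")


class TestMinimality:
    def test_repetition_free_covering_cycle_is_minimal(self, toy_net):
        states = [
            toy_net.state(a=0, b=2, c=1, d=0),
            toy_net.state(a=0, b=2, c=1, d=1),
            toy_net.state(a=1, b=2, c=1, d=1),
            toy_net.state(a=1, b=2, c=1, d=0),
            toy_net.state(a=0, b=2, c=1, d=0),
        ]
        p = path_from_states(toy_net, states, "asynchronous")
        assert is_minimal_cycle(toy_net, p, "asynchronous")

    def test_length_six_cover_of_size_four_trace_is_not_minimal(
        self, toy_net, example_path_states
    ):
        p = path_from_states(toy_net, example_path_states, "asynchronous")
        assert not is_minimal_cycle(toy_net, p, "asynchronous")
        assert shortest_covering_cycle_length(
            AnDynamics(toy_net, "asynchronous"), p.trace()
        ) == 4

    def test_thrice_repeated_two_cycle_is_not_minimal(self, toy_net):
        s, t = toy_net.state(a=0, b=1, c=0, d=0), toy_net.state(a=0, b=1, c=0, d=2)
        p = path_from_states(toy_net, [s, t, s, t, s, t, s], "asynchronous")
        assert is_trap_cycle(toy_net, p, "asynchronous")
        assert not is_minimal_cycle(toy_net, p, "asynchronous")

    def test_star_covering_cycle_of_length_six_is_minimal(self, star):
        p = path_from_states(star, ["s0", "s1", "s2", "s1", "s3", "s1", "s0"])
        assert is_trap_cycle(star, p)
        assert is_minimal_cycle(star, p)
        assert shortest_covering_cycle_length(star, ["s0", "s1", "s2", "s3"]) == 6


class TestEnumerateAttractors:
    def test_asynchronous_length_two(self, toy_net):
        found = enumerate_attractors(toy_net, 2, "asynchronous")
        assert [set(a.states) for a in found] == [
            {toy_net.state(a=0, b=1, c=0, d=0), toy_net.state(a=0, b=1, c=0, d=2)}
        ]

    def test_asynchronous_length_four(self, toy_net):
        found = enumerate_attractors(toy_net, 4, "asynchronous")
        assert [set(a.states) for a in found] == [
            {
                toy_net.state(a=0, b=2, c=1, d=0),
                toy_net.state(a=0, b=2, c=1, d=1),
                toy_net.state(a=1, b=2, c=1, d=1),
                toy_net.state(a=1, b=2, c=1, d=0),
            }
        ]

    @pytest.mark.parametrize("n", [1, 3, 5, 6, 7, 8])
    def test_asynchronous_other_lengths_empty(self, toy_net, n):
        assert enumerate_attractors(toy_net, n, "asynchronous") == []

    def test_synchronous_length_two(self, toy_net):
        found = enumerate_attractors(toy_net, 2, "synchronous")
        assert sorted(tuple(sorted(map(str, a.states))) for a in found) == sorted(
            [
                ("a:0 b:1 c:0 d:0", "a:0 b:1 c:0 d:2"),
                ("a:0 b:2 c:1 d:0", "a:1 b:2 c:1 d:1"),
            ]
        )

    def test_no_dedupe_reports_each_witnessing_cycle(self, toy_net):
        raw = enumerate_attractors(toy_net, 2, "asynchronous", dedupe=False)
        # the size-2 attractor is covered by one cycle per start state
        assert len(raw) == 2
        assert len({a.trace for a in raw}) == 1

    def test_zero_length_rejected(self, toy_net):
        with pytest.raises(ValueError, match="fixed-point"):
            enumerate_attractors(toy_net, 0, "asynchronous")


class TestEnumerateAllAttractors:
    def test_example_asynchronous_sizes(self, toy_net):
        found = enumerate_all_attractors(toy_net, 6, "asynchronous")
        assert sorted((a.size, a.cycle_length) for a in found) == [(2, 2), (4, 4)]

    def test_example_synchronous_sizes(self, toy_net):
        found = enumerate_all_attractors(toy_net, 6, "synchronous")
        assert sorted((a.size, a.cycle_length) for a in found) == [(2, 2), (2, 2)]

    def test_star_attractor_needs_length_six(self, star):
        found = enumerate_all_attractors(star, 6)
        assert [(a.size, a.cycle_length) for a in found] == [(4, 6)]
        for n in range(1, 6):
            assert enumerate_attractors(star, n) == []

    @pytest.mark.parametrize("seed,n_auto,max_lv,n_tr", random_sweep_cases(25))
    @pytest.mark.parametrize("scheme", ["asynchronous", "synchronous"])
    def test_completeness_against_terminal_scc_oracle(
        self, seed, n_auto, max_lv, n_tr, scheme
    ):
        net = random_an(n_auto, max_lv, n_tr, seed)
        fixed, expected = oracle_attractors(build_stg(net, scheme))
        dyn = AnDynamics(net, scheme)
        covers = [shortest_covering_cycle_length(dyn, tr) for tr in expected]
        max_n = max(covers, default=2)
        found = enumerate_all_attractors(net, max_n, scheme)
        assert {a.trace for a in found} == set(expected)
        # reported cycle lengths are the shortest covers
        by_trace = {a.trace: a.cycle_length for a in found}
        for tr, cov in zip(expected, covers):
            assert by_trace[tr] == cov


class TestAttractorInvariants:
    @pytest.mark.parametrize("scheme", ["asynchronous", "synchronous"])
    def test_soundness_trap_and_strongly_connected(self, toy_net, scheme):
        dyn = AnDynamics(toy_net, scheme)
        for a in enumerate_all_attractors(toy_net, 6, scheme):
            # closed under successors
            for s in a.trace:
                assert dyn.successors(s) <= a.trace
            # strongly connected
            g = nx.DiGraph(
                (s, t) for s in a.trace for t in dyn.successors(s)
            )
            assert nx.is_strongly_connected(g)

    def test_disjoint_from_fixed_points(self, toy_net):
        fps = set(enumerate_fixed_points(toy_net))
        for scheme in ("asynchronous", "synchronous"):
            for a in enumerate_all_attractors(toy_net, 6, scheme):
                assert a.size >= 2
                assert not (a.trace & fps)

    @pytest.mark.parametrize("scheme", ["asynchronous", "synchronous"])
    def test_trace_size_accounting_of_witness(self, toy_net, star, scheme):
        systems = [AnDynamics(toy_net, scheme), star]
        for system in systems:
            for a in enumerate_all_attractors(system, 6):
                w = a.witness
                assert a.size == w.length + 1 - len(repetitions(w))

    def test_boolean_synchronous_cycles_are_all_traps(self):
        """With Boolean automata and the synchronous scheme the dynamics is
        deterministic, so every cycle found is necessarily an attractor."""
        for seed in range(10):
            net = random_an(3, 2, 5, seed)
            for n in (1, 2, 3, 4):
                for cycle in enumerate_cycles(net, n, "synchronous"):
                    assert is_trap_cycle(net, cycle, "synchronous")
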