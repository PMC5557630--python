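import pytest

import antra


@pytest.fixture(scope="session")
def toy_net():
    """The packaged four-automaton example network."""
    return antra.toy_model()


@pytest.fixture(scope="session")
def star():
    """The four-state star transition system."""
    return antra.star_model()


@pytest.fixture(scope="session")
def example_path_states(toy_net):
    """The printed length-6 asynchronous path over the size-4 attractor."""
    return [
        toy_net.state(a=a, b=2, c=1, d=d)
        for a, d in [(1, 1), (0, 1), (1, 1), (1, 0), (0, 0), (0, 1), (1, 1)]
    ]


def random_sweep_cases(n=100):
    """Deterministic batch of random-network configurations.

    Sizes cycle through 2-5 automata, 2-3 levels, and between n and 2n
    transitions, so Boolean-only and multi-valued cases both occur.
    """
    cases = []
    for seed in range(n):
        n_auto = 2 + seed % 4
        max_lv = 2 + (seed // 4) % 2
        n_tr = n_auto + seed % (n_auto + 1)
        cases.append((seed, n_auto, max_lv, n_tr))
    return cases
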