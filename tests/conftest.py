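"""Shared fixtures: small nets with known behavior."""

import numpy as np
import pytest

from stochpn import PetriNet


@pytest.fixture
def chain_net():
    """A --> T1 --> B --> T2 --> C, all weights 1."""
    net = PetriNet()
    for p in "ABC":
        net.add_place(p)
    net.add_transition("T1")
    net.add_transition("T2")
    net.add_arc("A", "T1")
    net.add_arc("T1", "B")
    net.add_arc("B", "T2")
    net.add_arc("T2", "C")
    return net


@pytest.fixture
def conflict_net():
    """T1 and T2 compete for the single token pool on S."""
    net = PetriNet()
    net.add_place("S")
    net.add_place("X")
    net.add_place("Y")
    net.add_transition("T1")
    net.add_transition("T2")
    net.add_arc("S", "T1")
    net.add_arc("T1", "X")
    net.add_arc("S", "T2")
    net.add_arc("T2", "Y")
    return net


@pytest.fixture
def self_loop_net():
    """A --> T --> A: firing leaves the marking unchanged (always enabled)."""
    net = PetriNet()
    net.add_place("A")
    net.add_transition("T")
    net.add_arc("A", "T")
    net.add_arc("T", "A")
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_net(seed: int, n_places: int = 5, n_transitions: int = 5):
    """A random small net plus a random marking, for property tests."""
    r = np.random.default_rng(seed)
    net = PetriNet()
    places = [f"P{i}" for i in range(n_places)]
    for i, p in enumerate(places):
        net.add_place(p, constant=bool(i == 0 and r.random() < 0.3))
    for j in range(n_transitions):
        net.add_transition(f"T{j}")
    for j in range(n_transitions):
        for p in places:
            u = r.random()
            if u < 0.35:
                net.add_arc(p, f"T{j}", int(r.integers(1, 4)))
            elif u < 0.6:
                net.add_arc(f"T{j}", p, int(r.integers(1, 4)))
    marking = {p: int(r.integers(0, 10)) for p in places}
    return net, marking
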