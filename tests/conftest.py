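import itertools

import numpy as np
import pytest

from qgdm.hilbert_space import CompositeSpace, PureState, random_density
from qgdm.network_core import ProteinGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def qubit_space():
    return CompositeSpace(["a"], 2)


@pytest.fixture
def two_qubit_space():
    return CompositeSpace(["a", "b"], 2)


@pytest.fixture
def bell_state(two_qubit_space):
    amps = np.zeros(4, dtype=complex)
    amps[0] = amps[3] = 1 / np.sqrt(2)
    return PureState(two_qubit_space, amps)


@pytest.fixture
def plus_state(qubit_space):
    return PureState(qubit_space, np.array([1, 1]) / np.sqrt(2))


def random_graph(rng, n, p=0.5, weighted=True):
    """Erdos-Renyi helper used across module tests."""
    verts = [f"v{i}" for i in range(n)]
    weights = {}
    for a, b in itertools.combinations(verts, 2):
        if rng.random() < p:
            weights[(a, b)] = float(rng.uniform(0.2, 2.0)) if weighted else 1.0
    return ProteinGraph(verts, weights)


@pytest.fixture
def triangle():
    return ProteinGraph(
        ["a", "b", "c"], {("a", "b"): 1.0, ("b", "c"): 1.0, ("a", "c"): 1.0}
    )
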