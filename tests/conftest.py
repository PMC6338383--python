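import numpy as np
import pytest

from sympnet import SimulationConfig, SymptomNetwork, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (146 ADHD + 209 controls), fixed seed."""
    return generate_cohort(SimulationConfig(seed=20260929))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_network(weights, nodes=None) -> SymptomNetwork:
    """SymptomNetwork from a raw symmetric weight matrix."""
    w = np.asarray(weights, dtype=float)
    if nodes is None:
        nodes = tuple(chr(ord("A") + i) for i in range(len(w)))
    return SymptomNetwork(nodes=tuple(nodes), weights=w)


@pytest.fixture
def path_abc():
    """A - B - C chain with unit weights."""
    return toy_network([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
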