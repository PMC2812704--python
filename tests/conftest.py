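import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from carlm import (
    IndividualRecord,
    SimulationParams,
    WardGraph,
    make_lattice_graph,
    simulate_dataset,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=25,
)
settings.load_profile("ci")


@pytest.fixture
def path_graph():
    """A - B - C."""
    return WardGraph.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def cycle4_graph():
    return WardGraph.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture(scope="session")
def lattice_4x8():
    return make_lattice_graph(4, 8)


@pytest.fixture
def tiny_records():
    return [
        IndividualRecord("A", 69.5, 30.0, "male", "white_british"),
        IndividualRecord("A", 10.0, 25.0, "female", "black_african"),
        IndividualRecord("B", 200.0, 50.0, "female", "asian", "affective"),
    ]


@pytest.fixture(scope="session")
def simulated_32(lattice_4x8):
    """One default-condition synthetic dataset over the 32-ward lattice."""
    params = SimulationParams(seed=20_260_929)
    records, truth = simulate_dataset(lattice_4x8, params)
    return records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
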