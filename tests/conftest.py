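import pytest

from cappic import (
    InteractionNetwork,
    PlantedModuleSpec,
    generate_planted_network,
)


@pytest.fixture
def triangle():
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def two_triangles():
    return InteractionNetwork.from_edges(
        [("A", "B"), ("B", "C"), ("A", "C"),
         ("X", "Y"), ("Y", "Z"), ("X", "Z")]
    )


@pytest.fixture
def path3():
    """Path A-B-C-D (3 edges)."""
    return InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def star():
    return InteractionNetwork.from_edges(
        [("H", "A"), ("H", "B"), ("H", "C"), ("H", "D")]
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted-module network with full evidence labels and its
    ground-truth module map (session-scoped: generation is deterministic)."""
    spec = PlantedModuleSpec(evidence_high_fraction=1.0, seed=1)
    return generate_planted_network(spec)
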