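import pytest

from connmeta import CommunitySchemaRegistry, GeneratorConfig, build_store, generate


@pytest.fixture()
def registry():
    return CommunitySchemaRegistry()


SMALL_CONFIG = GeneratorConfig(
    seed=11, n_neurons=60, n_synapses=500, unassigned_layer_fraction=0.1
)


@pytest.fixture(scope="session")
def small_dataset():
    """A seeded desk-scale connectome: (config, store, ground_truth).

    Session-scoped and shared; tests must treat the store as read-only.
    """
    store, ground_truth = build_store(SMALL_CONFIG)
    return SMALL_CONFIG, store, ground_truth


@pytest.fixture(scope="session")
def small_metadata():
    """Typed metadata lists for the same seeded connectome."""
    neurons, synapses, layers, ground_truth = generate(SMALL_CONFIG)
    return neurons, synapses, layers, ground_truth
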