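"""Document store: CRUD, indexes, the eight endpoints, persistence."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmeta import (
    DuplicateIdError,
    ENDPOINT_NAMES,
    FilterParseError,
    FilterPredicate,
    MetadataStore,
    NotFoundError,
)
from connmeta.store import _sort_key
from helpers import store_with, toy_neuron, toy_synapse


def test_insert_then_get_roundtrips_documents():
    store = store_with(neurons=[toy_neuron(n) for n in (1, 2, 3)])
    for n in (1, 2, 3):
        record = store.get_neuron(n)
        assert record.entity_id == str(n)
        assert record.get("neuron_id") == n


def test_duplicate_id_rejected_and_store_unchanged():
    store = store_with(neurons=[toy_neuron(1)])
    before = store.count("neuron")
    with pytest.raises(DuplicateIdError):
        store.insert(toy_neuron(1).to_record("toy"))
    assert store.count("neuron") == before


def test_unknown_id_raises_not_found_distinct_from_empty_filter():
    store = store_with(neurons=[toy_neuron(1)])
    with pytest.raises(NotFoundError):
        store.get_neuron(99)
    # an empty filter result is just an empty list, never an exception
    assert store.list_neurons(FilterPredicate.equals(layer=6)) == []


def test_neuron_synapses_requires_the_neuron_to_exist():
    store = store_with()
    with pytest.raises(NotFoundError):
        store.neuron_synapses(1, "both")


def test_neuron_synapses_directions_partition_attachments():
    synapses = [
        toy_synapse("a", pre=1, post=2),
        toy_synapse("b", pre=2, post=1),
        toy_synapse("c", pre=1, post=3),
    ]
    store = store_with(neurons=[toy_neuron(n) for n in (1, 2, 3)], synapses=synapses)
    outgoing = {r.entity_id for r in store.neuron_synapses(1, "outgoing")}
    incoming = {r.entity_id for r in store.neuron_synapses(1, "incoming")}
    both = {r.entity_id for r in store.neuron_synapses(1, "both")}
    assert outgoing == {"a", "c"}
    assert incoming == {"b"}
    assert both == outgoing | incoming


def test_endpoint_surface_is_exactly_eight_operations():
    store = store_with()
    assert store.endpoints() == ENDPOINT_NAMES
    assert len(set(ENDPOINT_NAMES)) == 8
    for name in ENDPOINT_NAMES:
        assert callable(getattr(store, name))


def test_list_layers_returns_seven_records(small_dataset):
    _, store, _ = small_dataset
    layers = store.list_layers()
    assert len(layers) == 7
    assert [r.get("layer_id") for r in layers] == list(range(1, 8))


def test_indexed_layer_tallies_match_full_scan(small_dataset):
    _, store, _ = small_dataset
    for layer in range(1, 8):
        pred = FilterPredicate.equals(layer=layer)
        assert store.list_synapses(pred) == store.scan("synapse", pred)


def test_filtered_listing_equals_brute_force_scan(small_dataset):
    _, store, _ = small_dataset
    pred = FilterPredicate.from_items(
        [("synapse_type", "eq", "excitatory"), ("layer", "eq", 2)]
    )
    via_index = store.list_synapses(pred)
    docs = store.documents("synapse")
    expected = [
        d["entity_id"]
        for d in docs
        if d.get("synapse_type") == "excitatory" and d.get("layer") == 2
    ]
    assert [r.entity_id for r in via_index] == sorted(expected, key=_sort_key)
    assert len(via_index) > 0  # the seeded dataset populates layer 2


_CLAUSES = st.lists(
    st.one_of(
        st.tuples(st.just("layer"), st.sampled_from(["eq", "le", "ge", "lt", "gt"]),
                  st.integers(0, 8)),
        st.tuples(st.just("synapse_type"), st.just("eq"),
                  st.sampled_from(["excitatory", "inhibitory", "unknown"])),
        st.tuples(st.just("postsynaptic_partner.compartment"), st.just("eq"),
                  st.sampled_from(["dendrite_shaft", "dendritic_spine", "soma",
                                   "axon_initial_segment"])),
        st.tuples(st.just("postsynaptic_partner.neuron_id"), st.just("in"),
                  st.lists(st.integers(1, 60), max_size=5).map(tuple)),
    ),
    max_size=3,
)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(clauses=_CLAUSES)
def test_indexed_evaluation_equals_exhaustive_scan(small_dataset, clauses):
    """For every predicate, index-accelerated find == index-free scan."""
    _, store, _ = small_dataset
    pred = FilterPredicate.from_items(clauses)
    assert store.list_synapses(pred) == store.scan("synapse", pred)


def test_unknown_comparator_rejected_at_parse_time():
    with pytest.raises(FilterParseError):
        FilterPredicate.from_items([("layer", "regex", ".*")])


def test_list_results_are_stably_ordered(small_dataset):
    _, store, _ = small_dataset
    ids = [r.entity_id for r in store.list_synapses()]
    assert ids == sorted(ids, key=_sort_key)
    ids = [r.entity_id for r in store.list_neurons()]
    assert ids == sorted(ids, key=_sort_key)


def test_summary_conserves_totals(small_dataset):
    _, store, _ = small_dataset
    s = store.summary()
    assert sum(s.synapses_per_layer.values()) + s.synapses_unassigned_layer == s.counts["synapse"]
    assert sum(s.neurons_per_layer.values()) + s.neurons_unassigned_layer == s.counts["neuron"]
    assert s.counts["layer"] == 7


def test_save_load_roundtrip_preserves_collections(small_dataset, tmp_path):
    _, store, _ = small_dataset
    store.save(tmp_path)
    loaded = MetadataStore.load(tmp_path)
    assert loaded.dataset_id == store.dataset_id
    for cls in ("neuron", "synapse", "layer"):
        assert loaded.records(cls) == store.records(cls)
    assert loaded.summary() == store.summary()


def test_user_collection_and_schema_survive_persistence(tmp_path):
    from connmeta import EntityRecord, PropertyValue, Uri

    store = store_with()
    store.registry.register("mitochondrion", [("parent_neuron", "integer")])
    record = EntityRecord(
        entity_id="m1",
        entity_class="mitochondrion",
        uri=Uri("toy/mitochondria/m1"),
        representation="mesh",
        dataset_id="toy",
        properties={"parent_neuron": PropertyValue("parent_neuron", 3)},
    )
    store.insert(record)
    store.save(tmp_path)
    loaded = MetadataStore.load(tmp_path)
    assert loaded.records("mitochondrion") == [record]
    assert "mitochondrion" in loaded.registry.user_classes
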