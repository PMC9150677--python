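"""Entity model, community-schema validation, and derived quantities."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmeta import (
    EntityRecord,
    NeuronMetadata,
    PropertyOrigin,
    PropertyValue,
    SchemaError,
    UnknownClassError,
    Uri,
    compute_ei_balance,
    compute_spinyness,
    derive_neuron_aggregates,
    register_entity_class,
    validate_entity,
)
from helpers import toy_neuron, toy_synapse


# -- derived quantities ------------------------------------------------------


@pytest.mark.parametrize(
    "e, i, expected",
    [(3, 1, 0.75), (0, 5, 0.0), (5, 0, 1.0), (0, 0, None)],
)
def test_ei_balance_is_excitatory_fraction(e, i, expected):
    assert compute_ei_balance(e, i) == expected


@pytest.mark.parametrize(
    "spine, dendrite, expected",
    [(5, 10, 0.5), (0, 10, 0.0), (3, 0, None)],
)
def test_spinyness_is_spine_node_fraction(spine, dendrite, expected):
    assert compute_spinyness(spine, dendrite) == expected


@pytest.mark.parametrize("func", [compute_ei_balance, compute_spinyness])
def test_negative_counts_rejected(func):
    with pytest.raises(ValueError):
        func(-1, 3)
    with pytest.raises(ValueError):
        func(3, -1)


@settings(derandomize=True, max_examples=200)
@given(e=st.integers(0, 10_000), i=st.integers(0, 10_000))
def test_defined_balance_always_in_unit_interval(e, i):
    balance = compute_ei_balance(e, i)
    if e + i == 0:
        assert balance is None
    else:
        assert 0.0 <= balance <= 1.0
        assert abs(balance - e / (e + i)) <= 1e-12


# -- uri / primitive invariants ----------------------------------------------


@pytest.mark.parametrize("value", ["https://example.org/x", "h01/neurons/42", "urn:x-y:z"])
def test_uri_accepts_schemes_and_dataset_local_ids(value):
    assert str(Uri(value)) == value


@pytest.mark.parametrize("value", ["", "no spaces here", "just-one-segment"])
def test_uri_rejects_malformed_locators(value):
    with pytest.raises(SchemaError):
        Uri(value)


# -- validation ----------------------------------------------------------------


def test_full_synapse_record_is_valid(registry):
    record = toy_synapse("s1", pre=1, post=2, layer=3).to_record("toy")
    report = validate_entity(record, registry)
    assert report.valid
    assert report.errors == ()


def test_missing_required_synapse_type_is_named(registry):
    record = toy_synapse("s1", pre=1, post=2).to_record("toy")
    props = {k: v for k, v in record.properties.items() if k != "synapse_type"}
    broken = dataclasses.replace(record, properties=props)
    report = validate_entity(broken, registry)
    assert not report.valid
    assert len(report.errors) == 1
    assert report.errors[0].property_key == "synapse_type"


def test_unknown_extra_key_is_warning_not_error(registry):
    record = toy_synapse("s1", pre=1, post=2).to_record("toy")
    props = dict(record.properties)
    props["my_note"] = PropertyValue("my_note", "check this one", PropertyOrigin.USER)
    extended = dataclasses.replace(record, properties=props)
    report = validate_entity(extended, registry)
    assert report.valid
    assert any(w.property_key == "my_note" for w in report.warnings)


def test_location_outside_bounding_box_is_error(registry):
    syn = toy_synapse("s1", pre=1, post=2)
    bad = dataclasses.replace(syn, location=(999, 999, 999), bounding_box=syn.bounding_box)
    report = validate_entity(bad.to_record("toy"), registry)
    assert not report.valid
    assert any(i.property_key == "location" for i in report.errors)


def test_inverted_bounding_box_is_error(registry):
    syn = toy_synapse("s1", pre=1, post=2)
    lo, hi = syn.bounding_box
    bad = dataclasses.replace(syn, bounding_box=(hi, lo))
    report = validate_entity(bad.to_record("toy"), registry)
    assert not report.valid
    assert any(i.property_key == "bounding_box" for i in report.errors)


def test_stored_balance_conflicting_with_counts_warns_but_passes(registry):
    neuron = dataclasses.replace(toy_neuron(1, e=3, i=1), ei_balance=0.5)
    report = validate_entity(neuron.to_record("toy"), registry)
    assert report.valid
    assert any(w.property_key == "ei_balance" for w in report.warnings)


def test_incoming_fewer_than_classified_is_error(registry):
    neuron = dataclasses.replace(toy_neuron(1, e=3, i=2), n_incoming_synapses=4)
    report = validate_entity(neuron.to_record("toy"), registry)
    assert not report.valid


def test_unclassified_incoming_synapses_are_allowed(registry):
    # incoming may exceed E + I: some synapses have no polarity call
    neuron = toy_neuron(1, e=3, i=1, incoming=6)
    assert validate_entity(neuron.to_record("toy"), registry).valid


def test_unregistered_class_raises_distinct_error(registry):
    record = EntityRecord(
        entity_id="v1",
        entity_class="blood_vessel",
        uri=Uri("toy/blood_vessels/v1"),
        representation="mesh",
        dataset_id="toy",
        properties={"radius": PropertyValue("radius", 5)},
    )
    with pytest.raises(UnknownClassError):
        validate_entity(record, registry)


def test_user_defined_class_extension(registry):
    register_entity_class("blood_vessel", [("radius", "integer")], [], registry)
    record = EntityRecord(
        entity_id="v1",
        entity_class="blood_vessel",
        uri=Uri("toy/blood_vessels/v1"),
        representation="mesh",
        dataset_id="toy",
        properties={"radius": PropertyValue("radius", 5)},
    )
    assert validate_entity(record, registry).valid
    # a conforming record without the required key is invalid
    bare = dataclasses.replace(record, properties={})
    assert not validate_entity(bare, registry).valid


def test_community_classes_cannot_be_redefined(registry):
    with pytest.raises(SchemaError):
        register_entity_class("neuron", [("anything", "integer")], [], registry)


def test_validation_is_idempotent(registry, small_dataset):
    _, store, _ = small_dataset
    for record in store.records("neuron")[:10] + store.records("synapse")[:10]:
        first = validate_entity(record, registry)
        second = validate_entity(record, registry)
        assert first == second


def test_roundtripped_record_revalidates_identically(registry, small_dataset):
    _, store, _ = small_dataset
    for cls in ("neuron", "synapse", "layer"):
        for record in store.records(cls)[:15]:
            revived = EntityRecord.from_document(record.to_document(), registry)
            assert revived == record
            assert validate_entity(revived, registry) == validate_entity(record, registry)


# -- aggregate derivation -------------------------------------------------------


def test_aggregates_on_hand_counted_toy_table():
    synapses = [
        toy_synapse("s1", pre=1, post=42, stype="excitatory"),
        toy_synapse("s2", pre=2, post=42, stype="excitatory"),
        toy_synapse("s3", pre=3, post=42, stype="inhibitory"),
        toy_synapse("s4", pre=42, post=1),
        toy_synapse("s5", pre=42, post=2),
        toy_synapse("s6", pre=42, post=3),
    ]
    agg = derive_neuron_aggregates(42, synapses)
    assert (agg.n_outgoing, agg.n_incoming) == (3, 3)
    assert (agg.n_incoming_excitatory, agg.n_incoming_inhibitory) == (2, 1)
    assert agg.ei_balance == pytest.approx(2 / 3)


def test_aggregates_over_empty_collection_are_zero_with_undefined_balance():
    agg = derive_neuron_aggregates(1, [])
    assert (agg.n_outgoing, agg.n_incoming, agg.n_incoming_excitatory,
            agg.n_incoming_inhibitory) == (0, 0, 0, 0)
    assert agg.ei_balance is None


def test_generated_stored_aggregates_match_full_scan(small_metadata):
    """Dual route: the generator's stored fields vs an independent linear scan."""
    neurons, synapses, _, _ = small_metadata
    for neuron in neurons:
        agg = derive_neuron_aggregates(neuron.neuron_id, synapses)
        assert agg.n_outgoing == neuron.n_outgoing_synapses
        assert agg.n_incoming == neuron.n_incoming_synapses
        assert agg.n_incoming_excitatory == neuron.n_incoming_excitatory
        assert agg.n_incoming_inhibitory == neuron.n_incoming_inhibitory
        if agg.ei_balance is None:
            assert neuron.ei_balance is None
        else:
            assert neuron.ei_balance == pytest.approx(agg.ei_balance, abs=1e-12)


def test_aggregate_conservation_over_all_neurons(small_metadata):
    neurons, synapses, _, _ = small_metadata
    ids = {n.neuron_id for n in neurons}
    total_out = sum(
        derive_neuron_aggregates(nid, synapses).n_outgoing for nid in sorted(ids)
    )
    total_in = sum(
        derive_neuron_aggregates(nid, synapses).n_incoming for nid in sorted(ids)
    )
    n_pre_known = sum(1 for s in synapses if s.presynaptic_site.neuron_id in ids)
    n_post_known = sum(1 for s in synapses if s.postsynaptic_partner.neuron_id in ids)
    assert total_out == n_pre_known
    assert total_in == n_post_known
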