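"""Build typed neuron/synapse documents and validate them against the
community schemas, including a user-defined entity class."""

import dataclasses

from connmeta import (
    CommunitySchemaRegistry,
    EntityRecord,
    NeuronMetadata,
    PostsynapticPartner,
    PropertyValue,
    SynapseMetadata,
    SynapticSite,
    Uri,
    compute_ei_balance,
    compute_spinyness,
    validate_entity,
)

registry = CommunitySchemaRegistry()

# A neuron with 3 excitatory and 1 inhibitory incoming synapses; its derived
# fields (spinyness, E/(E+I) balance) must be consistent with the raw counts.
neuron = NeuronMetadata(
    neuron_id=42,
    volume=5_000_000,
    n_incoming_synapses=4,
    n_incoming_excitatory=3,
    n_incoming_inhibitory=1,
    n_dendrite_skeleton_nodes=120,
    n_dendritic_spine_skeleton_nodes=30,
    neuron_type=1,  # pyramidal in the default code table
    layer=3,
    spinyness=compute_spinyness(30, 120),
    ei_balance=compute_ei_balance(3, 1),
)
report = validate_entity(neuron.to_record("demo"), registry)
print(f"neuron 42 valid={report.valid}  balance={neuron.ei_balance}  "
      f"spinyness={neuron.spinyness}")
# balance 0.75 = 3/(3+1); spinyness 0.25 = spine nodes / dendrite nodes.

synapse = SynapseMetadata(
    synapse_id="syn-0001",
    synapse_type="excitatory",
    presynaptic_site=SynapticSite(neuron_id=42, class_type=1),
    postsynaptic_partner=PostsynapticPartner(
        neuron_id=7, class_type=2, compartment="dendritic_spine"
    ),
    location=(100, 2000, 40),
    bounding_box=((95, 1995, 35), (105, 2005, 45)),
    layer=3,
)
record = synapse.to_record("demo")
print(f"synapse valid={validate_entity(record, registry).valid}  "
      f"slots={len(record.properties)}")  # the seven synapse attribute slots

# Dropping a required slot is an error that names the missing property.
broken = dataclasses.replace(
    record,
    properties={k: v for k, v in record.properties.items() if k != "synapse_type"},
)
bad = validate_entity(broken, registry)
print(f"without synapse_type: valid={bad.valid}  "
      f"error on {bad.errors[0].property_key!r}")

# Data owners can register their own entity classes with required properties.
registry.register("blood_vessel", required=[("radius", "integer")])
vessel = EntityRecord(
    entity_id="v1",
    entity_class="blood_vessel",
    uri=Uri("demo/blood_vessels/v1"),
    representation="mesh",
    dataset_id="demo",
    properties={"radius": PropertyValue("radius", 5)},
)
print(f"user-defined blood_vessel valid={validate_entity(vessel, registry).valid}")
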