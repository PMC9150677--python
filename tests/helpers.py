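"""Hand-buildable toy entities for unit tests."""

from typing import Iterable, Optional, Sequence, Tuple

from connmeta import (
    LayerMetadata,
    MetadataStore,
    NeuronMetadata,
    PostsynapticPartner,
    SynapseMetadata,
    SynapticSite,
    compute_ei_balance,
    compute_spinyness,
)


def toy_neuron(
    nid: int,
    e: int = 0,
    i: int = 0,
    incoming: Optional[int] = None,
    outgoing: int = 0,
    layer: Optional[int] = None,
    dendrite: int = 0,
    spine: int = 0,
    axon: int = 0,
    neuron_type: int = 1,
    volume: int = 1000,
) -> NeuronMetadata:
    """Neuron whose derived fields are consistent with its counts."""
    return NeuronMetadata(
        neuron_id=nid,
        volume=volume,
        n_outgoing_synapses=outgoing,
        n_incoming_synapses=e + i if incoming is None else incoming,
        n_incoming_excitatory=e,
        n_incoming_inhibitory=i,
        n_dendrite_skeleton_nodes=dendrite,
        n_axon_skeleton_nodes=axon,
        n_dendritic_spine_skeleton_nodes=spine,
        neuron_type=neuron_type,
        spinyness=compute_spinyness(spine, dendrite),
        layer=layer,
        ei_balance=compute_ei_balance(e, i),
    )


def toy_synapse(
    sid: str,
    pre: int,
    post: int,
    stype: str = "excitatory",
    compartment: str = "dendrite_shaft",
    layer: Optional[int] = None,
    location: Tuple[int, int, int] = (10, 10, 10),
) -> SynapseMetadata:
    loc = tuple(location)
    bbox = (tuple(c - 2 for c in loc), tuple(c + 3 for c in loc))
    return SynapseMetadata(
        synapse_id=sid,
        synapse_type=stype,
        presynaptic_site=SynapticSite(pre),
        postsynaptic_partner=PostsynapticPartner(post, compartment=compartment),
        location=loc,
        bounding_box=bbox,
        layer=layer,
    )


def store_with(
    neurons: Iterable[NeuronMetadata] = (),
    synapses: Iterable[SynapseMetadata] = (),
    layers: Optional[Sequence[LayerMetadata]] = None,
    dataset_id: str = "toy",
) -> MetadataStore:
    """Store preloaded with all seven layers plus the given entities."""
    store = MetadataStore(dataset_id)
    if layers is None:
        layers = [LayerMetadata(k, 100_000 * k) for k in range(1, 8)]
    for layer in layers:
        store.insert(layer.to_record(dataset_id))
    for neuron in neurons:
        store.insert(neuron.to_record(dataset_id))
    for synapse in synapses:
        store.insert(synapse.to_record(dataset_id))
    return store
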