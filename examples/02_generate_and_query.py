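"""Generate a seeded synthetic connectome, load it into the metadata store,
and answer portal questions — cross-checked against the exact ground truth."""

from connmeta import (
    GeneratorConfig,
    Location,
    QuestionInstance,
    SynapseTypeSelector,
    WHOLE_VOLUME,
    answer,
    build_store,
    ground_truth_answer,
    q1_count_synapses,
    q2_layer_extremum,
    q5_top_neuron,
)

config = GeneratorConfig(seed=20, n_neurons=200, n_synapses=2000)
store, ground_truth = build_store(config)
print(f"dataset {store.dataset_id!r}: {store.summary().counts}")

# Q1: how many excitatory synapses are made in layer 3?
n = q1_count_synapses(store, SynapseTypeSelector.EXCITATORY, Location(3))
print(f"excitatory synapses in layer 3: {n}")

# Q2: which layer has the most synapses overall?
layer, count = q2_layer_extremum(store, "most", SynapseTypeSelector.ALL)
print(f"layer with most synapses: layer {layer} ({count} synapses)")

# Q5: the neuron receiving the most inhibitory input anywhere in the volume.
neuron_id, count = q5_top_neuron(store, SynapseTypeSelector.INHIBITORY, WHOLE_VOLUME)
print(f"top inhibitory target: neuron {neuron_id} ({count} incoming)")

# Every answer agrees with the generator's exact tallies:
question = QuestionInstance(
    "Q1", type_sel=SynapseTypeSelector.EXCITATORY, location=Location(3)
)
engine = answer(store, question)
oracle = ground_truth_answer(ground_truth, question)
print(f"engine={engine.value}  ground_truth={oracle.value}  "
      f"agree={engine.value == oracle.value}")
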