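# connmeta

Standardized annotation **metadata** for nanoscale connectomics datasets:
typed, validated documents for neurons, synapses and cortical layers, a
queryable document store, and the discovery-portal question catalog —
exercised end-to-end on a seeded synthetic connectome with exact ground
truth.

## Who this is for

Electron-microscopy and X-ray-microtomography connectomes annotate
neuroanatomical entities with key-value metadata: synapse counts, polarity,
layer membership, skeleton-node counts, cell types.  Raw annotation formats
(segmentations, meshes, skeletons) vary between labs; the metadata layer is
where standardization pays off.  `connmeta` implements a RAMON-lineage
standard for that layer, for tool builders and analysts who want to
validate, store, exchange and query entity metadata without touching raw
annotations.

## The model

Every entity is a document with a URI, a data representation (skeleton /
mesh / pixels / table / none), links to related entities, and an open
key-value property map.  Three **community-defined** classes carry a
minimum required property set:

- **neuron** — 16 attribute slots: id, volume, outgoing/incoming synapse
  tallies, incoming excitatory (E) and inhibitory (I) counts, six
  per-compartment skeleton-node counts, spinyness, layer, type, and the
  synapse balance **E/(E+I) ∈ [0, 1]** (undefined when E + I = 0);
- **synapse** — 7 slots: id, polarity, pre-synaptic site and post-synaptic
  partner sub-documents (neuron id, class type, target compartment), voxel
  location, half-open bounding box, layer;
- **layer** — one required attribute beyond its identifier: width (nm).

Spinyness is the ratio of dendritic-spine skeleton nodes to dendrite
skeleton nodes.  **User-defined** classes (e.g. `blood_vessel`) are
registered with their own required properties and never shadow the
community classes.  Validation yields a structured report: missing or
mistyped required properties are errors, unknown extra keys are warnings.

The store exposes exactly **eight retrieval endpoints** (get/list for each
of the three classes, per-neuron synapse lookup, dataset summary), and the
query layer enumerates the portal's **seven question templates** — synapse
counts, layer extrema, layer widths, neuron lengths, top synaptic targets,
and balance searches — over 4 synapse-type selectors × 8 locations (whole
volume + layers 1–7), a catalog of exactly **119 questions**.

## Worked example

```python
from connmeta import (GeneratorConfig, Location, SynapseTypeSelector,
                      build_store, q1_count_synapses, q2_layer_extremum)

config = GeneratorConfig(seed=20, n_neurons=200, n_synapses=2000)
store, ground_truth = build_store(config)
print(q1_count_synapses(store, SynapseTypeSelector.EXCITATORY, Location(3)))
print(q2_layer_extremum(store, "most", SynapseTypeSelector.ALL))
```

prints

```
285
(6, 409)
```

— 285 excitatory synapses carry a layer-3 assignment in this seeded
volume, and layer 6 holds the most synapses overall (409).  Both numbers
are exact tallies and agree with the generator's ground truth
(`ground_truth_answer` re-derives them from the emission bookkeeping
alone).  The `examples/` directory walks through validation, generation
and querying, catalog sweeps, and tabular round-trips; the same
functionality is scriptable via the `connmeta` CLI
(`generate`, `import`, `validate`, `query`, `endpoints`, `summary`):

```sh
connmeta generate --seed 9 --out data/
connmeta query Q1 --type all --location whole_volume --data data/
connmeta endpoints
```

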