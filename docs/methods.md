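# Methods

## Entity model

Entities are documents: a reserved envelope (`entity_id`, `entity_class`,
`uri`, `representation`, `links`, `dataset_id`) plus an open key-value
property map.  A URI is either a full `scheme:rest` locator or a
dataset-local `<dataset>/<collection>/<id>` identifier.  Links come from a
closed relation vocabulary (parent/child/sibling, pre/post-synaptic
neuron, member-of-layer).  Properties record their origin — *community*
(part of the class's adopted schema) or *user* (data-owner extension).

The community registry pre-registers the three classes with their minimum
required properties; the neuron schema carries 16 attribute slots, the
synapse schema 7, the layer schema one required attribute beyond its
identifier.  User classes are registered at run time and can never shadow
or redefine a community class.

### Validation semantics

`validate_entity` returns a report, not a boolean: every violation is
listed with a severity and the offending property key.

- Missing or mistyped required properties, out-of-range values (layer
  outside 1..7, balance or spinyness outside [0, 1], negative counts),
  inverted bounding boxes, and locations outside their box are **errors**.
- Extra keys unknown to the schema are **warnings** — the standard is
  extensible by design.
- A stored E/(E+I) balance (or spinyness) that disagrees with the value
  recomputed from the raw counts by more than 1e-9 is a **warning**:
  dataset-provided values are treated as authoritative, but the
  discrepancy is surfaced.
- Incoming synapse count may exceed E + I: synapses without a polarity
  call are legitimate.  Consequently the synapse polarity vocabulary
  admits `unknown` alongside `excitatory`/`inhibitory` (disk code 0 in
  the default code table); the excitatory/inhibitory query selectors
  never match it.  The default generator emits no unclassified synapses.
- Balance and spinyness are undefined exactly when their denominators are
  zero; undefined means an absent key on disk and `None` in memory, never
  a sentinel number.

Integer code tables (synapse polarity, neuron type, postsynaptic
compartment) apply only at the tabular import/export boundary and are
config-overridable; the canonical JSON Lines format stores symbols, which
keeps documents self-describing.

### Derived quantities

- **E/(E+I) balance**: excitatory fraction of classified incoming
  synapses, in [0, 1].
- **Spinyness**: dendritic-spine skeleton nodes / dendrite skeleton
  nodes.  The attribute is stored alongside the raw counts; this ratio is
  the definition used throughout.
- **Neuron aggregates**: exact outgoing/incoming/E/I tallies recomputed
  by a linear scan of the synapse collection (outgoing = presynaptic
  matches, incoming = postsynaptic matches).

## Store and retrieval surface

The reference backend is an in-memory collection per entity class with
JSON Lines persistence plus a dataset header (dataset id, voxel
resolution, code tables, user schemas).  Secondary hash indexes cover the
keys queries touch: layer, polarity, postsynaptic compartment, and the
pre/post partner neuron ids.  Index-accelerated filtering is an
optimization only — equality clauses narrow the candidate set, then the
full predicate is applied — and is property-tested equal to an index-free
scan.  All list results are stably ordered by entity id (numeric ids sort
numerically).  A missing id raises a not-found error, deliberately
distinct from an empty filter result.

The retrieval surface is exactly eight operations: `get_neuron`,
`list_neurons`, `get_synapse`, `list_synapses`, `get_layer`,
`list_layers`, `neuron_synapses` (incoming/outgoing/both via the partner
indexes), and `summary`.  The split into these eight is this package's
reading of an eight-endpoint portal API; alternatives (e.g. separate
incoming/outgoing endpoints) would be equally consistent.

## Question templates and catalog

Default dropdown domains: 4 synapse-type selectors (`all`, `excitatory`,
`inhibitory`, `onto_axon_initial_segment`) and 8 locations (whole volume,
layers 1–7).  The four-member selector domain is the only reading under
which the catalog totals 119 (a five-member domain, e.g. with a separate
onto-dendrite selector, gives 137); dendrite-targeted filtering remains
available off-catalog through filter predicates on
`postsynaptic_partner.compartment`.  Per template:

| template | free slots | instances |
|---|---|---|
| Q1 count synapses | type × location | 32 |
| Q2 layer extremum | most/fewest × type | 8 |
| Q3 layer width | layer | 7 |
| Q4 neuron length | average/total × location | 16 |
| Q5 top synaptic target | type × location | 32 |
| Q6 neuron by balance | location (+ free value) | 8 |
| Q7 neurons above/below balance | greater/less × location (+ free value) | 16 |

Total 119.  Q6/Q7 carry a numeric slot in [0, 1] supplied at ask time
(`QuestionInstance.bind`); each discrete combination counts once.

Conventions, applied uniformly: membership of a neuron or synapse in a
layer is its stored `layer` attribute (not bounding-box geometry); the
whole volume includes entities with an undefined layer, so per-layer
counts plus the unassigned count partition the whole-volume count; all
ties break to the lowest id; aggregates over empty sets are undefined,
not zero; Q5 counts *incoming* synapses tallied from the synapse
collection, never from stored aggregate fields; Q7 inequalities are
strict, and neurons with undefined balance are excluded from Q6/Q7.
"Neuron length" has no standard definition at the metadata level; it is
proxied as the sum of the six per-compartment skeleton-node counts times
a configurable inter-node spacing (default 1.0), i.e. a node-count proxy,
not a geometric path length.

## Synthetic connectome generator

The generator emulates the annotation structure of a human-cortex-scale
EM volume at desk scale so that every rule and query has a hermetic,
exactly-known oracle.  Defaults: 500 neurons, 5,000 synapses, seven
layers stacked along the y (depth) axis with widths
(160, 300, 360, 300, 240, 420, 220) µm summing to 2 mm of depth at
8 × 8 × 33 nm voxel resolution; 80% excitatory synapses (the cortical
excitatory majority); postsynaptic compartments 55% dendrite shaft, 32%
dendritic spine, 8% soma, 5% axon initial segment; neuron types 55%
pyramidal, 30% interneuron, 10% glia, 5% unclassified; 5% of synapses
left without a layer assignment to exercise whole-volume vs per-layer
bookkeeping; per-compartment skeleton-node counts uniform in fixed ranges
with spine nodes drawn as a sub-fraction of dendrite nodes so spinyness
stays in [0, 1].

Mechanics: one `numpy` generator seeded from the config, so identical
configs give identical documents and ground truth.  Synapse partners are
drawn uniformly over distinct neuron pairs (no self-synapses, no
distance-dependent connectivity).  A synapse's layer attribute is the
layer containing its location's depth coordinate unless it falls in the
unassigned fraction.  Bounding boxes are small half-open boxes guaranteed
to contain their location.  Neuron aggregate fields are filled from the
exact tallies of the emitted synapse table, so 100% of generated
documents validate with zero errors.  Infeasible configs (widths
exceeding the volume depth, probabilities not summing to 1, synapses
without at least two neurons) are rejected up front.

The `GroundTruth` object is produced by a direct pass over the emitted
metadata — per-(selector, location) synapse counts, per-neuron tallies,
per-layer neuron lists, layer widths — and `ground_truth_answer` answers
any catalog question from those tallies alone, never touching a store or
index.  Engine-vs-oracle equivalence over the full catalog is checked on
multiple seeds.

What the generator does **not** emulate: morphology, spatial synapse
clustering, realistic degree distributions, connection reciprocity, or
layer-dependent cell composition.  Passing tests therefore demonstrate
the correctness of the metadata standard, store and query machinery on
structurally faithful data — not biological conclusions about any real
volume.

## Interchange

Canonical form: JSON Lines, UTF-8, snake_case keys, one document per
line; undefined values are absent keys.  Reading revives geometric
vectors to tuples so round-trips compare field-for-field.  Tabular
import is driven by a column mapping (id column, per-column target/type,
optional code table, optional constants and links column); cells holding
nested documents or vectors are JSON-encoded strings.  Every imported
record is validated; rejected rows are enumerated with 1-based row
numbers and reasons, and `rows_read = created + rejected` always holds.
CSV/TSV dialect is chosen by file extension; a header row is required.

## Problem sizes

The test suite exercises a 60-neuron / 500-synapse dataset for unit and
property tests and three seeds of 500 neurons / 5,000 synapses for the
full catalog equivalence sweep; the acceptance script uses the same
500 / 5,000 scale.  These sizes give every layer and selector non-trivial
occupancy while keeping exhaustive brute-force oracles cheap.

## Known limitations

- The eight-endpoint split and the 119-consistent selector domain are
  documented readings of an underspecified surface, not the only ones.
- The neuron schema is fixed at the 16 listed attributes; additional
  dataset-specific attributes belong in the extension property map.
- The balance stored/derived consistency check warns rather than fails;
  pipelines that require strict equality should treat warnings as fatal.
- No HTTP façade is included; the endpoint surface is library + CLI.
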