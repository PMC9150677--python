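"""Seeded generator of H01-like annotation documents with exact ground truth.

Emulates the annotation *structure* of a petascale cortical EM dataset at
desk scale: seven cortical layers stacked along the y (depth) axis with
configured widths, neurons with per-compartment skeleton-node counts and a
layer assignment, and synapses with polarity, pre/post partners, a voxel
location, a half-open bounding box and a layer attribute.  Alongside the
documents it emits a :class:`GroundTruth` of exact tallies computed by a
direct pass over the generated metadata — independent of the store and its
indexes — so every query template has a hermetic oracle.

No biological realism beyond the statistics the queries touch: no
morphologies, no spatial clustering, no distance-dependent connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import yaml

from .errors import ConfigurationError
from .queries import (
    Location,
    QueryResult,
    QuestionInstance,
    SynapseTypeSelector,
)
from .schema import (
    Compartment,
    CommunitySchemaRegistry,
    LayerMetadata,
    NeuronMetadata,
    PostsynapticPartner,
    SynapseMetadata,
    SynapseType,
    SynapticSite,
    compute_ei_balance,
    compute_spinyness,
)
from .store import MetadataStore

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "NeuronTally",
    "generate",
    "build_store",
    "ground_truth_answer",
]

_DEFAULT_LAYER_WIDTHS = (160_000, 300_000, 360_000, 300_000, 240_000, 420_000, 220_000)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic connectome.

    Layer widths are nanometers along the depth axis; the volume is voxels
    at ``resolution_nm``.  Defaults describe a desk-scale slab with the
    cortical excitatory majority (80% excitatory synapses), dendrites as
    the dominant postsynaptic target, and a 5% fraction of synapses left
    without a layer assignment to exercise whole-volume vs per-layer
    bookkeeping.
    """

    seed: int = 0
    n_neurons: int = 500
    n_synapses: int = 5000
    layer_widths: Tuple[int, ...] = _DEFAULT_LAYER_WIDTHS
    resolution_nm: Tuple[float, float, float] = (8.0, 8.0, 33.0)
    volume_dim_voxels: Tuple[int, int, int] = (125_000, 250_000, 4_500)
    excitatory_fraction: float = 0.8
    neuron_type_mixture: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.55, 2: 0.30, 3: 0.10}
    )
    compartment_distribution: Mapping[str, float] = field(
        default_factory=lambda: {
            "dendrite_shaft": 0.55,
            "dendritic_spine": 0.32,
            "soma": 0.08,
            "axon_initial_segment": 0.05,
        }
    )
    unassigned_layer_fraction: float = 0.05
    node_count_ranges: Mapping[str, Tuple[int, int]] = field(
        default_factory=lambda: {
            "dendrite": (200, 2000),
            "axon": (200, 3000),
            "cilia": (0, 60),
            "axon_initial_segment": (0, 120),
            "myelinated_axon": (0, 600),
        }
    )
    spine_fraction_range: Tuple[float, float] = (0.0, 0.8)
    volume_range_voxels: Tuple[int, int] = (1_000_000, 1_000_000_000)
    dataset_id: str = "synthetic-h01"

    def __post_init__(self) -> None:
        if self.n_neurons < 0 or self.n_synapses < 0:
            raise ConfigurationError("entity counts must be non-negative")
        if len(self.layer_widths) != 7:
            raise ConfigurationError("exactly seven layer widths are required")
        if any(w < 0 for w in self.layer_widths):
            raise ConfigurationError("layer widths must be non-negative")
        for name, probs in (
            ("neuron_type_mixture", self.neuron_type_mixture.values()),
            ("compartment_distribution", self.compartment_distribution.values()),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities must sum to 1")
        for name, frac in (
            ("excitatory_fraction", self.excitatory_fraction),
            ("unassigned_layer_fraction", self.unassigned_layer_fraction),
        ):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_synapses > 0 and self.n_neurons < 2:
            raise ConfigurationError(
                "synapses need at least two neurons (self-synapses are excluded)"
            )
        if self._layered_depth_voxels() > self.volume_dim_voxels[1]:
            raise ConfigurationError(
                "layer widths exceed the volume's depth extent"
            )

    def _layered_depth_voxels(self) -> int:
        return int(sum(self.layer_widths) // self.resolution_nm[1])

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneratorConfig":
        kwargs = dict(d)
        for key in ("layer_widths", "resolution_nm", "volume_dim_voxels",
                    "spine_fraction_range", "volume_range_voxels"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "neuron_type_mixture" in kwargs:
            kwargs["neuron_type_mixture"] = {
                int(k): float(v) for k, v in kwargs["neuron_type_mixture"].items()
            }
        if "node_count_ranges" in kwargs:
            kwargs["node_count_ranges"] = {
                k: tuple(v) for k, v in kwargs["node_count_ranges"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "GeneratorConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


@dataclass(frozen=True)
class NeuronTally:
    """Exact per-neuron synapse bookkeeping plus the fields queries touch."""

    layer: Optional[int]
    outgoing: int
    incoming: int
    excitatory: int
    inhibitory: int
    incoming_onto_ais: int
    ei_balance: Optional[float]
    total_skeleton_nodes: int

    def incoming_by_selector(self, selector: SynapseTypeSelector) -> int:
        return {
            SynapseTypeSelector.ALL: self.incoming,
            SynapseTypeSelector.EXCITATORY: self.excitatory,
            SynapseTypeSelector.INHIBITORY: self.inhibitory,
            SynapseTypeSelector.ONTO_AXON_INITIAL_SEGMENT: self.incoming_onto_ais,
        }[selector]


_LOC_KEYS = ("whole_volume",) + tuple(f"layer{k}" for k in range(1, 8)) + ("unassigned",)


@dataclass(frozen=True)
class GroundTruth:
    """Exact tallies for a generated dataset, independent of any store."""

    n_neurons: int
    n_synapses: int
    layer_widths: Dict[int, int]
    # selector value -> location key ("whole_volume", "layer1".."layer7",
    # "unassigned") -> synapse count
    synapse_counts: Dict[str, Dict[str, int]]
    per_neuron: Dict[int, NeuronTally]
    neurons_per_layer: Dict[int, Tuple[int, ...]]

    def count(self, selector: SynapseTypeSelector, location: Location) -> int:
        return self.synapse_counts[SynapseTypeSelector(selector).value][str(location)]

    def unassigned_count(self, selector: SynapseTypeSelector) -> int:
        return self.synapse_counts[SynapseTypeSelector(selector).value]["unassigned"]

    def neurons_in(self, location: Location) -> List[int]:
        if location.is_whole_volume:
            return sorted(self.per_neuron)
        return sorted(self.neurons_per_layer.get(location.layer, ()))

    def as_dict(self) -> Dict[str, Any]:
        return {
            "n_neurons": self.n_neurons,
            "n_synapses": self.n_synapses,
            "layer_widths": {str(k): v for k, v in self.layer_widths.items()},
            "synapse_counts": self.synapse_counts,
            "per_neuron": {
                str(nid): {
                    "layer": t.layer,
                    "outgoing": t.outgoing,
                    "incoming": t.incoming,
                    "excitatory": t.excitatory,
                    "inhibitory": t.inhibitory,
                    "incoming_onto_ais": t.incoming_onto_ais,
                    "ei_balance": t.ei_balance,
                    "total_skeleton_nodes": t.total_skeleton_nodes,
                }
                for nid, t in self.per_neuron.items()
            },
            "neurons_per_layer": {
                str(k): list(v) for k, v in self.neurons_per_layer.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GroundTruth":
        return cls(
            n_neurons=d["n_neurons"],
            n_synapses=d["n_synapses"],
            layer_widths={int(k): v for k, v in d["layer_widths"].items()},
            synapse_counts={
                sel: dict(counts) for sel, counts in d["synapse_counts"].items()
            },
            per_neuron={
                int(nid): NeuronTally(
                    layer=t["layer"],
                    outgoing=t["outgoing"],
                    incoming=t["incoming"],
                    excitatory=t["excitatory"],
                    inhibitory=t["inhibitory"],
                    incoming_onto_ais=t["incoming_onto_ais"],
                    ei_balance=t["ei_balance"],
                    total_skeleton_nodes=t["total_skeleton_nodes"],
                )
                for nid, t in d["per_neuron"].items()
            },
            neurons_per_layer={
                int(k): tuple(v) for k, v in d["neurons_per_layer"].items()
            },
        )


# --------------------------------------------------------------------------
# Generation
# --------------------------------------------------------------------------


def _layer_of_y(y_voxel: int, boundaries_nm: Tuple[float, ...], res_y: float) -> int:
    """1-based layer containing a depth coordinate (boundaries cumulative, nm)."""
    y_nm = y_voxel * res_y
    for k, upper in enumerate(boundaries_nm, start=1):
        if y_nm < upper:
            return k
    return 7  # numerically at the last boundary: clamp into layer 7


def generate(
    config: GeneratorConfig,
) -> Tuple[List[NeuronMetadata], List[SynapseMetadata], List[LayerMetadata], GroundTruth]:
    """Generate typed metadata plus exact ground truth.

    Deterministic: identical config (including seed) yields identical
    output.  Every neuron's stored aggregate fields equal the exact tallies
    over the emitted synapse table, so 100% of documents validate.
    """
    rng = np.random.default_rng(config.seed)
    res_y = config.resolution_nm[1]
    boundaries_nm = tuple(np.cumsum(config.layer_widths).tolist())
    depth_voxels = config._layered_depth_voxels()

    layers = [LayerMetadata(k, int(w)) for k, w in enumerate(config.layer_widths, start=1)]

    # --- neuron skeletons, types, layers -----------------------------------
    type_codes = sorted(config.neuron_type_mixture)
    type_probs = np.array([config.neuron_type_mixture[c] for c in type_codes], dtype=float)
    type_probs = type_probs / type_probs.sum()
    neuron_ids = list(range(1, config.n_neurons + 1))

    skeletons: Dict[int, Dict[str, int]] = {}
    neuron_layer: Dict[int, int] = {}
    neuron_type: Dict[int, int] = {}
    neuron_volume: Dict[int, int] = {}
    for nid in neuron_ids:
        counts = {}
        for comp, (lo, hi) in config.node_count_ranges.items():
            counts[comp] = int(rng.integers(lo, hi + 1))
        frac = float(rng.uniform(*config.spine_fraction_range))
        counts["dendritic_spine"] = int(round(frac * counts["dendrite"]))
        skeletons[nid] = counts
        neuron_layer[nid] = int(1 + rng.integers(0, 7)) if depth_voxels > 0 else 1
        neuron_type[nid] = int(rng.choice(type_codes, p=type_probs))
        neuron_volume[nid] = int(rng.integers(*config.volume_range_voxels))

    # --- synapses ------------------------------------------------------------
    comp_names = sorted(config.compartment_distribution)
    comp_probs = np.array(
        [config.compartment_distribution[c] for c in comp_names], dtype=float
    )
    comp_probs = comp_probs / comp_probs.sum()
    dim_x, _, dim_z = config.volume_dim_voxels

    synapses: List[SynapseMetadata] = []
    for i in range(config.n_synapses):
        pre, post = (int(v) for v in rng.choice(neuron_ids, size=2, replace=False))
        stype = (
            SynapseType.EXCITATORY
            if rng.random() < config.excitatory_fraction
            else SynapseType.INHIBITORY
        )
        compartment = Compartment(str(rng.choice(comp_names, p=comp_probs)))
        loc = (
            int(rng.integers(0, dim_x)),
            int(rng.integers(0, max(depth_voxels, 1))),
            int(rng.integers(0, dim_z)),
        )
        true_layer = _layer_of_y(loc[1], boundaries_nm, res_y)
        layer: Optional[int] = (
            None if rng.random() < config.unassigned_layer_fraction else true_layer
        )
        slack = rng.integers(0, 11, size=3)
        extent = rng.integers(1, 12, size=3)
        lo = tuple(int(c - min(int(s), c)) for c, s in zip(loc, slack))
        hi = tuple(int(c + int(e)) for c, e in zip(loc, extent))
        synapses.append(
            SynapseMetadata(
                synapse_id=f"syn-{i:06d}",
                synapse_type=stype,
                presynaptic_site=SynapticSite(neuron_id=pre, class_type=neuron_type[pre]),
                postsynaptic_partner=PostsynapticPartner(
                    neuron_id=post, class_type=neuron_type[post], compartment=compartment
                ),
                location=loc,
                bounding_box=(lo, hi),
                layer=layer,
            )
        )

    # --- exact tallies (direct pass over the emitted metadata) ---------------
    tallies = {nid: {"out": 0, "in": 0, "e": 0, "i": 0, "ais": 0} for nid in neuron_ids}
    counts: Dict[str, Dict[str, int]] = {
        sel.value: {key: 0 for key in _LOC_KEYS} for sel in SynapseTypeSelector
    }
    for syn in synapses:
        tallies[syn.presynaptic_site.neuron_id]["out"] += 1
        t = tallies[syn.postsynaptic_partner.neuron_id]
        t["in"] += 1
        if syn.synapse_type is SynapseType.EXCITATORY:
            t["e"] += 1
        elif syn.synapse_type is SynapseType.INHIBITORY:
            t["i"] += 1
        onto_ais = syn.postsynaptic_partner.compartment is Compartment.AXON_INITIAL_SEGMENT
        if onto_ais:
            t["ais"] += 1
        selectors = [SynapseTypeSelector.ALL]
        if syn.synapse_type is SynapseType.EXCITATORY:
            selectors.append(SynapseTypeSelector.EXCITATORY)
        elif syn.synapse_type is SynapseType.INHIBITORY:
            selectors.append(SynapseTypeSelector.INHIBITORY)
        if onto_ais:
            selectors.append(SynapseTypeSelector.ONTO_AXON_INITIAL_SEGMENT)
        loc_key = "unassigned" if syn.layer is None else f"layer{syn.layer}"
        for sel in selectors:
            counts[sel.value]["whole_volume"] += 1
            counts[sel.value][loc_key] += 1

    # --- neurons with stored aggregates equal to the tallies -----------------
    neurons: List[NeuronMetadata] = []
    per_neuron: Dict[int, NeuronTally] = {}
    neurons_per_layer: Dict[int, List[int]] = {k: [] for k in range(1, 8)}
    for nid in neuron_ids:
        sk = skeletons[nid]
        t = tallies[nid]
        balance = compute_ei_balance(t["e"], t["i"])
        spin = compute_spinyness(sk["dendritic_spine"], sk["dendrite"])
        neuron = NeuronMetadata(
            neuron_id=nid,
            volume=neuron_volume[nid],
            n_outgoing_synapses=t["out"],
            n_incoming_synapses=t["in"],
            n_incoming_excitatory=t["e"],
            n_incoming_inhibitory=t["i"],
            n_dendrite_skeleton_nodes=sk["dendrite"],
            n_axon_skeleton_nodes=sk["axon"],
            n_dendritic_spine_skeleton_nodes=sk["dendritic_spine"],
            n_cilia_skeleton_nodes=sk["cilia"],
            n_ais_skeleton_nodes=sk["axon_initial_segment"],
            n_myelinated_axon_skeleton_nodes=sk["myelinated_axon"],
            neuron_type=neuron_type[nid],
            spinyness=spin,
            layer=neuron_layer[nid],
            ei_balance=balance,
        )
        neurons.append(neuron)
        neurons_per_layer[neuron_layer[nid]].append(nid)
        per_neuron[nid] = NeuronTally(
            layer=neuron_layer[nid],
            outgoing=t["out"],
            incoming=t["in"],
            excitatory=t["e"],
            inhibitory=t["i"],
            incoming_onto_ais=t["ais"],
            ei_balance=balance,
            total_skeleton_nodes=neuron.total_skeleton_nodes(),
        )

    ground_truth = GroundTruth(
        n_neurons=config.n_neurons,
        n_synapses=config.n_synapses,
        layer_widths={layer.layer_id: layer.width for layer in layers},
        synapse_counts=counts,
        per_neuron=per_neuron,
        neurons_per_layer={k: tuple(v) for k, v in neurons_per_layer.items()},
    )
    return neurons, synapses, layers, ground_truth


def build_store(
    config: GeneratorConfig, registry: Optional[CommunitySchemaRegistry] = None
) -> Tuple[MetadataStore, GroundTruth]:
    """Generate a dataset and load it, validated, into a fresh store."""
    neurons, synapses, layers, ground_truth = generate(config)
    store = MetadataStore(
        dataset_id=config.dataset_id,
        registry=registry,
        resolution_nm=config.resolution_nm,
    )
    for layer in layers:
        store.insert(layer.to_record(config.dataset_id))
    for neuron in neurons:
        store.insert(neuron.to_record(config.dataset_id))
    for synapse in synapses:
        store.insert(synapse.to_record(config.dataset_id))
    return store, ground_truth


# --------------------------------------------------------------------------
# Oracle twin of the query dispatcher
# --------------------------------------------------------------------------


def ground_truth_answer(gt: GroundTruth, question: QuestionInstance) -> QueryResult:
    """Answer a catalog question from ground-truth tallies only.

    Never consults a store or its indexes; the oracle twin of
    :func:`connmeta.queries.answer`.
    """
    if not isinstance(question, QuestionInstance):
        raise ValueError("question must be a QuestionInstance")
    t = question.template_id
    if t == "Q1":
        return QueryResult(
            question, "scalar", gt.count(question.type_sel, question.location)
        )
    if t == "Q2":
        counts = {
            k: gt.count(question.type_sel, Location(k)) for k in range(1, 8)
        }
        best = (max if question.extremum == "most" else min)(counts.values())
        layer_id = min(k for k, v in counts.items() if v == best)
        return QueryResult(question, "layer_count", (layer_id, best))
    if t == "Q3":
        return QueryResult(question, "scalar", gt.layer_widths[question.location.layer])
    if t == "Q4":
        lengths = [
            float(gt.per_neuron[nid].total_skeleton_nodes)
            for nid in gt.neurons_in(question.location)
        ]
        if question.aggregate == "total":
            return QueryResult(question, "scalar", float(sum(lengths)))
        if not lengths:
            return QueryResult(question, "empty", None)
        return QueryResult(question, "scalar", float(sum(lengths) / len(lengths)))
    if t == "Q5":
        ids = gt.neurons_in(question.location)
        if not ids:
            return QueryResult(question, "empty", None)
        incoming = {nid: gt.per_neuron[nid].incoming_by_selector(question.type_sel) for nid in ids}
        best = max(incoming.values())
        nid = min(k for k, v in incoming.items() if v == best)
        return QueryResult(question, "neuron_count", (nid, best))
    if question.value is None:
        raise ValueError(f"{t} requires the numeric value slot to be bound at ask time")
    balances = [
        (nid, gt.per_neuron[nid].ei_balance)
        for nid in gt.neurons_in(question.location)
        if gt.per_neuron[nid].ei_balance is not None
    ]
    if t == "Q6":
        if not balances:
            return QueryResult(question, "empty", None)
        nid = min(balances, key=lambda nb: (abs(nb[1] - question.value), nb[0]))[0]
        return QueryResult(question, "neuron", nid)
    if t == "Q7":
        keep = (
            (lambda b: b > question.value)
            if question.direction == "greater"
            else (lambda b: b < question.value)
        )
        return QueryResult(
            question, "neuron_list", sorted(nid for nid, b in balances if keep(b))
        )
    raise AssertionError("unreachable")
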