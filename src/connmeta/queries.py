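"""The seven question templates of the discovery-portal query surface.

A user of the portal composes a question from dropdown domains: a synapse
type selector (all / excitatory / inhibitory / onto axon initial segments),
a location (the whole volume or one of the seven cortical layers), and a
few template-specific slots (most/fewest, average/total, greater/less, a
numeric balance value).  Enumerating every discrete combination across the
seven templates yields the full catalog of 119 questions:

    Q1  4·8 = 32   How many [type] synapses are made in [location]?
    Q2  2·4 =  8   Which layer has the [most/fewest] [type] synapses?
    Q3      =  7   How wide is [layer]?
    Q4  2·8 = 16   What is the [average/total] length of neurons in [location]?
    Q5  4·8 = 32   Neuron with the greatest number of [type] synapses in [location].
    Q6      =  8   A neuron with an E/(E+I) value of [value] in [location].
    Q7  2·8 = 16   All neurons with E/(E+I) [greater/less] than [value] in [location].

Q6/Q7 carry a free numeric slot bound at ask time; each discrete
combination counts once in the catalog.  All ties break to the lowest id,
and aggregates over empty sets are undefined rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Any, Dict, List, Mapping, Optional, Tuple, Union

from .errors import ConfigurationError
from .store import MetadataStore

__all__ = [
    "SynapseTypeSelector",
    "Location",
    "WHOLE_VOLUME",
    "QuestionInstance",
    "QueryResult",
    "q1_count_synapses",
    "q2_layer_extremum",
    "q3_layer_width",
    "q4_neuron_length",
    "q5_top_neuron",
    "q6_find_neuron_by_balance",
    "q7_list_neurons_by_balance",
    "enumerate_question_catalog",
    "answer",
    "TEMPLATE_IDS",
]

TEMPLATE_IDS = ("Q1", "Q2", "Q3", "Q4", "Q5", "Q6", "Q7")


class SynapseTypeSelector(str, Enum):
    """Synapse-type dropdown: polarity or distinguished postsynaptic target."""

    ALL = "all"
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"
    ONTO_AXON_INITIAL_SEGMENT = "onto_axon_initial_segment"


@dataclass(frozen=True, order=True)
class Location:
    """Whole volume (``layer=None``) or one of the seven cortical layers."""

    layer: Optional[int] = None

    def __post_init__(self) -> None:
        if self.layer is not None and not (1 <= self.layer <= 7):
            raise ValueError(f"layer must be in 1..7, got {self.layer}")

    @property
    def is_whole_volume(self) -> bool:
        return self.layer is None

    def __str__(self) -> str:
        return "whole_volume" if self.layer is None else f"layer{self.layer}"

    @classmethod
    def parse(cls, text: str) -> "Location":
        text = text.strip().lower().replace(" ", "").replace("_", "")
        if text in ("wholevolume", "volume", "whole"):
            return cls(None)
        if text.startswith("layer"):
            return cls(int(text[5:]))
        return cls(int(text))

    @classmethod
    def domain(cls) -> Tuple["Location", ...]:
        """Default location dropdown: whole volume plus layers 1..7."""
        return (cls(None),) + tuple(cls(k) for k in range(1, 8))


WHOLE_VOLUME = Location(None)

# Location comes first in the dropdown ordering used for the catalog.
_DEFAULT_TYPE_DOMAIN = tuple(SynapseTypeSelector)


def _synapse_matches(doc: Mapping[str, Any], selector: SynapseTypeSelector) -> bool:
    if selector is SynapseTypeSelector.ALL:
        return True
    if selector is SynapseTypeSelector.ONTO_AXON_INITIAL_SEGMENT:
        partner = doc.get("postsynaptic_partner") or {}
        return partner.get("compartment") == "axon_initial_segment"
    return doc.get("synapse_type") == selector.value


def _in_location(doc: Mapping[str, Any], location: Location) -> bool:
    # Whole volume includes entities with an undefined layer; a layer
    # location matches on the stored layer attribute only.
    if location.is_whole_volume:
        return True
    return doc.get("layer") == location.layer


def _require_layers(store: MetadataStore) -> None:
    present = {doc.get("layer_id") for doc in store.documents("layer")}
    missing = [k for k in range(1, 8) if k not in present]
    if missing:
        raise ConfigurationError(f"dataset is missing layer entities: {missing}")


# --------------------------------------------------------------------------
# The seven templates
# --------------------------------------------------------------------------


def q1_count_synapses(
    store: MetadataStore, type_sel: SynapseTypeSelector, location: Location
) -> int:
    """How many [type] synapses are made in [location]?"""
    type_sel = SynapseTypeSelector(type_sel)
    n = 0
    for doc in store.documents("synapse"):
        if _in_location(doc, location) and _synapse_matches(doc, type_sel):
            n += 1
    return n


def q2_layer_extremum(
    store: MetadataStore, extremum: str, type_sel: SynapseTypeSelector
) -> Tuple[int, int]:
    """Which layer has the [most/fewest] [type] synapses? Ties → lowest layer."""
    if extremum not in ("most", "fewest"):
        raise ValueError(f"extremum must be 'most' or 'fewest', got {extremum!r}")
    _require_layers(store)
    counts = {k: q1_count_synapses(store, type_sel, Location(k)) for k in range(1, 8)}
    best = (max if extremum == "most" else min)(counts.values())
    layer_id = min(k for k, v in counts.items() if v == best)
    return layer_id, best


def q3_layer_width(store: MetadataStore, layer_id: int) -> int:
    """How wide is [layer]? Verbatim width attribute; unknown layer → not found."""
    record = store.get_layer(layer_id)
    return record.get("width")


def q4_neuron_length(
    store: MetadataStore,
    aggregate: str,
    location: Location,
    node_spacing: float = 1.0,
) -> Optional[float]:
    """[Average/Total] length of neurons in [location].

    Neuron length is proxied by the sum of the six per-compartment
    skeleton-node counts times the inter-node spacing.  The average over a
    location with no neurons is undefined (``None``), not zero.
    """
    if aggregate not in ("average", "total"):
        raise ValueError(f"aggregate must be 'average' or 'total', got {aggregate!r}")
    node_fields = (
        "n_dendrite_skeleton_nodes",
        "n_axon_skeleton_nodes",
        "n_dendritic_spine_skeleton_nodes",
        "n_cilia_skeleton_nodes",
        "n_ais_skeleton_nodes",
        "n_myelinated_axon_skeleton_nodes",
    )
    lengths = [
        sum(doc.get(f, 0) for f in node_fields) * node_spacing
        for doc in store.documents("neuron")
        if _in_location(doc, location)
    ]
    if aggregate == "total":
        return float(sum(lengths))
    if not lengths:
        return None
    return float(sum(lengths) / len(lengths))


def q5_top_neuron(
    store: MetadataStore, type_sel: SynapseTypeSelector, location: Location
) -> Optional[Tuple[int, int]]:
    """Neuron in [location] with the most incoming [type] synapses.

    Counts are tallied from the synapse collection via the postsynaptic
    index, never from stored aggregate fields.  Ties break to the lowest
    neuron id; a location without neurons yields an empty result.
    """
    type_sel = SynapseTypeSelector(type_sel)
    neuron_ids = [
        doc["neuron_id"]
        for doc in store.documents("neuron")
        if _in_location(doc, location)
    ]
    if not neuron_ids:
        return None
    incoming: Dict[int, int] = {nid: 0 for nid in neuron_ids}
    for doc in store.documents("synapse"):
        partner = doc.get("postsynaptic_partner") or {}
        nid = partner.get("neuron_id")
        if nid in incoming and _synapse_matches(doc, type_sel):
            incoming[nid] += 1
    best = max(incoming.values())
    neuron_id = min(nid for nid, v in incoming.items() if v == best)
    return neuron_id, best


def _defined_balances(store: MetadataStore, location: Location) -> List[Tuple[int, float]]:
    out = []
    for doc in store.documents("neuron"):
        if _in_location(doc, location) and doc.get("ei_balance") is not None:
            out.append((doc["neuron_id"], doc["ei_balance"]))
    return out


def q6_find_neuron_by_balance(
    store: MetadataStore, value: float, location: Location
) -> Optional[int]:
    """A neuron in [location] whose E/(E+I) balance is nearest [value].

    Only neurons with a defined balance compete; ties break to the lowest
    neuron id; none defined → empty result.
    """
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"balance value must lie in [0, 1], got {value}")
    candidates = _defined_balances(store, location)
    if not candidates:
        return None
    return min(candidates, key=lambda nb: (abs(nb[1] - value), nb[0]))[0]


def q7_list_neurons_by_balance(
    store: MetadataStore, direction: str, value: float, location: Location
) -> List[int]:
    """All neurons in [location] with balance strictly [greater/less] than [value]."""
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"balance value must lie in [0, 1], got {value}")
    keep = (lambda b: b > value) if direction == "greater" else (lambda b: b < value)
    return sorted(nid for nid, b in _defined_balances(store, location) if keep(b))


# --------------------------------------------------------------------------
# Catalog enumeration and dispatch
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class QuestionInstance:
    """One concrete parameterization of a question template."""

    template_id: str
    type_sel: Optional[SynapseTypeSelector] = None
    location: Optional[Location] = None
    extremum: Optional[str] = None
    aggregate: Optional[str] = None
    direction: Optional[str] = None
    value: Optional[float] = None

    _REQUIRED = {
        "Q1": ("type_sel", "location"),
        "Q2": ("extremum", "type_sel"),
        "Q3": ("location",),  # must be a specific layer
        "Q4": ("aggregate", "location"),
        "Q5": ("type_sel", "location"),
        "Q6": ("location",),
        "Q7": ("direction", "location"),
    }

    def __post_init__(self) -> None:
        if self.template_id not in TEMPLATE_IDS:
            raise ValueError(f"unknown template id {self.template_id!r}")
        for name in self._REQUIRED[self.template_id]:
            if getattr(self, name) is None:
                raise ValueError(f"{self.template_id} requires parameter {name!r}")
        if self.template_id == "Q3" and self.location.is_whole_volume:
            raise ValueError("Q3 asks about one specific layer")
        if self.value is not None and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"value slot must lie in [0, 1], got {self.value}")

    def bind(self, value: float) -> "QuestionInstance":
        """Fill the free numeric slot (Q6/Q7) at ask time."""
        return replace(self, value=value)

    def as_dict(self) -> Dict[str, Any]:
        d: Dict[str, Any] = {"template_id": self.template_id}
        if self.type_sel is not None:
            d["type_sel"] = self.type_sel.value
        if self.location is not None:
            d["location"] = str(self.location)
        for name in ("extremum", "aggregate", "direction", "value"):
            if getattr(self, name) is not None:
                d[name] = getattr(self, name)
        return d


@dataclass(frozen=True)
class QueryResult:
    """Typed answer to one question, echoing the instance it answers.

    ``kind`` is one of scalar, layer_count, neuron_count, neuron_list,
    neuron, empty.
    """

    question: QuestionInstance
    kind: str
    value: Any

    def as_dict(self) -> Dict[str, Any]:
        value = self.value
        if isinstance(value, tuple):
            value = list(value)
        return {"question": self.question.as_dict(), "kind": self.kind, "value": value}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "QueryResult":
        q = d["question"]
        question = QuestionInstance(
            template_id=q["template_id"],
            type_sel=SynapseTypeSelector(q["type_sel"]) if "type_sel" in q else None,
            location=Location.parse(q["location"]) if "location" in q else None,
            extremum=q.get("extremum"),
            aggregate=q.get("aggregate"),
            direction=q.get("direction"),
            value=q.get("value"),
        )
        value = d["value"]
        if isinstance(value, list) and d["kind"] in ("layer_count", "neuron_count"):
            value = tuple(value)
        return cls(question=question, kind=d["kind"], value=value)


def enumerate_question_catalog(
    type_domain: Tuple[SynapseTypeSelector, ...] = _DEFAULT_TYPE_DOMAIN,
    location_domain: Tuple[Location, ...] = Location.domain(),
) -> List[QuestionInstance]:
    """Enumerate every discrete question the portal can ask.

    With the default 4-member type domain and 8-member location domain the
    catalog holds exactly 119 unique instances across the 7 templates.
    Deterministic: templates in order, then dropdowns in domain order.
    """
    catalog: List[QuestionInstance] = []
    layers = tuple(Location(k) for k in range(1, 8))
    for t in type_domain:
        for loc in location_domain:
            catalog.append(QuestionInstance("Q1", type_sel=t, location=loc))
    for extremum in ("most", "fewest"):
        for t in type_domain:
            catalog.append(QuestionInstance("Q2", extremum=extremum, type_sel=t))
    for loc in layers:
        catalog.append(QuestionInstance("Q3", location=loc))
    for aggregate in ("average", "total"):
        for loc in location_domain:
            catalog.append(QuestionInstance("Q4", aggregate=aggregate, location=loc))
    for t in type_domain:
        for loc in location_domain:
            catalog.append(QuestionInstance("Q5", type_sel=t, location=loc))
    for loc in location_domain:
        catalog.append(QuestionInstance("Q6", location=loc))
    for direction in ("greater", "less"):
        for loc in location_domain:
            catalog.append(QuestionInstance("Q7", direction=direction, location=loc))
    return catalog


def answer(store: MetadataStore, question: QuestionInstance) -> QueryResult:
    """Dispatch a question instance to its template implementation.

    Q6/Q7 instances must have their numeric slot bound
    (:meth:`QuestionInstance.bind`) before being answered.
    """
    if not isinstance(question, QuestionInstance):
        raise ValueError("question must be a QuestionInstance")
    t = question.template_id
    if t == "Q1":
        return QueryResult(
            question, "scalar", q1_count_synapses(store, question.type_sel, question.location)
        )
    if t == "Q2":
        return QueryResult(
            question,
            "layer_count",
            q2_layer_extremum(store, question.extremum, question.type_sel),
        )
    if t == "Q3":
        return QueryResult(question, "scalar", q3_layer_width(store, question.location.layer))
    if t == "Q4":
        result = q4_neuron_length(store, question.aggregate, question.location)
        return QueryResult(question, "empty" if result is None else "scalar", result)
    if t == "Q5":
        result = q5_top_neuron(store, question.type_sel, question.location)
        return QueryResult(question, "empty" if result is None else "neuron_count", result)
    if question.value is None:
        raise ValueError(f"{t} requires the numeric value slot to be bound at ask time")
    if t == "Q6":
        result = q6_find_neuron_by_balance(store, question.value, question.location)
        return QueryResult(question, "empty" if result is None else "neuron", result)
    if t == "Q7":
        return QueryResult(
            question,
            "neuron_list",
            q7_list_neurons_by_balance(store, question.direction, question.value, question.location),
        )
    raise AssertionError("unreachable")
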