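"""Standardized annotation-metadata model for connectomics entities.

Connectomics datasets annotate neuroanatomical entities — neurons, synapses,
cortical layers — with key-value metadata (counts, types, layer membership,
derived ratios).  This module defines a standardized document model for such
metadata in the RAMON lineage:

* generic :class:`EntityRecord` documents carrying a URI, a data
  representation, links to related entities, and an open key-value property
  map;
* *community-defined* entity classes (``neuron``, ``synapse``, ``layer``)
  whose minimum required properties are held in a
  :class:`CommunitySchemaRegistry`, extensible with *user-defined* classes;
* validation (:func:`validate_entity`) producing a structured report of
  errors and warnings rather than a bare boolean;
* the derived quantities used throughout the query layer: the
  excitatory/inhibitory synapse balance E/(E+I), spinyness, and exact
  per-neuron synapse tallies.

Undefined values (a neuron with no classified incoming synapses has no
balance) are represented as ``None`` in memory and as *absent keys* on disk,
never as sentinel numbers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import SchemaError, UnknownClassError

__all__ = [
    "Uri",
    "LinkRelation",
    "Link",
    "DataRepresentation",
    "PropertyOrigin",
    "PropertyValue",
    "EntityRecord",
    "Severity",
    "Issue",
    "ValidationReport",
    "ClassSchema",
    "CommunitySchemaRegistry",
    "register_entity_class",
    "validate_entity",
    "compute_ei_balance",
    "compute_spinyness",
    "derive_neuron_aggregates",
    "NeuronAggregates",
    "SynapseType",
    "Compartment",
    "SynapticSite",
    "PostsynapticPartner",
    "NeuronMetadata",
    "SynapseMetadata",
    "LayerMetadata",
    "CodeTables",
    "DEFAULT_CODE_TABLES",
    "COMMUNITY_CLASSES",
    "RESERVED_KEYS",
]

# --------------------------------------------------------------------------
# Primitive value types
# --------------------------------------------------------------------------

_URI_SCHEME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:\S+$")
_LOCAL_URI_RE = re.compile(r"^[^/\s]+/[^/\s]+/[^/\s]+$")


@dataclass(frozen=True)
class Uri:
    """Locator of an entity's source data.

    Accepts either a full ``scheme:rest`` URI or a dataset-local identifier
    of the form ``<dataset>/<collection>/<id>``.
    """

    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise SchemaError("URI must be non-empty")
        if not (_URI_SCHEME_RE.match(self.value) or _LOCAL_URI_RE.match(self.value)):
            raise SchemaError(
                f"not a URI nor a <dataset>/<collection>/<id> identifier: {self.value!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


class LinkRelation(str, Enum):
    """Closed vocabulary of inter-entity link relations."""

    PARENT = "parent"
    CHILD = "child"
    SIBLING = "sibling"
    PRESYNAPTIC_NEURON = "presynaptic_neuron"
    POSTSYNAPTIC_NEURON = "postsynaptic_neuron"
    MEMBER_OF_LAYER = "member_of_layer"


@dataclass(frozen=True)
class Link:
    relation: LinkRelation
    target: Uri

    def __post_init__(self) -> None:
        if not isinstance(self.relation, LinkRelation):
            object.__setattr__(self, "relation", LinkRelation(self.relation))
        if not isinstance(self.target, Uri):
            object.__setattr__(self, "target", Uri(self.target))


class DataRepresentation(str, Enum):
    """How the entity's raw annotation is represented, if at all."""

    SKELETON = "skeleton"
    MESH = "mesh"
    PIXELS = "pixels"
    TABLE = "table"
    NONE = "none"


class PropertyOrigin(str, Enum):
    COMMUNITY = "community"
    USER = "user"


@dataclass(frozen=True)
class PropertyValue:
    """One key-value attribute attached to an entity.

    ``origin`` records whether the key belongs to the community-adopted
    schema of the entity's class or was added by the data owner.
    """

    key: str
    value: Any
    origin: PropertyOrigin = PropertyOrigin.USER

    def __post_init__(self) -> None:
        if not self.key:
            raise SchemaError("property key must be non-empty")
        if not isinstance(self.origin, PropertyOrigin):
            object.__setattr__(self, "origin", PropertyOrigin(self.origin))


RESERVED_KEYS = (
    "entity_id",
    "entity_class",
    "uri",
    "representation",
    "links",
    "dataset_id",
)


@dataclass(frozen=True)
class EntityRecord:
    """A standardized annotation document.

    All metadata beyond the reserved envelope keys lives in ``properties``;
    the canonical on-disk form (see :mod:`connmeta.formats`) is one JSON
    object per line with the properties flattened to top level.
    """

    entity_id: str
    entity_class: str
    uri: Uri
    representation: DataRepresentation
    dataset_id: str
    links: Tuple[Link, ...] = ()
    properties: Mapping[str, PropertyValue] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise SchemaError("entity_id must be non-empty")
        if not self.entity_class:
            raise SchemaError("entity_class must be non-empty")
        if not isinstance(self.uri, Uri):
            object.__setattr__(self, "uri", Uri(self.uri))
        if not isinstance(self.representation, DataRepresentation):
            object.__setattr__(
                self, "representation", DataRepresentation(self.representation)
            )
        object.__setattr__(self, "links", tuple(self.links))
        props = dict(self.properties)
        for key, pv in props.items():
            if key != pv.key:
                raise SchemaError(f"property map key {key!r} != PropertyValue.key {pv.key!r}")
            if key in RESERVED_KEYS:
                raise SchemaError(f"property key {key!r} collides with a reserved key")
        object.__setattr__(self, "properties", props)

    # -- convenience accessors ------------------------------------------------
    def get(self, key: str, default: Any = None) -> Any:
        pv = self.properties.get(key)
        return default if pv is None else pv.value

    def to_document(self) -> Dict[str, Any]:
        """Flatten to a plain JSON-serializable dict (canonical document)."""
        doc: Dict[str, Any] = {
            "entity_id": self.entity_id,
            "entity_class": self.entity_class,
            "uri": str(self.uri),
            "representation": self.representation.value,
            "links": [
                {"relation": ln.relation.value, "target": str(ln.target)}
                for ln in self.links
            ],
            "dataset_id": self.dataset_id,
        }
        for key, pv in self.properties.items():
            doc[key] = pv.value
        return doc

    @classmethod
    def from_document(
        cls, doc: Mapping[str, Any], registry: Optional["CommunitySchemaRegistry"] = None
    ) -> "EntityRecord":
        """Rebuild a record from its canonical document form.

        Property origins are recovered from the registry: keys present in the
        class schema are community-origin, anything else user-origin.
        """
        missing = [k for k in ("entity_id", "entity_class", "uri", "dataset_id") if k not in doc]
        if missing:
            raise SchemaError(f"document missing reserved keys: {missing}")
        entity_class = str(doc["entity_class"])
        is_community = registry is not None and registry.is_community(entity_class)
        schema = registry.schema_for(entity_class) if registry is not None else None
        schema_keys = set(schema.slot_keys()) if schema is not None else set()
        props: Dict[str, PropertyValue] = {}
        for key, value in doc.items():
            if key in RESERVED_KEYS:
                continue
            origin = (
                PropertyOrigin.COMMUNITY
                if is_community and key in schema_keys
                else PropertyOrigin.USER
            )
            value = _revive_value(value)
            props[key] = PropertyValue(key, value, origin)
        links = tuple(
            Link(LinkRelation(ln["relation"]), Uri(ln["target"]))
            for ln in doc.get("links", ())
        )
        return cls(
            entity_id=str(doc["entity_id"]),
            entity_class=entity_class,
            uri=Uri(str(doc["uri"])),
            representation=DataRepresentation(doc.get("representation", "none")),
            dataset_id=str(doc["dataset_id"]),
            links=links,
            properties=props,
        )


def _revive_value(value: Any) -> Any:
    # JSON turns tuples into lists; canonicalize geometric vectors to tuples
    # so round-tripped records compare equal field-for-field.
    if isinstance(value, list):
        return tuple(_revive_value(v) for v in value)
    if isinstance(value, dict):
        return {k: _revive_value(v) for k, v in value.items()}
    return value


# --------------------------------------------------------------------------
# Validation report
# --------------------------------------------------------------------------


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Issue:
    severity: Severity
    property_key: Optional[str]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    issues: Tuple[Issue, ...] = ()

    @property
    def errors(self) -> Tuple[Issue, ...]:
        return tuple(i for i in self.issues if i.severity is Severity.ERROR)

    @property
    def warnings(self) -> Tuple[Issue, ...]:
        return tuple(i for i in self.issues if i.severity is Severity.WARNING)


# --------------------------------------------------------------------------
# Class schemas and the community registry
# --------------------------------------------------------------------------

#: Property type tags understood by the validator.
PROPERTY_TYPES = (
    "integer",
    "long",
    "float",
    "string",
    "boolean",
    "object",
    "point3",
    "box3",
)


def _check_type(value: Any, ptype: str) -> bool:
    if ptype in ("integer", "long"):
        return isinstance(value, int) and not isinstance(value, bool)
    if ptype == "float":
        return (
            isinstance(value, float)
            or (isinstance(value, int) and not isinstance(value, bool))
        ) and math.isfinite(float(value))
    if ptype == "string":
        return isinstance(value, str)
    if ptype == "boolean":
        return isinstance(value, bool)
    if ptype == "object":
        return isinstance(value, Mapping)
    if ptype == "point3":
        return (
            isinstance(value, (list, tuple))
            and len(value) == 3
            and all(isinstance(v, int) and not isinstance(v, bool) for v in value)
        )
    if ptype == "box3":
        return (
            isinstance(value, (list, tuple))
            and len(value) == 2
            and all(_check_type(corner, "point3") for corner in value)
        )
    raise SchemaError(f"unknown property type tag {ptype!r}")


@dataclass(frozen=True)
class ClassSchema:
    """Minimum required and optional properties for one entity class."""

    name: str
    required: Tuple[Tuple[str, str], ...]
    optional: Tuple[Tuple[str, str], ...] = ()
    id_key: Optional[str] = None

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.required] + [k for k, _ in self.optional]
        if len(keys) != len(set(keys)):
            raise SchemaError(f"duplicate property keys in schema {self.name!r}")
        for _, t in self.required + self.optional:
            if t not in PROPERTY_TYPES:
                raise SchemaError(f"unknown property type {t!r} in schema {self.name!r}")

    def slot_keys(self) -> Tuple[str, ...]:
        """All top-level attribute slots (required then optional)."""
        return tuple(k for k, _ in self.required) + tuple(k for k, _ in self.optional)

    @property
    def n_slots(self) -> int:
        return len(self.required) + len(self.optional)

    def required_beyond_id(self) -> Tuple[str, ...]:
        return tuple(k for k, _ in self.required if k != self.id_key)


COMMUNITY_CLASSES = ("neuron", "synapse", "layer")

#: The 16 neuron attribute slots of the community standard: identifier,
#: volume, synapse tallies, per-compartment skeleton-node counts, and the
#: derived/assigned fields (spinyness, layer, type, E/(E+I) balance).
NEURON_SCHEMA = ClassSchema(
    name="neuron",
    required=(
        ("neuron_id", "integer"),
        ("volume", "long"),
        ("n_outgoing_synapses", "integer"),
        ("n_incoming_synapses", "integer"),
        ("n_incoming_excitatory", "integer"),
        ("n_incoming_inhibitory", "integer"),
        ("n_dendrite_skeleton_nodes", "integer"),
        ("n_axon_skeleton_nodes", "integer"),
        ("n_dendritic_spine_skeleton_nodes", "integer"),
        ("n_cilia_skeleton_nodes", "integer"),
        ("n_ais_skeleton_nodes", "integer"),
        ("n_myelinated_axon_skeleton_nodes", "integer"),
        ("neuron_type", "integer"),
    ),
    optional=(
        ("spinyness", "float"),
        ("layer", "integer"),
        ("ei_balance", "float"),
    ),
    id_key="neuron_id",
)

#: The seven synapse attribute slots: identifier, polarity, the two partner
#: sub-documents, location, bounding box, and (optionally defined) layer.
SYNAPSE_SCHEMA = ClassSchema(
    name="synapse",
    required=(
        ("synapse_id", "string"),
        ("synapse_type", "string"),
        ("presynaptic_site", "object"),
        ("postsynaptic_partner", "object"),
        ("location", "point3"),
        ("bounding_box", "box3"),
    ),
    optional=(("layer", "integer"),),
    id_key="synapse_id",
)

#: A layer carries exactly one required attribute beyond its identifier.
LAYER_SCHEMA = ClassSchema(
    name="layer",
    required=(("layer_id", "integer"), ("width", "integer")),
    optional=(),
    id_key="layer_id",
)


class CommunitySchemaRegistry:
    """Registry of entity-class schemas.

    The three community classes are pre-registered and protected; data
    owners may register additional user-defined classes, which never shadow
    the community ones.
    """

    def __init__(self) -> None:
        self._community: Dict[str, ClassSchema] = {
            "neuron": NEURON_SCHEMA,
            "synapse": SYNAPSE_SCHEMA,
            "layer": LAYER_SCHEMA,
        }
        self._user: Dict[str, ClassSchema] = {}

    def register(
        self,
        name: str,
        required: Sequence[Tuple[str, str]],
        optional: Sequence[Tuple[str, str]] = (),
        id_key: Optional[str] = None,
    ) -> "CommunitySchemaRegistry":
        if name in self._community:
            raise SchemaError(
                f"cannot redefine community class {name!r}; community schemas are protected"
            )
        self._user[name] = ClassSchema(
            name=name,
            required=tuple((k, t) for k, t in required),
            optional=tuple((k, t) for k, t in optional),
            id_key=id_key,
        )
        return self

    def schema_for(self, entity_class: str) -> Optional[ClassSchema]:
        return self._community.get(entity_class) or self._user.get(entity_class)

    def is_community(self, entity_class: str) -> bool:
        return entity_class in self._community

    @property
    def community_classes(self) -> Tuple[str, ...]:
        return tuple(self._community)

    @property
    def user_classes(self) -> Tuple[str, ...]:
        return tuple(self._user)

    def user_schemas_as_dict(self) -> Dict[str, Any]:
        """Serializable form of the user-registered schemas (for headers)."""
        return {
            name: {
                "required": [list(p) for p in s.required],
                "optional": [list(p) for p in s.optional],
                "id_key": s.id_key,
            }
            for name, s in self._user.items()
        }

    @classmethod
    def from_user_schemas(cls, user_schemas: Mapping[str, Any]) -> "CommunitySchemaRegistry":
        reg = cls()
        for name, body in user_schemas.items():
            reg.register(
                name,
                required=[tuple(p) for p in body.get("required", ())],
                optional=[tuple(p) for p in body.get("optional", ())],
                id_key=body.get("id_key"),
            )
        return reg


def register_entity_class(
    name: str,
    required: Sequence[Tuple[str, str]],
    optional: Sequence[Tuple[str, str]],
    registry: CommunitySchemaRegistry,
) -> CommunitySchemaRegistry:
    """Register a user-defined entity class; community classes are protected."""
    return registry.register(name, required, optional)


# --------------------------------------------------------------------------
# Derived quantities
# --------------------------------------------------------------------------


def compute_ei_balance(n_excitatory: int, n_inhibitory: int) -> Optional[float]:
    """Excitatory/inhibitory balance E/(E+I) of a neuron's incoming synapses.

    Returns a value in [0, 1], or ``None`` when the neuron has no classified
    incoming synapses (E + I = 0).
    """
    if n_excitatory < 0 or n_inhibitory < 0:
        raise ValueError("synapse counts must be non-negative")
    total = n_excitatory + n_inhibitory
    if total == 0:
        return None
    return n_excitatory / total


def compute_spinyness(n_spine_nodes: int, n_dendrite_nodes: int) -> Optional[float]:
    """Spinyness: dendritic-spine skeleton nodes per dendrite skeleton node.

    ``None`` when the neuron has no dendrite skeleton nodes.
    """
    if n_spine_nodes < 0 or n_dendrite_nodes < 0:
        raise ValueError("skeleton node counts must be non-negative")
    if n_dendrite_nodes == 0:
        return None
    return n_spine_nodes / n_dendrite_nodes


@dataclass(frozen=True)
class NeuronAggregates:
    n_outgoing: int
    n_incoming: int
    n_incoming_excitatory: int
    n_incoming_inhibitory: int
    ei_balance: Optional[float]


def derive_neuron_aggregates(
    neuron_id: int, synapses: Iterable["SynapseMetadata"]
) -> NeuronAggregates:
    """Exact synapse tallies for one neuron from a synapse collection.

    Outgoing synapses are those whose presynaptic site references the
    neuron; incoming ones reference it as postsynaptic partner.  Only
    incoming synapses with a classified polarity contribute to E and I.
    """
    n_out = n_in = n_e = n_i = 0
    for syn in synapses:
        if syn.presynaptic_site.neuron_id == neuron_id:
            n_out += 1
        if syn.postsynaptic_partner.neuron_id == neuron_id:
            n_in += 1
            if syn.synapse_type is SynapseType.EXCITATORY:
                n_e += 1
            elif syn.synapse_type is SynapseType.INHIBITORY:
                n_i += 1
    return NeuronAggregates(n_out, n_in, n_e, n_i, compute_ei_balance(n_e, n_i))


# --------------------------------------------------------------------------
# Typed community metadata
# --------------------------------------------------------------------------


class SynapseType(str, Enum):
    EXCITATORY = "excitatory"
    INHIBITORY = "inhibitory"
    UNKNOWN = "unknown"


class Compartment(str, Enum):
    DENDRITE_SHAFT = "dendrite_shaft"
    DENDRITIC_SPINE = "dendritic_spine"
    SOMA = "soma"
    AXON_INITIAL_SEGMENT = "axon_initial_segment"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class CodeTables:
    """Integer code <-> symbol tables used at the tabular-disk boundary."""

    synapse_type: Mapping[int, str] = field(
        default_factory=lambda: {0: "unknown", 1: "excitatory", 2: "inhibitory"}
    )
    neuron_type: Mapping[int, str] = field(
        default_factory=lambda: {0: "unclassified", 1: "pyramidal", 2: "interneuron", 3: "glia"}
    )
    compartment: Mapping[int, str] = field(
        default_factory=lambda: {
            0: "unknown",
            1: "dendrite_shaft",
            2: "dendritic_spine",
            3: "soma",
            4: "axon_initial_segment",
        }
    )

    def as_dict(self) -> Dict[str, Dict[int, str]]:
        return {
            "synapse_type": dict(self.synapse_type),
            "neuron_type": dict(self.neuron_type),
            "compartment": dict(self.compartment),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[Any, str]]) -> "CodeTables":
        def intkeys(m: Mapping[Any, str]) -> Dict[int, str]:
            return {int(k): v for k, v in m.items()}

        return cls(
            synapse_type=intkeys(d.get("synapse_type", {0: "unknown", 1: "excitatory", 2: "inhibitory"})),
            neuron_type=intkeys(d.get("neuron_type", {0: "unclassified", 1: "pyramidal", 2: "interneuron", 3: "glia"})),
            compartment=intkeys(
                d.get(
                    "compartment",
                    {0: "unknown", 1: "dendrite_shaft", 2: "dendritic_spine", 3: "soma", 4: "axon_initial_segment"},
                )
            ),
        )


DEFAULT_CODE_TABLES = CodeTables()


def _record_helper(
    entity_class: str,
    entity_id: str,
    dataset_id: str,
    props: Dict[str, Any],
    representation: DataRepresentation,
    links: Tuple[Link, ...],
    uri: Optional[Uri],
) -> EntityRecord:
    if uri is None:
        uri = Uri(f"{dataset_id}/{entity_class}s/{entity_id}")
    properties = {
        k: PropertyValue(k, v, PropertyOrigin.COMMUNITY)
        for k, v in props.items()
        if v is not None
    }
    return EntityRecord(
        entity_id=entity_id,
        entity_class=entity_class,
        uri=uri,
        representation=representation,
        dataset_id=dataset_id,
        links=links,
        properties=properties,
    )


@dataclass(frozen=True)
class SynapticSite:
    neuron_id: int
    class_type: int = 0

    def as_dict(self) -> Dict[str, int]:
        return {"neuron_id": self.neuron_id, "class_type": self.class_type}


@dataclass(frozen=True)
class PostsynapticPartner:
    neuron_id: int
    class_type: int = 0
    compartment: Compartment = Compartment.UNKNOWN

    def __post_init__(self) -> None:
        if not isinstance(self.compartment, Compartment):
            object.__setattr__(self, "compartment", Compartment(self.compartment))

    def as_dict(self) -> Dict[str, Any]:
        return {
            "neuron_id": self.neuron_id,
            "class_type": self.class_type,
            "compartment": self.compartment.value,
        }


@dataclass(frozen=True)
class NeuronMetadata:
    """Typed view of a community neuron document (16 attribute slots)."""

    neuron_id: int
    volume: int = 0
    n_outgoing_synapses: int = 0
    n_incoming_synapses: int = 0
    n_incoming_excitatory: int = 0
    n_incoming_inhibitory: int = 0
    n_dendrite_skeleton_nodes: int = 0
    n_axon_skeleton_nodes: int = 0
    n_dendritic_spine_skeleton_nodes: int = 0
    n_cilia_skeleton_nodes: int = 0
    n_ais_skeleton_nodes: int = 0
    n_myelinated_axon_skeleton_nodes: int = 0
    neuron_type: int = 0
    spinyness: Optional[float] = None
    layer: Optional[int] = None
    ei_balance: Optional[float] = None

    SKELETON_NODE_FIELDS = (
        "n_dendrite_skeleton_nodes",
        "n_axon_skeleton_nodes",
        "n_dendritic_spine_skeleton_nodes",
        "n_cilia_skeleton_nodes",
        "n_ais_skeleton_nodes",
        "n_myelinated_axon_skeleton_nodes",
    )

    def total_skeleton_nodes(self) -> int:
        return sum(getattr(self, f) for f in self.SKELETON_NODE_FIELDS)

    def to_record(
        self,
        dataset_id: str,
        uri: Optional[Uri] = None,
        representation: DataRepresentation = DataRepresentation.SKELETON,
        links: Tuple[Link, ...] = (),
    ) -> EntityRecord:
        props = {
            "neuron_id": self.neuron_id,
            "volume": self.volume,
            "n_outgoing_synapses": self.n_outgoing_synapses,
            "n_incoming_synapses": self.n_incoming_synapses,
            "n_incoming_excitatory": self.n_incoming_excitatory,
            "n_incoming_inhibitory": self.n_incoming_inhibitory,
            "n_dendrite_skeleton_nodes": self.n_dendrite_skeleton_nodes,
            "n_axon_skeleton_nodes": self.n_axon_skeleton_nodes,
            "n_dendritic_spine_skeleton_nodes": self.n_dendritic_spine_skeleton_nodes,
            "n_cilia_skeleton_nodes": self.n_cilia_skeleton_nodes,
            "n_ais_skeleton_nodes": self.n_ais_skeleton_nodes,
            "n_myelinated_axon_skeleton_nodes": self.n_myelinated_axon_skeleton_nodes,
            "neuron_type": self.neuron_type,
            "spinyness": self.spinyness,
            "layer": self.layer,
            "ei_balance": self.ei_balance,
        }
        return _record_helper(
            "neuron", str(self.neuron_id), dataset_id, props, representation, links, uri
        )

    @classmethod
    def from_record(cls, record: EntityRecord) -> "NeuronMetadata":
        g = record.get
        return cls(
            neuron_id=g("neuron_id"),
            volume=g("volume", 0),
            n_outgoing_synapses=g("n_outgoing_synapses", 0),
            n_incoming_synapses=g("n_incoming_synapses", 0),
            n_incoming_excitatory=g("n_incoming_excitatory", 0),
            n_incoming_inhibitory=g("n_incoming_inhibitory", 0),
            n_dendrite_skeleton_nodes=g("n_dendrite_skeleton_nodes", 0),
            n_axon_skeleton_nodes=g("n_axon_skeleton_nodes", 0),
            n_dendritic_spine_skeleton_nodes=g("n_dendritic_spine_skeleton_nodes", 0),
            n_cilia_skeleton_nodes=g("n_cilia_skeleton_nodes", 0),
            n_ais_skeleton_nodes=g("n_ais_skeleton_nodes", 0),
            n_myelinated_axon_skeleton_nodes=g("n_myelinated_axon_skeleton_nodes", 0),
            neuron_type=g("neuron_type", 0),
            spinyness=g("spinyness"),
            layer=g("layer"),
            ei_balance=g("ei_balance"),
        )


@dataclass(frozen=True)
class SynapseMetadata:
    """Typed view of a community synapse document (7 attribute slots)."""

    synapse_id: str
    synapse_type: SynapseType
    presynaptic_site: SynapticSite
    postsynaptic_partner: PostsynapticPartner
    location: Tuple[int, int, int]
    bounding_box: Tuple[Tuple[int, int, int], Tuple[int, int, int]]
    layer: Optional[int] = None

    def __post_init__(self) -> None:
        if not isinstance(self.synapse_type, SynapseType):
            object.__setattr__(self, "synapse_type", SynapseType(self.synapse_type))
        object.__setattr__(self, "location", tuple(int(v) for v in self.location))
        lo, hi = self.bounding_box
        object.__setattr__(
            self,
            "bounding_box",
            (tuple(int(v) for v in lo), tuple(int(v) for v in hi)),
        )

    def to_record(
        self,
        dataset_id: str,
        uri: Optional[Uri] = None,
        representation: DataRepresentation = DataRepresentation.NONE,
        links: Tuple[Link, ...] = (),
    ) -> EntityRecord:
        props = {
            "synapse_id": self.synapse_id,
            "synapse_type": self.synapse_type.value,
            "presynaptic_site": self.presynaptic_site.as_dict(),
            "postsynaptic_partner": self.postsynaptic_partner.as_dict(),
            "location": self.location,
            "bounding_box": self.bounding_box,
            "layer": self.layer,
        }
        return _record_helper(
            "synapse", self.synapse_id, dataset_id, props, representation, links, uri
        )

    @classmethod
    def from_record(cls, record: EntityRecord) -> "SynapseMetadata":
        pre = dict(record.get("presynaptic_site", {}))
        post = dict(record.get("postsynaptic_partner", {}))
        return cls(
            synapse_id=record.get("synapse_id"),
            synapse_type=SynapseType(record.get("synapse_type")),
            presynaptic_site=SynapticSite(
                neuron_id=pre.get("neuron_id"), class_type=pre.get("class_type", 0)
            ),
            postsynaptic_partner=PostsynapticPartner(
                neuron_id=post.get("neuron_id"),
                class_type=post.get("class_type", 0),
                compartment=Compartment(post.get("compartment", "unknown")),
            ),
            location=tuple(record.get("location")),
            bounding_box=tuple(record.get("bounding_box")),
            layer=record.get("layer"),
        )


@dataclass(frozen=True)
class LayerMetadata:
    """A cortical layer: identifier 1..7 and its width in nanometers."""

    layer_id: int
    width: int

    def to_record(
        self,
        dataset_id: str,
        uri: Optional[Uri] = None,
        representation: DataRepresentation = DataRepresentation.PIXELS,
        links: Tuple[Link, ...] = (),
    ) -> EntityRecord:
        props = {"layer_id": self.layer_id, "width": self.width}
        return _record_helper(
            "layer", str(self.layer_id), dataset_id, props, representation, links, uri
        )

    @classmethod
    def from_record(cls, record: EntityRecord) -> "LayerMetadata":
        return cls(layer_id=record.get("layer_id"), width=record.get("width"))


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

_EI_CONSISTENCY_TOL = 1e-9


def _err(key: Optional[str], msg: str) -> Issue:
    return Issue(Severity.ERROR, key, msg)


def _warn(key: Optional[str], msg: str) -> Issue:
    return Issue(Severity.WARNING, key, msg)


def _neuron_checks(props: Dict[str, Any]) -> List[Issue]:
    issues: List[Issue] = []
    count_keys = [k for k, _ in NEURON_SCHEMA.required if k.startswith(("n_", "volume"))]
    for key in count_keys:
        v = props.get(key)
        if isinstance(v, int) and v < 0:
            issues.append(_err(key, f"{key} must be non-negative, got {v}"))
    layer = props.get("layer")
    if layer is not None and not (1 <= layer <= 7):
        issues.append(_err("layer", f"layer must be in 1..7, got {layer}"))
    for key in ("spinyness", "ei_balance"):
        v = props.get(key)
        if v is not None and not (0.0 <= v <= 1.0):
            issues.append(_err(key, f"{key} must lie in [0, 1], got {v}"))

    n_in = props.get("n_incoming_synapses")
    n_e = props.get("n_incoming_excitatory")
    n_i = props.get("n_incoming_inhibitory")
    if all(isinstance(v, int) for v in (n_in, n_e, n_i)):
        if n_in < n_e + n_i:
            issues.append(
                _err(
                    "n_incoming_synapses",
                    f"incoming synapses ({n_in}) fewer than classified E+I ({n_e}+{n_i})",
                )
            )
        # balance defined exactly when at least one classified incoming synapse
        balance = props.get("ei_balance")
        if n_e + n_i == 0 and balance is not None:
            issues.append(
                _err("ei_balance", "ei_balance defined but neuron has no classified incoming synapses")
            )
        if n_e + n_i > 0:
            if balance is None:
                issues.append(
                    _err("ei_balance", "ei_balance undefined despite classified incoming synapses")
                )
            else:
                derived = n_e / (n_e + n_i)
                if abs(balance - derived) > _EI_CONSISTENCY_TOL:
                    # stored H01-style values are authoritative; flag, don't fail
                    issues.append(
                        _warn(
                            "ei_balance",
                            f"stored ei_balance {balance} differs from derived {derived}",
                        )
                    )
    n_dend = props.get("n_dendrite_skeleton_nodes")
    n_spine = props.get("n_dendritic_spine_skeleton_nodes")
    if isinstance(n_dend, int) and isinstance(n_spine, int):
        spin = props.get("spinyness")
        if n_dend == 0 and spin is not None:
            issues.append(_err("spinyness", "spinyness defined but neuron has no dendrite nodes"))
        if n_dend > 0:
            if spin is None:
                issues.append(_err("spinyness", "spinyness undefined despite dendrite nodes"))
            elif abs(spin - n_spine / n_dend) > _EI_CONSISTENCY_TOL:
                issues.append(
                    _warn(
                        "spinyness",
                        f"stored spinyness {spin} differs from derived {n_spine / n_dend}",
                    )
                )
    return issues


_VALID_SYNAPSE_TYPES = {t.value for t in SynapseType}
_VALID_COMPARTMENTS = {c.value for c in Compartment}


def _synapse_checks(props: Dict[str, Any]) -> List[Issue]:
    issues: List[Issue] = []
    stype = props.get("synapse_type")
    if isinstance(stype, str) and stype not in _VALID_SYNAPSE_TYPES:
        issues.append(_err("synapse_type", f"unknown synapse polarity {stype!r}"))
    layer = props.get("layer")
    if layer is not None and not (1 <= layer <= 7):
        issues.append(_err("layer", f"layer must be in 1..7, got {layer}"))
    for side, extra in (
        ("presynaptic_site", ()),
        ("postsynaptic_partner", ("compartment",)),
    ):
        sub = props.get(side)
        if isinstance(sub, Mapping):
            nid = sub.get("neuron_id")
            if not (isinstance(nid, int) and not isinstance(nid, bool)):
                issues.append(_err(side, f"{side}.neuron_id must be an integer"))
            ct = sub.get("class_type")
            if ct is not None and not (isinstance(ct, int) and not isinstance(ct, bool)):
                issues.append(_err(side, f"{side}.class_type must be an integer"))
            for k in extra:
                comp = sub.get(k)
                if comp is not None and comp not in _VALID_COMPARTMENTS:
                    issues.append(_err(side, f"{side}.{k}: unknown compartment {comp!r}"))
    bbox = props.get("bounding_box")
    loc = props.get("location")
    if _check_type(bbox, "box3"):
        lo, hi = bbox
        if not all(a < b for a, b in zip(lo, hi)):
            issues.append(
                _err("bounding_box", f"bounding box min {tuple(lo)} not strictly below max {tuple(hi)}")
            )
        elif _check_type(loc, "point3"):
            # half-open box: min inclusive, max exclusive
            if not all(a <= x < b for x, a, b in zip(loc, lo, hi)):
                issues.append(
                    _err("location", f"location {tuple(loc)} outside bounding box [{tuple(lo)}, {tuple(hi)})")
                )
    return issues


def _layer_checks(props: Dict[str, Any]) -> List[Issue]:
    issues: List[Issue] = []
    lid = props.get("layer_id")
    if isinstance(lid, int) and not (1 <= lid <= 7):
        issues.append(_err("layer_id", f"layer_id must be in 1..7, got {lid}"))
    width = props.get("width")
    if isinstance(width, int) and width < 0:
        issues.append(_err("width", f"width must be non-negative, got {width}"))
    return issues


_CLASS_CHECKS = {
    "neuron": _neuron_checks,
    "synapse": _synapse_checks,
    "layer": _layer_checks,
}


def validate_entity(
    record: EntityRecord, registry: CommunitySchemaRegistry
) -> ValidationReport:
    """Validate a record against its class schema.

    The record is valid iff every required property is present with a
    conforming type and all class invariants hold.  Extra keys unknown to
    the schema yield warnings, never errors; an unregistered entity class
    raises :class:`UnknownClassError`.  Pure function: the report lists every
    violation, and repeated calls on the same record are identical.
    """
    schema = registry.schema_for(record.entity_class)
    if schema is None:
        raise UnknownClassError(
            f"unknown entity class {record.entity_class!r}: no community or user schema registered"
        )
    issues: List[Issue] = []
    props = {k: pv.value for k, pv in record.properties.items()}

    typed = dict(schema.required + schema.optional)
    for key, ptype in schema.required:
        if key not in props:
            issues.append(_err(key, f"required property {key!r} is missing"))
        elif not _check_type(props[key], ptype):
            issues.append(
                _err(key, f"property {key!r} has non-conforming type (expected {ptype})")
            )
    for key, ptype in schema.optional:
        if key in props and not _check_type(props[key], ptype):
            issues.append(
                _err(key, f"property {key!r} has non-conforming type (expected {ptype})")
            )
    for key, pv in record.properties.items():
        if key not in typed:
            issues.append(_warn(key, f"property {key!r} is not part of the {schema.name!r} schema"))
            if pv.origin is PropertyOrigin.COMMUNITY:
                issues.append(
                    _err(key, f"community-origin property {key!r} absent from the {schema.name!r} schema")
                )

    checker = _CLASS_CHECKS.get(record.entity_class)
    if checker is not None and not any(i.severity is Severity.ERROR for i in issues):
        issues.extend(checker(props))

    valid = not any(i.severity is Severity.ERROR for i in issues)
    return ValidationReport(valid=valid, issues=tuple(issues))
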