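"""Document-oriented metadata store with the eight retrieval endpoints.

The reference backend is an in-memory collection-of-documents with JSON
Lines persistence, mirroring how a hosted document database would hold the
same data: one collection per entity class, secondary indexes on the keys
the query layer touches (layer, polarity, pre/post partner ids), and a
retrieval surface of exactly eight endpoint operations over neurons,
synapses and layers.  Index-accelerated filtering is an optimization only:
its results always equal an exhaustive scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import (
    DuplicateIdError,
    FilterParseError,
    NotFoundError,
    ValidationFailure,
)
from .schema import (
    CodeTables,
    CommunitySchemaRegistry,
    DEFAULT_CODE_TABLES,
    EntityRecord,
    validate_entity,
)

__all__ = [
    "FilterPredicate",
    "Clause",
    "DatasetSummary",
    "MetadataStore",
    "ENDPOINT_NAMES",
]

_COMPARATORS = ("eq", "lt", "gt", "le", "ge", "in")


@dataclass(frozen=True)
class Clause:
    key: str
    op: str
    value: Any

    def __post_init__(self) -> None:
        if self.op not in _COMPARATORS:
            raise FilterParseError(
                f"unknown comparator {self.op!r}; expected one of {_COMPARATORS}"
            )

    def matches(self, doc: Mapping[str, Any]) -> bool:
        actual = _dotted_get(doc, self.key)
        if actual is None:
            return False
        try:
            if self.op == "eq":
                return actual == self.value
            if self.op == "lt":
                return actual < self.value
            if self.op == "gt":
                return actual > self.value
            if self.op == "le":
                return actual <= self.value
            if self.op == "ge":
                return actual >= self.value
            if self.op == "in":
                return actual in self.value
        except TypeError:
            return False
        raise AssertionError("unreachable")


def _dotted_get(doc: Mapping[str, Any], key: str) -> Any:
    cur: Any = doc
    for part in key.split("."):
        if not isinstance(cur, Mapping) or part not in cur:
            return None
        cur = cur[part]
    return cur


@dataclass(frozen=True)
class FilterPredicate:
    """Conjunction of comparison clauses over document keys.

    Dotted keys reach into nested sub-documents, e.g.
    ``postsynaptic_partner.compartment``.
    """

    clauses: Tuple[Clause, ...] = ()

    @classmethod
    def from_items(cls, items: Iterable[Union[Clause, Sequence[Any]]]) -> "FilterPredicate":
        clauses = []
        for item in items:
            if isinstance(item, Clause):
                clauses.append(item)
            else:
                key, op, value = item
                clauses.append(Clause(key, op, value))
        return cls(tuple(clauses))

    @classmethod
    def equals(cls, **kwargs: Any) -> "FilterPredicate":
        return cls(tuple(Clause(k, "eq", v) for k, v in kwargs.items()))

    def matches(self, doc: Mapping[str, Any]) -> bool:
        return all(c.matches(doc) for c in self.clauses)


@dataclass(frozen=True)
class DatasetSummary:
    """Exact scan tallies for a whole dataset."""

    dataset_id: str
    counts: Dict[str, int]
    synapses_per_layer: Dict[int, int]
    neurons_per_layer: Dict[int, int]
    synapses_unassigned_layer: int
    neurons_unassigned_layer: int

    def as_dict(self) -> Dict[str, Any]:
        return {
            "dataset_id": self.dataset_id,
            "counts": dict(self.counts),
            "synapses_per_layer": {str(k): v for k, v in self.synapses_per_layer.items()},
            "neurons_per_layer": {str(k): v for k, v in self.neurons_per_layer.items()},
            "synapses_unassigned_layer": self.synapses_unassigned_layer,
            "neurons_unassigned_layer": self.neurons_unassigned_layer,
        }


#: The eight retrieval operations of the store's endpoint surface.
ENDPOINT_NAMES = (
    "get_neuron",
    "list_neurons",
    "get_synapse",
    "list_synapses",
    "get_layer",
    "list_layers",
    "neuron_synapses",
    "summary",
)

# Secondary indexes maintained per collection (key -> value -> entity ids).
_INDEXED_KEYS = {
    "neuron": ("layer",),
    "synapse": (
        "layer",
        "synapse_type",
        "presynaptic_site.neuron_id",
        "postsynaptic_partner.neuron_id",
        "postsynaptic_partner.compartment",
    ),
    "layer": (),
}


def _sort_key(entity_id: str) -> Tuple[int, Any]:
    # Numeric ids sort numerically, everything else lexicographically.
    try:
        return (0, int(entity_id))
    except ValueError:
        return (1, entity_id)


class _Collection:
    """In-memory document collection with unique ids and secondary indexes."""

    def __init__(self, entity_class: str) -> None:
        self.entity_class = entity_class
        self.records: Dict[str, EntityRecord] = {}
        self.docs: Dict[str, Dict[str, Any]] = {}
        self.indexes: Dict[str, Dict[Any, set]] = {
            key: {} for key in _INDEXED_KEYS.get(entity_class, ())
        }

    def insert(self, record: EntityRecord) -> None:
        if record.entity_id in self.records:
            raise DuplicateIdError(
                f"duplicate entity_id {record.entity_id!r} in collection {self.entity_class!r}"
            )
        doc = record.to_document()
        self.records[record.entity_id] = record
        self.docs[record.entity_id] = doc
        for key, index in self.indexes.items():
            value = _dotted_get(doc, key)
            if value is not None:
                index.setdefault(value, set()).add(record.entity_id)

    def ids_sorted(self) -> List[str]:
        return sorted(self.records, key=_sort_key)

    def find(self, predicate: Optional[FilterPredicate]) -> List[EntityRecord]:
        """Filtered retrieval: equality clauses on indexed keys narrow the
        candidate set; the full predicate is then applied.  Equivalent to an
        exhaustive scan by construction."""
        candidate_ids: Optional[set] = None
        if predicate is not None:
            for clause in predicate.clauses:
                if clause.op == "eq" and clause.key in self.indexes:
                    hits = self.indexes[clause.key].get(clause.value, set())
                    candidate_ids = hits if candidate_ids is None else candidate_ids & hits
        ids = self.records.keys() if candidate_ids is None else candidate_ids
        out = []
        for eid in sorted(ids, key=_sort_key):
            if predicate is None or predicate.matches(self.docs[eid]):
                out.append(self.records[eid])
        return out

    def scan(self, predicate: Optional[FilterPredicate]) -> List[EntityRecord]:
        """Index-free exhaustive scan (oracle twin of :meth:`find`)."""
        return [
            self.records[eid]
            for eid in self.ids_sorted()
            if predicate is None or predicate.matches(self.docs[eid])
        ]


class MetadataStore:
    """Queryable store of standardized annotation documents.

    Holds the three community collections (neurons, synapses, layers) plus
    any user-defined collections, validates every document on insert, and
    exposes the eight-endpoint retrieval surface (:data:`ENDPOINT_NAMES`).
    """

    def __init__(
        self,
        dataset_id: str,
        registry: Optional[CommunitySchemaRegistry] = None,
        resolution_nm: Tuple[float, float, float] = (8.0, 8.0, 33.0),
        code_tables: CodeTables = DEFAULT_CODE_TABLES,
    ) -> None:
        self.dataset_id = dataset_id
        self.registry = registry if registry is not None else CommunitySchemaRegistry()
        self.resolution_nm = tuple(resolution_nm)
        self.code_tables = code_tables
        self._collections: Dict[str, _Collection] = {
            "neuron": _Collection("neuron"),
            "synapse": _Collection("synapse"),
            "layer": _Collection("layer"),
        }

    # -- ingestion ----------------------------------------------------------
    def insert(self, record: EntityRecord, validate: bool = True) -> None:
        if validate:
            report = validate_entity(record, self.registry)
            if not report.valid:
                msgs = "; ".join(i.message for i in report.errors)
                raise ValidationFailure(
                    f"record {record.entity_id!r} failed validation: {msgs}", report
                )
        coll = self._collections.get(record.entity_class)
        if coll is None:
            coll = _Collection(record.entity_class)
            self._collections[record.entity_class] = coll
        coll.insert(record)

    def insert_many(self, records: Iterable[EntityRecord], validate: bool = True) -> int:
        n = 0
        for record in records:
            self.insert(record, validate=validate)
            n += 1
        return n

    # -- generic access ------------------------------------------------------
    def collection_names(self) -> Tuple[str, ...]:
        return tuple(self._collections)

    def count(self, entity_class: str) -> int:
        coll = self._collections.get(entity_class)
        return 0 if coll is None else len(coll.records)

    def records(self, entity_class: str) -> List[EntityRecord]:
        coll = self._collections.get(entity_class)
        if coll is None:
            return []
        return [coll.records[eid] for eid in coll.ids_sorted()]

    def documents(self, entity_class: str) -> List[Dict[str, Any]]:
        coll = self._collections.get(entity_class)
        if coll is None:
            return []
        return [coll.docs[eid] for eid in coll.ids_sorted()]

    def scan(self, entity_class: str, predicate: Optional[FilterPredicate]) -> List[EntityRecord]:
        coll = self._collections.get(entity_class)
        return [] if coll is None else coll.scan(predicate)

    def _get(self, entity_class: str, entity_id: str) -> EntityRecord:
        coll = self._collections.get(entity_class)
        if coll is None or entity_id not in coll.records:
            raise NotFoundError(f"{entity_class} {entity_id!r} not found in dataset {self.dataset_id!r}")
        return coll.records[entity_id]

    # -- the eight retrieval endpoints ---------------------------------------
    def get_neuron(self, neuron_id: Union[int, str]) -> EntityRecord:
        return self._get("neuron", str(neuron_id))

    def list_neurons(self, predicate: Optional[FilterPredicate] = None) -> List[EntityRecord]:
        return self._collections["neuron"].find(predicate)

    def get_synapse(self, synapse_id: str) -> EntityRecord:
        return self._get("synapse", str(synapse_id))

    def list_synapses(self, predicate: Optional[FilterPredicate] = None) -> List[EntityRecord]:
        return self._collections["synapse"].find(predicate)

    def get_layer(self, layer_id: Union[int, str]) -> EntityRecord:
        return self._get("layer", str(layer_id))

    def list_layers(self) -> List[EntityRecord]:
        return self._collections["layer"].find(None)

    def neuron_synapses(
        self, neuron_id: Union[int, str], direction: str = "both"
    ) -> List[EntityRecord]:
        """Synapses attached to a neuron via the pre/post partner indexes."""
        if direction not in ("incoming", "outgoing", "both"):
            raise ValueError(f"direction must be incoming/outgoing/both, got {direction!r}")
        self._get("neuron", str(neuron_id))  # not-found if the neuron is absent
        nid = int(neuron_id)
        coll = self._collections["synapse"]
        ids: set = set()
        if direction in ("outgoing", "both"):
            ids |= coll.indexes["presynaptic_site.neuron_id"].get(nid, set())
        if direction in ("incoming", "both"):
            ids |= coll.indexes["postsynaptic_partner.neuron_id"].get(nid, set())
        return [coll.records[eid] for eid in sorted(ids, key=_sort_key)]

    def summary(self) -> DatasetSummary:
        syn_per_layer: Dict[int, int] = {}
        neu_per_layer: Dict[int, int] = {}
        syn_unassigned = neu_unassigned = 0
        for doc in self.documents("synapse"):
            layer = doc.get("layer")
            if layer is None:
                syn_unassigned += 1
            else:
                syn_per_layer[layer] = syn_per_layer.get(layer, 0) + 1
        for doc in self.documents("neuron"):
            layer = doc.get("layer")
            if layer is None:
                neu_unassigned += 1
            else:
                neu_per_layer[layer] = neu_per_layer.get(layer, 0) + 1
        return DatasetSummary(
            dataset_id=self.dataset_id,
            counts={name: self.count(name) for name in self._collections},
            synapses_per_layer=syn_per_layer,
            neurons_per_layer=neu_per_layer,
            synapses_unassigned_layer=syn_unassigned,
            neurons_unassigned_layer=neu_unassigned,
        )

    def endpoints(self) -> Tuple[str, ...]:
        """Names of the retrieval surface (exactly eight operations)."""
        return ENDPOINT_NAMES

    # -- persistence ----------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        """Write one JSON Lines file per collection plus a dataset header."""
        from .formats import write_jsonl  # local import: avoid cycle

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "dataset_id": self.dataset_id,
            "resolution_nm": list(self.resolution_nm),
            "code_tables": self.code_tables.as_dict(),
            "collections": {
                name: f"{name}.jsonl" for name in self._collections
            },
            "user_schemas": self.registry.user_schemas_as_dict(),
        }
        (directory / "header.json").write_text(json.dumps(header, indent=2))
        for name in self._collections:
            write_jsonl(self.records(name), directory / f"{name}.jsonl")

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "MetadataStore":
        from .formats import read_jsonl

        directory = Path(directory)
        header_path = directory / "header.json"
        if not header_path.exists():
            raise NotFoundError(f"no dataset header at {header_path}")
        header = json.loads(header_path.read_text())
        registry = CommunitySchemaRegistry.from_user_schemas(header.get("user_schemas", {}))
        store = cls(
            dataset_id=header["dataset_id"],
            registry=registry,
            resolution_nm=tuple(header.get("resolution_nm", (8.0, 8.0, 33.0))),
            code_tables=CodeTables.from_dict(header.get("code_tables", {})),
        )
        for name, fname in header.get("collections", {}).items():
            path = directory / fname
            if path.exists():
                store.insert_many(read_jsonl(path, registry), validate=False)
        return store
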