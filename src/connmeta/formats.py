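"""Import/export between lab-style tables and canonical entity documents.

Two interchange surfaces:

* the canonical format — one JSON object per line (JSON Lines, UTF-8,
  snake_case keys) with reserved envelope keys and all other keys treated
  as properties; undefined values are absent keys, never sentinels;
* delimited tables (CSV/TSV) as exported by annotation pipelines, imported
  through an explicit :class:`ColumnMapping` that names the id column, the
  per-column target property and type, and any integer code tables to
  translate.  Nested sub-documents and geometric vectors travel as
  JSON-encoded strings inside single cells, which keeps the tabular
  round-trip exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError
from .schema import (
    CodeTables,
    CommunitySchemaRegistry,
    DEFAULT_CODE_TABLES,
    DataRepresentation,
    EntityRecord,
    Link,
    LinkRelation,
    PropertyOrigin,
    PropertyValue,
    Uri,
    _revive_value,
    validate_entity,
)

__all__ = [
    "ColumnSpec",
    "ColumnMapping",
    "ImportReport",
    "import_table",
    "export_table",
    "write_jsonl",
    "read_jsonl",
    "default_mapping",
]

_COLUMN_TYPES = ("integer", "long", "float", "string", "boolean", "json", "code")

_DEFAULT_REPRESENTATION = {
    "neuron": DataRepresentation.SKELETON,
    "synapse": DataRepresentation.NONE,
    "layer": DataRepresentation.PIXELS,
}


@dataclass(frozen=True)
class ColumnSpec:
    """One source column: where it lands and how its cells are parsed."""

    source: str
    target: str
    type: str = "string"
    code_table: Optional[str] = None  # name of a table in CodeTables, for type "code"
    optional: bool = False

    def __post_init__(self) -> None:
        if self.type not in _COLUMN_TYPES:
            raise ConfigurationError(f"unknown column type {self.type!r}")
        if self.type == "code" and self.code_table is None:
            raise ConfigurationError(f"column {self.source!r}: type 'code' needs a code_table")


@dataclass(frozen=True)
class ColumnMapping:
    """How one delimited table maps onto entity documents of a single class."""

    entity_class: str
    id_column: str
    columns: Tuple[ColumnSpec, ...]
    constants: Mapping[str, Any] = field(default_factory=dict)
    links_column: Optional[str] = None
    representation: Optional[str] = None

    def __post_init__(self) -> None:
        sources = [c.source for c in self.columns]
        if self.id_column not in sources:
            raise ConfigurationError(
                f"id column {self.id_column!r} is not among the mapped columns"
            )
        targets = [c.target for c in self.columns]
        if len(targets) != len(set(targets)):
            raise ConfigurationError("target property keys must be unique")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ColumnMapping":
        return cls(
            entity_class=d["entity_class"],
            id_column=d["id_column"],
            columns=tuple(
                ColumnSpec(
                    source=c["source"],
                    target=c.get("target", c["source"]),
                    type=c.get("type", "string"),
                    code_table=c.get("code_table"),
                    optional=bool(c.get("optional", False)),
                )
                for c in d["columns"]
            ),
            constants=dict(d.get("constants", {})),
            links_column=d.get("links_column"),
            representation=d.get("representation"),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ColumnMapping":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class ImportReport:
    """Outcome of a tabular import: read = created + rejected."""

    rows_read: int
    records_created: int
    rejected: Tuple[Tuple[int, str], ...]  # (1-based data row number, reason)

    def as_dict(self) -> Dict[str, Any]:
        return {
            "rows_read": self.rows_read,
            "records_created": self.records_created,
            "rejected": [list(r) for r in self.rejected],
        }


def _parse_cell(raw: str, spec: ColumnSpec, tables: CodeTables) -> Any:
    if spec.type in ("integer", "long"):
        return int(raw)
    if spec.type == "float":
        return float(raw)
    if spec.type == "boolean":
        low = raw.strip().lower()
        if low in ("true", "1"):
            return True
        if low in ("false", "0"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    if spec.type == "json":
        return _revive_value(json.loads(raw))
    if spec.type == "code":
        code = int(raw)
        table = getattr(tables, spec.code_table)
        if code not in table:
            raise KeyError(f"unknown code {code} for table {spec.code_table!r}")
        return table[code]
    return raw  # string


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def import_table(
    path: Union[str, Path],
    mapping: ColumnMapping,
    registry: Optional[CommunitySchemaRegistry] = None,
    dataset_id: str = "imported",
    code_tables: CodeTables = DEFAULT_CODE_TABLES,
) -> Tuple[List[EntityRecord], ImportReport]:
    """Import a delimited annotation table into standardized documents.

    Every created record validates against the registry; rows that fail
    cell conversion, code translation, or validation are enumerated in the
    report with their 1-based data row number and a reason.  A mapped
    column missing from the file is a hard error naming the column.
    Deterministic: same file and mapping give the same records in order.
    """
    path = Path(path)
    registry = registry if registry is not None else CommunitySchemaRegistry()
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    needed = [c.source for c in mapping.columns]
    if mapping.links_column is not None:
        needed.append(mapping.links_column)
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"mapped column(s) missing from {path.name}: {', '.join(sorted(missing))}"
        )

    repr_name = mapping.representation or _DEFAULT_REPRESENTATION.get(
        mapping.entity_class, DataRepresentation.NONE
    )
    representation = DataRepresentation(repr_name)
    id_target = next(c.target for c in mapping.columns if c.source == mapping.id_column)

    records: List[EntityRecord] = []
    rejected: List[Tuple[int, str]] = []
    for row_number, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            props: Dict[str, Any] = {}
            for spec in mapping.columns:
                raw = row[spec.source]
                if raw == "":
                    if spec.optional:
                        continue
                    raise ValueError(f"required column {spec.source!r} is empty")
                props[spec.target] = _parse_cell(raw, spec, code_tables)
            for key, value in mapping.constants.items():
                props[key] = _revive_value(value)
            links: Tuple[Link, ...] = ()
            if mapping.links_column is not None and row[mapping.links_column] != "":
                links = tuple(
                    Link(LinkRelation(ln["relation"]), Uri(ln["target"]))
                    for ln in json.loads(row[mapping.links_column])
                )
            entity_id = str(props[id_target])
            is_community = registry.is_community(mapping.entity_class)
            schema = registry.schema_for(mapping.entity_class)
            schema_keys = (
                set(schema.slot_keys()) if schema is not None and is_community else set()
            )
            record = EntityRecord(
                entity_id=entity_id,
                entity_class=mapping.entity_class,
                uri=Uri(f"{dataset_id}/{mapping.entity_class}s/{entity_id}"),
                representation=representation,
                dataset_id=dataset_id,
                links=links,
                properties={
                    k: PropertyValue(
                        k,
                        v,
                        PropertyOrigin.COMMUNITY if k in schema_keys else PropertyOrigin.USER,
                    )
                    for k, v in props.items()
                },
            )
            report = validate_entity(record, registry)
            if not report.valid:
                reasons = "; ".join(i.message for i in report.errors)
                raise ValueError(f"validation failed: {reasons}")
        except KeyError as exc:
            rejected.append((row_number, f"unknown code: {exc.args[0]}"))
        except (ValueError, SchemaError) as exc:
            rejected.append((row_number, str(exc)))
        else:
            records.append(record)

    return records, ImportReport(
        rows_read=len(frame),
        records_created=len(records),
        rejected=tuple(rejected),
    )


def _jsonable(value: Any) -> Any:
    if isinstance(value, tuple):
        return [_jsonable(v) for v in value]
    if isinstance(value, list):
        return [_jsonable(v) for v in value]
    if isinstance(value, Mapping):
        return {k: _jsonable(v) for k, v in value.items()}
    return value


def export_table(
    records: Sequence[EntityRecord],
    path: Union[str, Path],
    mapping: ColumnMapping,
    code_tables: CodeTables = DEFAULT_CODE_TABLES,
) -> None:
    """Export records of one class to a delimited table (inverse of import).

    Undefined properties become empty cells; code-typed columns translate
    symbols back to their integer codes; object/vector properties are
    JSON-encoded into their cells.
    """
    path = Path(path)
    rows = []
    for record in records:
        if record.entity_class != mapping.entity_class:
            raise ConfigurationError(
                f"record class {record.entity_class!r} does not match mapping "
                f"class {mapping.entity_class!r}"
            )
        row: Dict[str, Any] = {}
        for spec in mapping.columns:
            value = record.get(spec.target)
            if value is None:
                row[spec.source] = ""
            elif spec.type == "json":
                row[spec.source] = json.dumps(_jsonable(value))
            elif spec.type == "code":
                table = getattr(code_tables, spec.code_table)
                inverse = {symbol: code for code, symbol in table.items()}
                row[spec.source] = inverse[value]
            elif spec.type == "boolean":
                row[spec.source] = "true" if value else "false"
            else:
                row[spec.source] = value
        if mapping.links_column is not None:
            row[mapping.links_column] = (
                json.dumps(
                    [{"relation": ln.relation.value, "target": str(ln.target)} for ln in record.links]
                )
                if record.links
                else ""
            )
        rows.append(row)
    columns = [c.source for c in mapping.columns]
    if mapping.links_column is not None:
        columns.append(mapping.links_column)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep=_sep_for(path), index=False)


def default_mapping(entity_class: str) -> ColumnMapping:
    """Built-in mappings for the community classes' tabular form.

    Flat numeric columns for neurons and layers; the synapse table carries
    its polarity as an integer code and its partner sub-documents, location
    and bounding box as JSON cells.
    """
    if entity_class == "neuron":
        specs = [ColumnSpec("neuron_id", "neuron_id", "integer")]
        for key in (
            "volume",
            "n_outgoing_synapses",
            "n_incoming_synapses",
            "n_incoming_excitatory",
            "n_incoming_inhibitory",
            "n_dendrite_skeleton_nodes",
            "n_axon_skeleton_nodes",
            "n_dendritic_spine_skeleton_nodes",
            "n_cilia_skeleton_nodes",
            "n_ais_skeleton_nodes",
            "n_myelinated_axon_skeleton_nodes",
            "neuron_type",
        ):
            specs.append(ColumnSpec(key, key, "long" if key == "volume" else "integer"))
        specs.append(ColumnSpec("spinyness", "spinyness", "float", optional=True))
        specs.append(ColumnSpec("layer", "layer", "integer", optional=True))
        specs.append(ColumnSpec("ei_balance", "ei_balance", "float", optional=True))
        return ColumnMapping("neuron", "neuron_id", tuple(specs), links_column="links")
    if entity_class == "synapse":
        specs = (
            ColumnSpec("synapse_id", "synapse_id", "string"),
            ColumnSpec("synapse_type", "synapse_type", "code", code_table="synapse_type"),
            ColumnSpec("presynaptic_site", "presynaptic_site", "json"),
            ColumnSpec("postsynaptic_partner", "postsynaptic_partner", "json"),
            ColumnSpec("location", "location", "json"),
            ColumnSpec("bounding_box", "bounding_box", "json"),
            ColumnSpec("layer", "layer", "integer", optional=True),
        )
        return ColumnMapping("synapse", "synapse_id", specs, links_column="links")
    if entity_class == "layer":
        specs = (
            ColumnSpec("layer_id", "layer_id", "integer"),
            ColumnSpec("width", "width", "integer"),
        )
        return ColumnMapping("layer", "layer_id", specs, links_column="links")
    raise ConfigurationError(f"no default mapping for class {entity_class!r}")


# --------------------------------------------------------------------------
# Canonical JSON Lines
# --------------------------------------------------------------------------


def write_jsonl(records: Iterable[EntityRecord], path: Union[str, Path]) -> None:
    """Write canonical entity documents, one JSON object per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for record in records:
            fh.write(json.dumps(_jsonable(record.to_document()), ensure_ascii=False))
            fh.write("\n")


def read_jsonl(
    path: Union[str, Path], registry: Optional[CommunitySchemaRegistry] = None
) -> List[EntityRecord]:
    """Read canonical entity documents; malformed lines raise with their line number."""
    path = Path(path)
    registry = registry if registry is not None else CommunitySchemaRegistry()
    records: List[EntityRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for line_number, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                doc = json.loads(line)
                records.append(EntityRecord.from_document(doc, registry))
            except (json.JSONDecodeError, SchemaError, KeyError, TypeError) as exc:
                raise SchemaError(f"{path.name}:{line_number}: malformed document: {exc}") from exc
    return records
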