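"""Round-trip annotation tables: export generated documents to CSV and
re-import them through a column mapping with integer code translation."""

import tempfile
from pathlib import Path

from connmeta import (
    GeneratorConfig,
    build_store,
    default_mapping,
    export_table,
    import_table,
    read_jsonl,
    write_jsonl,
)

store, _ = build_store(GeneratorConfig(seed=40, n_neurons=30, n_synapses=150))
synapses = store.records("synapse")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)

    # CSV export applies the code table (excitatory -> 1, inhibitory -> 2)
    # and JSON-encodes the nested partner documents into single cells.
    mapping = default_mapping("synapse")
    export_table(synapses, tmp / "synapses.csv", mapping)
    print((tmp / "synapses.csv").read_text().splitlines()[0])

    imported, report = import_table(
        tmp / "synapses.csv", mapping, dataset_id=store.dataset_id
    )
    print(f"imported {report.records_created}/{report.rows_read} rows, "
          f"{len(report.rejected)} rejected")
    print(f"identical after round-trip: {sorted(imported, key=lambda r: r.entity_id) == synapses}")

    # The canonical JSON Lines form round-trips field-for-field.
    write_jsonl(synapses, tmp / "synapses.jsonl")
    back = read_jsonl(tmp / "synapses.jsonl")
    print(f"JSONL identity: {back == synapses}")
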