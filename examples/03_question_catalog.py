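"""Enumerate the full 119-question catalog and sweep it over a dataset."""

from collections import Counter

from connmeta import (
    GeneratorConfig,
    answer,
    build_store,
    enumerate_question_catalog,
)

catalog = enumerate_question_catalog()
per_template = Counter(q.template_id for q in catalog)
print(f"catalog: {len(catalog)} questions across {len(per_template)} templates")
print(dict(sorted(per_template.items())))
# 119 = 32 + 8 + 7 + 16 + 32 + 8 + 16 with 4 synapse-type selectors and
# 8 locations (whole volume + layers 1..7).

store, _ = build_store(GeneratorConfig(seed=30, n_neurons=50, n_synapses=400))
answered = 0
for question in catalog:
    if question.template_id in ("Q6", "Q7"):
        question = question.bind(0.5)  # the free balance slot, bound at ask time
    answer(store, question)
    answered += 1
print(f"answered all {answered} catalog questions without error")
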