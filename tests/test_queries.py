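"""The seven question templates, catalog enumeration, and dispatch."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connmeta import (
    ConfigurationError,
    Location,
    MetadataStore,
    NotFoundError,
    QueryResult,
    QuestionInstance,
    SynapseTypeSelector,
    WHOLE_VOLUME,
    answer,
    enumerate_question_catalog,
    q1_count_synapses,
    q2_layer_extremum,
    q3_layer_width,
    q4_neuron_length,
    q5_top_neuron,
    q6_find_neuron_by_balance,
    q7_list_neurons_by_balance,
)
from connmeta import LayerMetadata
from helpers import store_with, toy_neuron, toy_synapse

ALL = SynapseTypeSelector.ALL
EXC = SynapseTypeSelector.EXCITATORY


# -- catalog -------------------------------------------------------------------


def test_catalog_holds_119_unique_questions_over_7_templates():
    catalog = enumerate_question_catalog()
    assert len(catalog) == 119
    assert len(set(catalog)) == 119
    assert {q.template_id for q in catalog} == {f"Q{i}" for i in range(1, 8)}


def test_catalog_per_template_counts_follow_dropdown_domains():
    from collections import Counter

    counts = Counter(q.template_id for q in enumerate_question_catalog())
    assert counts == {"Q1": 32, "Q2": 8, "Q3": 7, "Q4": 16, "Q5": 32, "Q6": 8, "Q7": 16}


def test_catalog_with_singleton_domains_has_16_instances():
    catalog = enumerate_question_catalog(
        type_domain=(ALL,), location_domain=(WHOLE_VOLUME,)
    )
    # 1 + 2 + 7 + 2 + 1 + 1 + 2: Q3 always spans the seven layers
    assert len(catalog) == 16


def test_catalog_enumeration_is_deterministic():
    assert enumerate_question_catalog() == enumerate_question_catalog()


def test_default_dropdown_domains():
    assert len(tuple(SynapseTypeSelector)) == 4
    domain = Location.domain()
    assert len(domain) == 8
    assert domain[0].is_whole_volume
    assert [loc.layer for loc in domain[1:]] == list(range(1, 8))


# -- Q1 ------------------------------------------------------------------------


def test_q1_empty_store_counts_zero():
    assert q1_count_synapses(store_with(), ALL, WHOLE_VOLUME) == 0


def test_q1_whole_volume_matches_generator_count(small_dataset):
    config, store, _ = small_dataset
    assert q1_count_synapses(store, ALL, WHOLE_VOLUME) == config.n_synapses


def test_q1_layer_count_matches_brute_force(small_dataset):
    _, store, _ = small_dataset
    expected = sum(
        1
        for d in store.documents("synapse")
        if d.get("layer") == 3 and d.get("synapse_type") == "excitatory"
    )
    assert q1_count_synapses(store, EXC, Location(3)) == expected


@settings(derandomize=True, max_examples=16, deadline=None)
@given(selector=st.sampled_from(list(SynapseTypeSelector)))
def test_q1_layer_sums_plus_unassigned_equal_whole_volume(small_dataset, selector):
    """Additivity: per-layer counts and unassigned-layer synapses partition
    the whole-volume count, for every selector."""
    _, store, _ = small_dataset
    per_layer = sum(q1_count_synapses(store, selector, Location(k)) for k in range(1, 8))
    unassigned = sum(
        1
        for d in store.documents("synapse")
        if d.get("layer") is None
        and (
            selector is ALL
            or (
                selector is SynapseTypeSelector.ONTO_AXON_INITIAL_SEGMENT
                and d["postsynaptic_partner"].get("compartment") == "axon_initial_segment"
            )
            or d.get("synapse_type") == selector.value
        )
    )
    assert per_layer + unassigned == q1_count_synapses(store, selector, WHOLE_VOLUME)


# -- Q2 ------------------------------------------------------------------------


def test_q2_most_and_fewest_with_tie_to_lowest_layer():
    synapses = [toy_synapse(f"a{i}", 1, 2, layer=1) for i in range(5)]
    synapses += [toy_synapse(f"b{i}", 1, 2, layer=2) for i in range(3)]
    store = store_with(neurons=[toy_neuron(1), toy_neuron(2)], synapses=synapses)
    assert q2_layer_extremum(store, "most", ALL) == (1, 5)
    assert q2_layer_extremum(store, "fewest", ALL) == (3, 0)  # layers 3..7 tie at 0

    tie = [toy_synapse(f"t{i}", 1, 2, layer=1 + i % 2) for i in range(4)]
    tie += [toy_synapse(f"u{i}", 1, 2, layer=3 + i % 5) for i in range(25)]
    store = store_with(neurons=[toy_neuron(1), toy_neuron(2)], synapses=tie)
    assert q2_layer_extremum(store, "fewest", ALL) == (1, 2)


def test_q2_requires_all_seven_layer_entities():
    store = MetadataStore("toy")
    store.insert(LayerMetadata(1, 100).to_record("toy"))
    with pytest.raises(ConfigurationError):
        q2_layer_extremum(store, "most", ALL)


def test_q2_consistent_with_q1_per_layer_vector(small_dataset):
    _, store, _ = small_dataset
    for selector in SynapseTypeSelector:
        counts = {k: q1_count_synapses(store, selector, Location(k)) for k in range(1, 8)}
        layer, count = q2_layer_extremum(store, "most", selector)
        assert count == max(counts.values())
        assert layer == min(k for k, v in counts.items() if v == count)
        layer, count = q2_layer_extremum(store, "fewest", selector)
        assert count == min(counts.values())
        assert layer == min(k for k, v in counts.items() if v == count)


# -- Q3 ------------------------------------------------------------------------


def test_q3_returns_stored_width_verbatim():
    store = store_with(layers=[LayerMetadata(k, 250_000 if k == 4 else 50_000 * k)
                               for k in range(1, 8)])
    assert q3_layer_width(store, 4) == 250_000


def test_q3_unknown_layer_is_not_found():
    store = store_with()
    with pytest.raises(NotFoundError):
        q3_layer_width(store, 8)


def test_q3_matches_generator_configured_widths(small_dataset):
    config, store, _ = small_dataset
    for k in range(1, 8):
        assert q3_layer_width(store, k) == config.layer_widths[k - 1]


# -- Q4 ------------------------------------------------------------------------


def test_q4_length_proxy_totals_and_averages():
    n1 = toy_neuron(1, dendrite=10, axon=5, layer=2)
    n2 = toy_neuron(2, dendrite=10, axon=5, layer=2)
    store = store_with(neurons=[n1, n2])
    assert q4_neuron_length(store, "total", WHOLE_VOLUME) == pytest.approx(30.0)
    assert q4_neuron_length(store, "average", WHOLE_VOLUME) == pytest.approx(15.0)
    assert q4_neuron_length(store, "total", Location(2)) == pytest.approx(30.0)


def test_q4_average_over_empty_location_is_undefined():
    store = store_with(neurons=[toy_neuron(1, layer=1)])
    assert q4_neuron_length(store, "average", Location(5)) is None
    assert q4_neuron_length(store, "total", Location(5)) == 0.0


def test_q4_node_spacing_scales_lengths():
    store = store_with(neurons=[toy_neuron(1, dendrite=10, axon=5)])
    assert q4_neuron_length(store, "total", WHOLE_VOLUME, node_spacing=2.5) == pytest.approx(37.5)


# -- Q5 ------------------------------------------------------------------------


def test_q5_top_neuron_counts_incoming_from_synapse_table():
    neurons = [toy_neuron(n, layer=1) for n in (3, 7, 9)]
    synapses = [toy_synapse(f"e{i}", pre=3, post=7, stype="excitatory") for i in range(4)]
    synapses += [toy_synapse(f"x{i}", pre=7, post=9, stype="excitatory") for i in range(2)]
    synapses += [toy_synapse("i0", pre=9, post=3, stype="inhibitory")]
    store = store_with(neurons=neurons, synapses=synapses)
    assert q5_top_neuron(store, EXC, WHOLE_VOLUME) == (7, 4)
    assert q5_top_neuron(store, SynapseTypeSelector.INHIBITORY, WHOLE_VOLUME) == (3, 1)


def test_q5_without_neurons_in_location_is_empty():
    store = store_with(neurons=[toy_neuron(1, layer=1)])
    assert q5_top_neuron(store, ALL, Location(6)) is None


def test_q5_ties_break_to_lowest_neuron_id():
    neurons = [toy_neuron(n) for n in (5, 2, 8)]
    store = store_with(neurons=neurons)  # nobody receives anything: 0-way tie
    assert q5_top_neuron(store, ALL, WHOLE_VOLUME) == (2, 0)


# -- Q6 / Q7 -------------------------------------------------------------------


def _balance_store():
    return store_with(
        neurons=[toy_neuron(1, e=1, i=4, layer=1),  # balance 0.2
                 toy_neuron(2, e=4, i=1, layer=2)]  # balance 0.8
    )


def test_q6_returns_nearest_defined_balance():
    assert q6_find_neuron_by_balance(_balance_store(), 0.75, WHOLE_VOLUME) == 2
    assert q6_find_neuron_by_balance(_balance_store(), 0.2, WHOLE_VOLUME) == 1
    # equidistant: ties break to the lowest neuron id
    assert q6_find_neuron_by_balance(_balance_store(), 0.5, WHOLE_VOLUME) == 1


def test_q6_with_no_defined_balances_is_empty():
    store = store_with(neurons=[toy_neuron(1), toy_neuron(2)])
    assert q6_find_neuron_by_balance(store, 0.5, WHOLE_VOLUME) is None


@pytest.mark.parametrize("bad", [-0.1, 1.5])
def test_q6_q7_reject_values_outside_unit_interval(bad):
    store = _balance_store()
    with pytest.raises(ValueError):
        q6_find_neuron_by_balance(store, bad, WHOLE_VOLUME)
    with pytest.raises(ValueError):
        q7_list_neurons_by_balance(store, "greater", bad, WHOLE_VOLUME)


def test_q7_strict_inequality_and_sorting():
    store = _balance_store()
    assert q7_list_neurons_by_balance(store, "greater", 0.5, WHOLE_VOLUME) == [2]
    assert q7_list_neurons_by_balance(store, "less", 0.5, WHOLE_VOLUME) == [1]
    assert q7_list_neurons_by_balance(store, "greater", 0.8, WHOLE_VOLUME) == []


def test_q7_greater_less_equal_partition_defined_balances(small_dataset):
    _, store, _ = small_dataset
    value = 0.8
    greater = set(q7_list_neurons_by_balance(store, "greater", value, WHOLE_VOLUME))
    less = set(q7_list_neurons_by_balance(store, "less", value, WHOLE_VOLUME))
    equal = {
        d["neuron_id"]
        for d in store.documents("neuron")
        if d.get("ei_balance") == value
    }
    defined = {
        d["neuron_id"]
        for d in store.documents("neuron")
        if d.get("ei_balance") is not None
    }
    assert greater | less | equal == defined
    assert greater & less == set()


# -- dispatch ------------------------------------------------------------------


def test_answer_dispatches_identically_to_direct_calls(small_dataset):
    _, store, _ = small_dataset
    q = QuestionInstance("Q1", type_sel=EXC, location=Location(3))
    assert answer(store, q).value == q1_count_synapses(store, EXC, Location(3))
    q = QuestionInstance("Q5", type_sel=ALL, location=WHOLE_VOLUME)
    assert answer(store, q).value == q5_top_neuron(store, ALL, WHOLE_VOLUME)


def test_unknown_template_and_malformed_instances_rejected():
    with pytest.raises(ValueError):
        QuestionInstance("Q8", location=WHOLE_VOLUME)
    with pytest.raises(ValueError):
        QuestionInstance("Q1", location=WHOLE_VOLUME)  # missing type_sel
    with pytest.raises(ValueError):
        QuestionInstance("Q3", location=WHOLE_VOLUME)  # Q3 needs one layer
    with pytest.raises(ValueError):
        QuestionInstance("Q6", location=WHOLE_VOLUME, value=1.5)


def test_q6_requires_bound_value_at_ask_time(small_dataset):
    _, store, _ = small_dataset
    unbound = QuestionInstance("Q6", location=WHOLE_VOLUME)
    with pytest.raises(ValueError):
        answer(store, unbound)
    result = answer(store, unbound.bind(0.5))
    assert result.kind in ("neuron", "empty")


def test_query_result_json_roundtrip(small_dataset):
    _, store, _ = small_dataset
    for q in (
        QuestionInstance("Q2", extremum="most", type_sel=ALL),
        QuestionInstance("Q7", direction="greater", location=Location(2)).bind(0.4),
    ):
        result = answer(store, q)
        revived = QueryResult.from_dict(json.loads(json.dumps(result.as_dict())))
        assert revived.kind == result.kind
        assert revived.question == result.question
        value = result.value if not isinstance(result.value, tuple) else tuple(result.value)
        assert revived.value == value
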