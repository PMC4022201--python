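import math

import pytest

from kgchain.chain_model import PCS, ReasoningRuleChain, halve_pcs, rrc_to_pcs
from kgchain.mr_engine import Direct, Keyed, run_job, split_key
from kgchain.oracle import brute_force_associations
from kgchain.rdf_model import TripleGraph, triple
from kgchain.reasoner_efficient import (
    efficient_map,
    efficient_reason,
    efficient_reduce,
    parity_join_key,
)
from kgchain.synthetic_network import GeneratorConfig, generate


class TestParityJoinKey:
    def test_odd_pid_keys_on_predecessor_and_subject(self):
        t1 = triple("Disease_0", "possibleDrug", "Drug_0")
        assert split_key(parity_join_key(1, t1, 6))[1:] == (0, "Disease_0")

    def test_even_pid_keys_on_own_position_and_object(self):
        t0 = triple("Herb_0", "treatment", "Disease_0")
        assert split_key(parity_join_key(0, t0, 6))[1:] == (0, "Disease_0")
        t2 = triple("Drug_0", "hasTarget", "Target_0")
        assert split_key(parity_join_key(2, t2, 6))[1:] == (2, "Target_0")

    def test_unpaired_last_even_position_has_no_key(self):
        t = triple("Protein_0", "classifiedWith|symbol", "Gene_0")
        assert parity_join_key(2, t, 3) is None

    def test_negative_pid_rejected(self):
        with pytest.raises(ValueError):
            parity_join_key(-1, triple("a", "p", "b"), 4)

    def test_pid_zero_and_one_share_a_key_exactly_when_joinable(self):
        left = triple("Herb_0", "treatment", "Disease_0")
        right = triple("Disease_0", "possibleDrug", "Drug_0")
        stranger = triple("Disease_1", "possibleDrug", "Drug_1")
        assert parity_join_key(0, left, 6) == parity_join_key(1, right, 6)
        assert parity_join_key(0, left, 6) != parity_join_key(1, stranger, 6)


class TestEfficientMap:
    def test_unpaired_tail_of_odd_length_pcs_is_direct_emitted(self):
        pcs1 = PCS.of("treatment|possibleDrug", "hasTarget|hasAccession", "classifiedWith|symbol")
        t11 = triple("Protein_0", "classifiedWith|symbol", "Gene_0")
        (emission,) = efficient_map(t11, pcs1)
        assert isinstance(emission, Direct)
        assert emission.value == t11

    def test_paired_position_is_keyed_with_pid(self, pcs0):
        t0 = triple("Herb_0", "treatment", "Disease_0")
        (emission,) = efficient_map(t0, pcs0)
        assert isinstance(emission, Keyed)
        assert emission.value == (0, t0)

    def test_out_of_chain_triple_dropped(self, pcs0):
        assert efficient_map(triple("Target_0", "geneSequence", "Sequence_0"), pcs0) == []

    def test_first_iteration_on_worked_example_builds_three_parity_groups(self, g0, pcs0):
        keys = set()
        for t in g0:
            for emission in efficient_map(t, pcs0):
                if isinstance(emission, Keyed):
                    keys.add(emission.key)
        assert len(keys) == 3  # ceil(6/2) position pair-groups
        assert sorted(split_key(k)[1] for k in keys) == [0, 2, 4]


class TestEfficientReduce:
    def test_worked_example_head_group(self, pcs0):
        t0 = triple("Herb_0", "treatment", "Disease_0")
        t6 = triple("Herb_1", "treatment", "Disease_0")
        t1 = triple("Disease_0", "possibleDrug", "Drug_0")
        key = parity_join_key(0, t0, 6)
        derived = efficient_reduce(key, [(0, t0), (0, t6), (1, t1)], pcs0)
        assert set(derived) == {
            triple("Herb_0", "treatment|possibleDrug", "Drug_0"),
            triple("Herb_1", "treatment|possibleDrug", "Drug_0"),
        }

    def test_odd_only_group_is_empty(self, pcs0):
        t1 = triple("Disease_0", "possibleDrug", "Drug_0")
        key = parity_join_key(1, t1, 6)
        assert efficient_reduce(key, [(1, t1)], pcs0) == []

    def test_cross_product_count(self, pcs0):
        t0 = triple("Herb_0", "treatment", "Disease_0")
        key = parity_join_key(0, t0, 6)
        group = [(0, triple(f"Herb_{i}", "treatment", "Disease_0")) for i in range(2)]
        group += [(1, triple("Disease_0", "possibleDrug", f"Drug_{j}")) for j in range(2)]
        assert len(efficient_reduce(key, group, pcs0)) == 4

    def test_foreign_pid_in_group_is_an_internal_error(self, pcs0):
        t0 = triple("Herb_0", "treatment", "Disease_0")
        key = parity_join_key(0, t0, 6)
        with pytest.raises(AssertionError):
            efficient_reduce(key, [(0, t0), (3, t0)], pcs0)


class TestEfficientReason:
    def test_worked_example_three_iterations_two_associations(self, g0, pcs0):
        result = efficient_reason(g0, pcs0)
        assert result.iterations == 3
        assert {(s.identifier, o.identifier) for s, _, o in result.associations} == {
            ("Herb_0", "Gene_0"),
            ("Herb_1", "Gene_0"),
        }

    def test_first_iteration_derives_exactly_the_four_intermediate_triples(self, g0, pcs0):
        result = run_job(
            g0,
            lambda t: efficient_map(t, pcs0),
            lambda key, group: efficient_reduce(key, group, pcs0),
        )
        g1 = TripleGraph(result.reduced) | TripleGraph(result.passthrough)
        assert g1 == TripleGraph(
            [
                triple("Herb_0", "treatment|possibleDrug", "Drug_0"),
                triple("Herb_1", "treatment|possibleDrug", "Drug_0"),
                triple("Drug_0", "hasTarget|hasAccession", "Protein_0"),
                triple("Protein_0", "classifiedWith|symbol", "Gene_0"),
            ]
        )

    def test_two_chain_needs_one_iteration(self):
        graph = TripleGraph([triple("a", "p", "b"), triple("b", "q", "c")])
        result = efficient_reason(graph, PCS.of("p", "q"))
        assert result.iterations == 1
        assert {(s.identifier, o.identifier) for s, o in result.pairs} == {("a", "c")}

    @pytest.mark.parametrize("n", range(1, 11))
    def test_iteration_count_is_log_of_length_even_on_empty_graph(self, n):
        pcs = rrc_to_pcs(ReasoningRuleChain.from_properties([f"p{i}" for i in range(n)]))
        expected = math.ceil(math.log2(n)) if n >= 2 else 0
        assert efficient_reason(TripleGraph(), pcs).iterations == expected

    def test_odd_length_chain_correct_via_passthrough(self):
        props = [f"p{i}" for i in range(5)]
        graph = TripleGraph([triple(f"n{i}", props[i], f"n{i+1}") for i in range(5)])
        pcs = rrc_to_pcs(ReasoningRuleChain.from_properties(props))
        result = efficient_reason(graph, pcs)
        assert {(s.identifier, o.identifier) for s, o in result.pairs} == {("n0", "n5")}

    def test_matches_naive_and_oracle_on_random_graphs(self):
        from kgchain.reasoner_naive import naive_reason

        for seed in range(10):
            dataset = generate(
                GeneratorConfig(seed=seed + 100, out_degree=2.2, distractor_fraction=0.3)
            )
            pcs = rrc_to_pcs(dataset.rrc)
            oracle = brute_force_associations(dataset.graph, pcs)
            assert set(efficient_reason(dataset.graph, pcs).pairs) == oracle
            assert set(naive_reason(dataset.graph, pcs).pairs) == oracle
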