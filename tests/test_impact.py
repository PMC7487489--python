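import heapq

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import (
    build_network,
    enumerate_shortest_paths,
    oracle_pair_sign,
    random_signed_digraph,
)
from mignet.errors import ContractViolation
from mignet.impact import (
    PairImpact,
    gene_impact,
    mirna_impact,
    pair_impact,
    pair_sign,
    path_sign,
    rank_mirnas,
    score_pairs,
    shortest_path_length,
    summarize,
)


def unit_dijkstra(net, source, target):
    """Unit-weight Dijkstra oracle, independent of the BFS implementation."""
    dist = {source: 0}
    heap = [(0, source)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == target and d > 0:
            return d
        if d > dist.get(node, np.inf):
            continue
        for nxt in net.graph.successors(node):
            if d + 1 < dist.get(nxt, np.inf):
                dist[nxt] = d + 1
                heapq.heappush(heap, (d + 1, nxt))
    d = dist.get(target)
    return None if d is None or d == 0 else d


class TestWorkedExample:
    """Two-hop toy: an inhibitory miRNA hop then an activating gene hop."""

    def test_path_length_is_two(self, two_hop_network):
        assert shortest_path_length(two_hop_network, "mir-5", "Gene*") == 2

    def test_sign_product_is_minus_one(self, two_hop_network):
        assert path_sign(two_hop_network, ["mir-5", "Gene1", "Gene*"]) == -1

    @pytest.mark.parametrize("policy", ["majority", "lexicographic", "all_paths_mean"])
    def test_unique_path_sign_independent_of_policy(self, two_hop_network, policy):
        assert pair_sign(two_hop_network, "mir-5", "Gene*", policy) == -1

    def test_direct_target_edge_has_length_one(self, two_hop_network):
        assert shortest_path_length(two_hop_network, "mir-5", "Gene1") == 1


class TestShortestPathLength:
    def test_unreachable_is_none_and_unknown_node_raises(self, two_hop_network):
        assert shortest_path_length(two_hop_network, "Gene1", "mir-5") is None
        with pytest.raises(KeyError):
            shortest_path_length(two_hop_network, "mir-5", "nope")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_unit_weight_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net, mir, genes = random_signed_digraph(rng, 100, edge_prob=0.03)
        for gene in genes[:30]:
            assert shortest_path_length(net, mir, gene) == unit_dijkstra(net, mir, gene)


class TestPathSign:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=8))
    def test_equals_parity_of_inhibitory_edges(self, signs):
        nodes = [f"n{i}" for i in range(len(signs) + 1)]
        net = build_network(
            [(nodes[i], nodes[i + 1], s) for i, s in enumerate(signs)]
        )
        expected = (-1) ** sum(1 for s in signs if s == -1)
        assert path_sign(net, nodes) == expected

    def test_two_inhibitory_edges_cancel(self):
        net = build_network([("a", "b", -1), ("b", "c", -1)])
        assert path_sign(net, ["a", "b", "c"]) == 1

    def test_non_path_rejected(self, two_hop_network):
        with pytest.raises(ContractViolation):
            path_sign(two_hop_network, ["Gene1", "mir-5"])


class TestPairSign:
    def test_tie_between_equal_length_paths_is_ambiguous(self):
        net = build_network(
            [("m", "a", 1), ("m", "b", -1), ("a", "t", 1), ("b", "t", 1)]
        )
        assert pair_sign(net, "m", "t", "majority") == 0
        assert pair_sign(net, "m", "t", "all_paths_mean") == 0
        # lexicographic resolves through the 'a' branch
        assert pair_sign(net, "m", "t", "lexicographic") == 1

    def test_unreachable_pair_is_contract_violation(self, two_hop_network):
        with pytest.raises(ContractViolation, match="unreachable"):
            pair_sign(two_hop_network, "Gene*", "Gene1")

    @pytest.mark.parametrize("policy", ["majority", "lexicographic", "all_paths_mean"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration_oracle(self, seed, policy):
        rng = np.random.default_rng(seed)
        net, mir, genes = random_signed_digraph(
            rng, int(rng.integers(4, 12)), edge_prob=0.35
        )
        checked = 0
        for gene in genes:
            L, paths = enumerate_shortest_paths(net, mir, gene)
            if L is None:
                assert shortest_path_length(net, mir, gene) is None
                continue
            expected_L, expected_S = oracle_pair_sign(net, mir, gene, policy)
            assert shortest_path_length(net, mir, gene) == expected_L
            assert pair_sign(net, mir, gene, policy) == expected_S
            checked += 1
        assert checked > 0


class TestPairImpact:
    def test_zero_fold_change_zero_impact(self, two_hop_network):
        pi = pair_impact(two_hop_network, "mir-5", "Gene*", log2fc=0.0)
        assert pi.I == 0.0

    def test_two_hop_inhibition_with_plugin_fold_change(self, two_hop_network):
        pi = pair_impact(two_hop_network, "mir-5", "Gene*", log2fc=2.25)
        assert pi.L == 2 and pi.S == -1
        assert pi.I == pytest.approx(-1.125)

    def test_doubling_path_length_halves_magnitude(self):
        chain2 = build_network([("a", "t", 1)], [("m", "a")], {"t": "apoptosis"})
        chain4 = build_network(
            [("a", "b", 1), ("b", "c", 1), ("c", "t", 1)],
            [("m", "a")],
            {"t": "apoptosis"},
        )
        short = pair_impact(chain2, "m", "t", log2fc=1.8)
        long = pair_impact(chain4, "m", "t", log2fc=1.8)
        assert short.L * 2 == long.L
        assert abs(long.I) == pytest.approx(abs(short.I) / 2)

    def test_unreachable_pair_returns_none(self):
        net = build_network([("a", "t", 1)], [("m", "a")], {"t": "apoptosis"})
        net.graph.add_node("island", kind="gene")
        assert pair_impact(net, "m", "island", log2fc=1.0) is None

    def test_magnitude_bounded_by_fold_change(self):
        rng = np.random.default_rng(31)
        for seed in range(5):
            net, mir, genes = random_signed_digraph(np.random.default_rng(seed), 10)
            fc = float(rng.normal(0, 3))
            for gene in genes:
                if shortest_path_length(net, mir, gene) is not None:
                    pi = pair_impact(net, mir, gene, log2fc=fc)
                    assert abs(pi.I) <= abs(fc) + 1e-15

    def test_invalid_length_or_sign_rejected(self):
        with pytest.raises(ContractViolation):
            PairImpact("m", "g", 0, 1, 1.0)
        with pytest.raises(ContractViolation):
            PairImpact("m", "g", 1, 2, 1.0)


def two_mirna_fixture():
    """Two miRNAs converging on two sinks through a shared middle gene."""
    return build_network(
        gene_edges=[("a", "t1", 1), ("a", "t2", -1), ("b", "t2", 1)],
        mirna_edges=[("m1", "a"), ("m2", "a"), ("m2", "b")],
        cell_fate={"t1": "proliferation", "t2": "apoptosis"},
    )


class TestAggregation:
    def test_singleton_and_cancelling_sums(self):
        pairs = pd.DataFrame(
            {
                "mirna": ["m1", "m1", "m2"],
                "gene": ["g1", "g2", "g1"],
                "I": [-1.125, 0.5, -0.5],
            }
        )
        assert gene_impact(pairs, "g2") == pytest.approx(0.5)
        assert gene_impact(pairs, "g1") == pytest.approx(-1.625)
        assert mirna_impact(pairs, "m2") == pytest.approx(-0.5)

    def test_totals_match_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        net, mir, genes = random_signed_digraph(rng, 15, edge_prob=0.2)
        fate = {g: "proliferation" for g in genes[:4]}
        fate[genes[4]] = "apoptosis"
        net.cell_fate.update(fate)
        fc = {mir: 1.7}
        pairs = score_pairs(net, fc)
        for gene in fate:
            expected = sum(
                row.I for row in pairs.itertuples() if row.gene == gene
            )
            assert gene_impact(pairs, gene) == pytest.approx(expected)
        assert mirna_impact(pairs, mir) == pytest.approx(pairs["I"].sum())

    @pytest.mark.parametrize("seed", range(6))
    def test_global_conservation(self, seed):
        rng = np.random.default_rng(seed)
        net, mir, genes = random_signed_digraph(rng, 12, edge_prob=0.3)
        net.cell_fate.update({g: "apoptosis" for g in genes[:5]})
        summary = summarize(net, {mir: float(rng.normal(0, 2))})
        lhs = summary.gene_table["I_gene"].sum()
        rhs = summary.mirna_table["I_miR"].sum()
        assert abs(lhs - rhs) < 1e-9
        assert abs(lhs - summary.pair_table["I"].sum()) < 1e-9

    def test_gene_without_upstream_mirna_flagged_zero(self):
        net = build_network([("a", "t1", 1)], [("m", "a")], {"t1": "proliferation"})
        net.graph.add_node("orphan", kind="gene")
        net.cell_fate["orphan"] = "apoptosis"
        summary = summarize(net, {"m": 1.0})
        assert summary.gene_table.loc["orphan", "I_gene"] == 0.0
        assert bool(summary.gene_table.loc["orphan", "no_upstream"])


class TestRanking:
    def test_absolute_value_ordering(self):
        assert rank_mirnas({"a": -3.0, "b": 2.0, "c": -1.0}, k=2) == ["a", "b"]

    def test_ties_break_lexicographically(self):
        assert rank_mirnas({"b": 1.0, "a": -1.0}, k=2) == ["a", "b"]

    def test_k_larger_than_population(self):
        assert rank_mirnas({"a": 1.0}, k=10) == ["a"]

    def test_summary_rank_column_matches_ranking(self):
        net = two_mirna_fixture()
        summary = summarize(net, {"m1": 3.0, "m2": -0.5})
        assert summary.ranking == list(summary.mirna_table.index)
        assert list(summary.mirna_table["rank"]) == [1, 2]


class TestStructuralProperties:
    def test_impact_decays_when_paths_lengthen(self):
        # same sign structure, progressively longer unique path
        for extra in range(4):
            inner = [f"x{i}" for i in range(extra)]
            chain = ["a"] + inner + ["t"]
            gene_edges = [(u, v, 1) for u, v in zip(chain, chain[1:])]
            net = build_network(gene_edges, [("m", "a")], {"t": "apoptosis"})
            pi = pair_impact(net, "m", "t", log2fc=2.0)
            assert abs(pi.I) == pytest.approx(2.0 / (2 + extra))

    def test_odd_inhibitory_parity_anticorrelates_impact_with_fold_change(self):
        # all-activating gene layer: every route has exactly one inhibitory
        # edge (the miRNA hop), so sign(I_miR) == -sign(log2fc).
        net = build_network(
            [("a", "t1", 1), ("a", "t2", 1), ("b", "t2", 1)],
            [("up", "a"), ("down", "b")],
            {"t1": "proliferation", "t2": "apoptosis"},
        )
        summary = summarize(net, {"up": 2.5, "down": -1.5})
        assert summary.mirna_table.loc["up", "I_miR"] < 0
        assert summary.mirna_table.loc["down", "I_miR"] > 0

    def test_score_pairs_deterministic(self):
        rng = np.random.default_rng(8)
        net, mir, genes = random_signed_digraph(rng, 12)
        net.cell_fate.update({g: "proliferation" for g in genes[:4]})
        first = score_pairs(net, {mir: 1.3})
        second = score_pairs(net, {mir: 1.3})
        pd.testing.assert_frame_equal(first, second)

    def test_ambiguous_pairs_carry_zero_impact(self):
        net = build_network(
            [("a", "t", 1), ("b", "t", -1)],
            [("m", "a"), ("m", "b")],
            {"t": "apoptosis"},
        )
        pairs = score_pairs(net, {"m": 2.0})
        row = pairs.iloc[0]
        assert bool(row["ambiguous"]) and row["I"] == 0.0 and row["S"] == 0
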