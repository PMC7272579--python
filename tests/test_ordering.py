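import networkx as nx
import numpy as np
import pytest

from conftest import make_module, random_connected_graph
from tippingnet.io import GeneNetwork
from tippingnet.ordering import (
    MutationSequence,
    consensus_order,
    derive_order,
    enumerate_sequences,
    kendall_tau,
    merged_cluster_size,
    pairwise_precedence,
)
from tippingnet.patient import PatientNetwork


def seq(*genes, pid="P1"):
    return MutationSequence(
        patient_id=pid, genes=list(genes), fallback_flags=[False] * len(genes)
    )


class TestMergedClusterSize:
    def test_path_growth(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "W")])
        assert merged_cluster_size({"A", "B"}, make_module("W", {"B", "W"}), net) == 3

    def test_star_growth(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "X"), ("B", "Y"), ("B", "Z")])
        module = make_module("X", {"B", "X", "Y", "Z"})
        assert merged_cluster_size({"A", "B"}, module, net) == 5

    def test_contained_module_no_growth(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C")])
        module = make_module("B", {"A", "B"})
        assert merged_cluster_size({"A", "B", "C"}, module, net) == 3

    def test_disjoint_module_rejected(self):
        net = GeneNetwork.from_edges([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError):
            merged_cluster_size({"A", "B"}, make_module("C", {"C", "D"}), net)


def toy_patient(edges, seeds):
    net = GeneNetwork.from_edges(edges)
    return PatientNetwork(patient_id="P1", network=net, seeds=set(seeds))


class TestEnumerateSequences:
    def test_one_sequence_per_nondriver_initial(self):
        patient = toy_patient([("A", "B"), ("B", "C")], {"A", "B", "C"})
        modules = {
            "A": make_module("A", {"A", "B"}),
            "B": make_module("B", {"A", "B", "C"}),
            "C": make_module("C", {"B", "C"}),
        }
        sequences = enumerate_sequences(patient, modules, drivers={"C"})
        assert len(sequences) == 2  # initials A and B only
        assert {s.genes[0] for s in sequences} == {"A", "B"}
        for s in sequences:
            assert sorted(s.genes) == ["A", "B", "C"]

    def test_disjoint_modules_all_fallback(self):
        patient = toy_patient([("A", "B"), ("C", "D"), ("E", "F")], {"A", "C", "E"})
        modules = {
            "A": make_module("A", {"A", "B"}),
            "C": make_module("C", {"C", "D"}),
            "E": make_module("E", {"E", "F"}),
        }
        sequences = enumerate_sequences(patient, modules, drivers=set())
        for s in sequences:
            assert s.fallback_flags[0] is False  # initial is never a fallback
            assert all(s.fallback_flags[1:])

    def test_no_nondriver_seeds_yields_empty(self):
        patient = toy_patient([("A", "B")], {"A"})
        modules = {"A": make_module("A", {"A", "B"})}
        assert enumerate_sequences(patient, modules, drivers={"A"}) == []

    def test_greedy_matches_exhaustive_argmin(self):
        """Each greedy choice equals the brute-force minimal-growth candidate."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(12, 40))
            net = random_connected_graph(rng, n, p=0.08)
            nodes = sorted(net.nodes)
            n_seeds = int(rng.integers(2, 9))
            seeds = list(rng.choice(nodes, size=n_seeds, replace=False))
            modules = {}
            for s in seeds:
                ball = list(nx.single_source_shortest_path_length(net.graph, s, cutoff=2))
                size = min(len(ball), int(rng.integers(2, 7)))
                members = {s} | set(rng.choice(ball, size=size, replace=False))
                modules[s] = make_module(s, members)
            patient = PatientNetwork(patient_id="PX", network=net, seeds=set(seeds))
            sequences = enumerate_sequences(patient, modules, drivers=set())
            for s in sequences:
                current = set(modules[s.genes[0]].members)
                remaining = sorted(set(seeds) - {s.genes[0]})
                for pos, chosen in enumerate(s.genes[1:], start=1):
                    overlapping = [
                        c for c in remaining if modules[c].members & current
                    ]
                    if overlapping:
                        assert not s.fallback_flags[pos]
                        best = min(
                            overlapping,
                            key=lambda c: (
                                merged_cluster_size(current, modules[c], net),
                                c,
                            ),
                        )
                        assert chosen == best
                    else:
                        assert s.fallback_flags[pos]
                    current |= modules[chosen].members
                    remaining.remove(chosen)

    def test_determinism(self):
        patient = toy_patient([("A", "B"), ("B", "C"), ("C", "D")], {"A", "B", "C", "D"})
        modules = {
            g: make_module(g, {g, n})
            for g, n in [("A", "B"), ("B", "C"), ("C", "D"), ("D", "C")]
        }
        runs = [enumerate_sequences(patient, modules, drivers=set()) for _ in range(3)]
        as_tuples = [tuple(tuple(s.genes) for s in run) for run in runs]
        assert len(set(as_tuples)) == 1


class TestPrecedence:
    def test_hand_counted_example(self):
        matrix = pairwise_precedence([seq("A", "B", "C"), seq("B", "A", "C")])
        assert matrix.get("A", "B") == 1
        assert matrix.get("B", "A") == 1
        assert matrix.get("A", "C") == 2
        assert matrix.get("B", "C") == 2

    def test_single_sequence_indicator(self):
        matrix = pairwise_precedence([seq("X", "Y")])
        assert matrix.get("X", "Y") == 1 and matrix.get("Y", "X") == 0

    def test_identity_pair_totals(self):
        """C[i][j] + C[j][i] equals the number of sequences containing both."""
        rng = np.random.default_rng(3)
        genes = list("ABCDEF")
        sequences = []
        for i in range(12):
            k = int(rng.integers(2, len(genes) + 1))
            chosen = list(rng.choice(genes, size=k, replace=False))
            sequences.append(seq(*chosen, pid=f"P{i}"))
        matrix = pairwise_precedence(sequences)
        for i in genes:
            for j in genes:
                if i >= j:
                    continue
                both = sum(1 for s in sequences if i in s.genes and j in s.genes)
                assert matrix.get(i, j) + matrix.get(j, i) == both


class TestDeriveOrder:
    def test_copeland_with_lexicographic_tie(self):
        matrix = pairwise_precedence([seq("A", "B", "C"), seq("B", "A", "C")])
        order = derive_order(matrix, {"A", "B", "C"})
        assert order.genes == ["A", "B", "C"]
        assert order.copeland["A"] == order.copeland["B"] == 1
        assert order.copeland["C"] == -2

    def test_consistent_sequences_keep_order(self):
        matrix = pairwise_precedence([seq("C", "A", "B"), seq("C", "A", "B")])
        assert derive_order(matrix, {"A", "B", "C"}).genes == ["C", "A", "B"]

    def test_single_gene(self):
        matrix = pairwise_precedence([seq("A", "B")])
        assert derive_order(matrix, {"A"}).genes == ["A"]

    def test_empty_restriction_rejected(self):
        matrix = pairwise_precedence([seq("A", "B")])
        with pytest.raises(ValueError):
            derive_order(matrix, set())


class TestConsensus:
    def test_scaling_invariance(self):
        m = pairwise_precedence([seq("A", "B", "C")])
        one = consensus_order([m], {"A", "B", "C"}, label="x")
        two = consensus_order([m, m], {"A", "B", "C"}, label="x")
        assert one.genes == two.genes

    def test_reversed_pair_ties_lexicographically(self):
        m1 = pairwise_precedence([seq("A", "B")])
        m2 = pairwise_precedence([seq("B", "A")])
        assert consensus_order([m1, m2], {"A", "B"}, label="x").genes == ["A", "B"]


class TestKendallTau:
    def test_identical_and_reversed(self):
        assert kendall_tau(list("ABCD"), list("ABCD")) == 1.0
        assert kendall_tau(list("ABCD"), list("DCBA")) == -1.0

    def test_partial_overlap(self):
        assert kendall_tau(["A", "B", "X"], ["A", "B", "Y"]) == 1.0
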