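import networkx as nx
import numpy as np
import pytest

from conftest import make_module, random_connected_graph
from tippingnet.io import GeneNetwork
from tippingnet.propagation import (
    build_giant_cluster,
    build_module,
    column_normalize,
    rwr,
    seed_coverage,
)


def direct_solve(network: GeneNetwork, seed: str, r: float) -> dict[str, float]:
    """Closed-form stationary solution p = r (I - (1-r) M)^-1 e_seed."""
    tm = column_normalize(network)
    n = len(tm.nodes)
    m = tm.matrix.toarray()
    e = np.zeros(n)
    e[tm.index[seed]] = 1.0
    p = r * np.linalg.solve(np.eye(n) - (1 - r) * m, e)
    return dict(zip(tm.nodes, p))


class TestColumnNormalize:
    def test_path_middle_column(self, path_abc):
        tm = column_normalize(path_abc)
        col_b = tm.matrix.toarray()[:, tm.index["B"]]
        expected = {"A": 0.5, "B": 0.0, "C": 0.5}
        assert col_b == pytest.approx([expected[n] for n in tm.nodes])

    def test_single_edge(self):
        net = GeneNetwork.from_edges([("A", "B")])
        tm = column_normalize(net)
        assert tm.matrix.toarray().tolist() == [[0.0, 1.0], [1.0, 0.0]]

    def test_triangle_half_entries(self, triangle):
        m = column_normalize(triangle).matrix.toarray()
        assert np.allclose(m.sum(axis=0), 1.0)
        assert sorted(np.unique(m)) == [0.0, 0.5]


class TestRWR:
    def test_triangle_closed_form(self, triangle):
        res = rwr(triangle, "A", r=0.7)
        expected = {"A": 17 / 23, "B": 3 / 23, "C": 3 / 23}
        for gene, want in expected.items():
            assert res.score(gene) == pytest.approx(want, abs=1e-9)

    def test_restart_dominance_near_one(self, triangle):
        res = rwr(triangle, "A", r=0.999)
        assert res.score("A") == pytest.approx(1.0, abs=2e-3)

    def test_disconnected_component_scores_zero(self):
        net = GeneNetwork.from_edges([("A", "B"), ("C", "D")])
        res = rwr(net, "A", r=0.7)
        assert res.score("C") == 0.0 and res.score("D") == 0.0
        assert res.score("A") + res.score("B") == pytest.approx(1.0)

    def test_unknown_seed(self, triangle):
        with pytest.raises(KeyError):
            rwr(triangle, "ZZ")

    def test_bad_restart_probability(self, triangle):
        with pytest.raises(ValueError):
            rwr(triangle, "A", r=1.0)

    def test_iterative_matches_direct_solve_on_random_graphs(self):
        """Power iteration agrees with the linear-solve oracle to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 201))
            net = random_connected_graph(rng, n)
            seed = sorted(net.nodes)[int(rng.integers(n))]
            r = float(rng.uniform(0.2, 0.9))
            res = rwr(net, seed, r=r)
            oracle = direct_solve(net, seed, r)
            err = max(abs(res.score(g) - oracle[g]) for g in net.nodes)
            assert err < 1e-8
            # contracts: conservation, seed floor, nonnegativity
            assert res.scores.sum() == pytest.approx(1.0, abs=1e-9)
            assert res.score(seed) >= r
            assert (res.scores >= 0).all()


class TestModules:
    def test_threshold_keeps_all_triangle_nodes(self, triangle):
        res = rwr(triangle, "A", r=0.7)
        assert build_module(res, threshold=0.001).members == {"A", "B", "C"}

    def test_threshold_strictness(self, triangle):
        res = rwr(triangle, "A", r=0.7)
        # 3/23 ~ 0.1304 < 0.2 -> only the seed survives
        assert build_module(res, threshold=0.2).members == {"A"}
        # exactly at a score: strict > excludes it
        at_score = res.score("B")
        assert "B" not in build_module(res, threshold=at_score).members

    def test_empty_module_allowed_above_seed_score(self, triangle):
        res = rwr(triangle, "A", r=0.7)
        assert build_module(res, threshold=0.9).members == set()

    def test_members_monotone_in_threshold(self, triangle):
        res = rwr(triangle, "A", r=0.7)
        thresholds = [0.0005, 0.01, 0.1, 0.5, 0.74]
        previous = None
        for t in thresholds:
            members = build_module(res, threshold=t).members
            if previous is not None:
                assert members <= previous
            previous = members


class TestGiantCluster:
    def test_union_components(self):
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("D", "E")])
        modules = [
            make_module("A", {"A", "B"}),
            make_module("C", {"B", "C"}),
            make_module("D", {"D", "E"}),
        ]
        gc = build_giant_cluster(modules, net)
        assert gc.genes == {"A", "B", "C"}
        assert gc.contributing_seeds == {"A", "C"}

    def test_single_module_internal_component(self):
        net = GeneNetwork.from_edges([("A", "B"), ("C", "D"), ("D", "E")])
        gc = build_giant_cluster([make_module("D", {"A", "C", "D", "E"})], net)
        assert gc.genes == {"C", "D", "E"}

    def test_tie_broken_by_seed_count_then_lexicographic(self):
        net = GeneNetwork.from_edges([("A", "B"), ("C", "D")])
        modules = [
            make_module("A", {"A", "B"}),
            make_module("B", {"A", "B"}),
            make_module("C", {"C", "D"}),
        ]
        gc = build_giant_cluster(modules, net)
        assert gc.genes == {"A", "B"}  # two seeds beat one
        modules = [make_module("C", {"C", "D"}), make_module("A", {"A", "B"})]
        gc = build_giant_cluster(modules, net)
        assert gc.genes == {"A", "B"}  # equal seeds: lexicographic

    def test_empty_modules_rejected(self, triangle):
        with pytest.raises(ValueError):
            build_giant_cluster([make_module("A", set())], triangle)

    def test_maximality_against_brute_force(self):
        """The GC is never smaller than any component of the union subgraph."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            net = random_connected_graph(rng, n, p=0.03)
            nodes = sorted(net.nodes)
            modules = []
            for s in range(int(rng.integers(1, 6))):
                size = int(rng.integers(1, 8))
                members = set(rng.choice(nodes, size=size, replace=False))
                seed = sorted(members)[0]
                members.add(seed)
                modules.append(make_module(seed, members))
            gc = build_giant_cluster(modules, net)
            union = set().union(*(m.members for m in modules))
            comps = list(nx.connected_components(net.graph.subgraph(union)))
            assert gc.size == max(len(c) for c in comps)


class TestSeedCoverage:
    def test_fraction(self):
        from tippingnet.propagation import GiantCluster

        gc_seeds = {f"S{i}" for i in range(9)}
        gc = GiantCluster(genes=set(), contributing_seeds=gc_seeds)
        all_seeds = {f"S{i}" for i in range(10)}
        assert seed_coverage(gc, all_seeds) == pytest.approx(0.9)
        assert seed_coverage(gc, gc_seeds) == 1.0

    def test_empty_seed_set_rejected(self):
        from tippingnet.propagation import GiantCluster

        with pytest.raises(ValueError):
            seed_coverage(GiantCluster(genes=set(), contributing_seeds=set()), set())
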