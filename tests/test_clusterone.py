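"""Cohesiveness growth, overlap merging and Mann–Whitney significance."""

import itertools
import random

import numpy as np
import pytest
from scipy import stats as sps

from ppicluster.clusterone import (
    DEFAULT_PENALTY,
    ClusterParams,
    cluster_one,
    cluster_significance,
    cohesiveness,
    grow_from_seed,
    overlap_score,
)
from ppicluster.discovery import clusters_tsv
from ppicluster.graph import ValidationError, cluster_stats

from conftest import clique_edges, net_from_edges


def growth_quality(members, net, penalty):
    """Independent recomputation of the growth objective."""
    s = cluster_stats(members, net)
    denom = s.m_internal + s.m_boundary + penalty * len(members)
    return s.m_internal / denom if denom > 0 else 1.0


def is_growth_local_max(members, net, penalty=DEFAULT_PENALTY):
    """No single-node addition or removal improves the growth quality."""
    members = set(members)
    q = growth_quality(members, net, penalty)
    external = {
        v for u in members for v in net.g.neighbors(u) if v not in members
    }
    for v in sorted(external):
        if growth_quality(members | {v}, net, penalty) > q + 1e-12:
            return False
    if len(members) > 1:
        for u in sorted(members):
            if growth_quality(members - {u}, net, penalty) > q + 1e-12:
                return False
    return True


class TestCohesiveness:
    def test_isolated_clique(self):
        net = net_from_edges(clique_edges(["A", "B", "C", "D"]))
        assert cohesiveness({"A", "B", "C", "D"}, net) == 1.0

    def test_triangle_with_three_outgoing(self):
        edges = clique_edges(["A", "B", "C"]) + [("A", "X"), ("B", "Y"), ("C", "Z")]
        net = net_from_edges(edges)
        assert cohesiveness({"A", "B", "C"}, net) == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        net = net_from_edges([("A", "B")])
        with pytest.raises(ValidationError):
            cohesiveness(set(), net)


class TestGrowFromSeed:
    def test_clique_attached_by_one_edge(self):
        clique = ["C1", "C2", "C3", "C4", "C5"]
        edges = clique_edges(clique) + [("C1", "OUT"), ("OUT", "FAR")]
        net = net_from_edges(edges)
        members, trace = grow_from_seed("C3", net)
        assert members == frozenset(clique)
        assert is_growth_local_max(members, net)
        # quality strictly increases along the recorded moves
        qs = [q for _, _, q in trace.moves]
        assert qs == sorted(qs) and len(set(qs)) == len(qs)

    def test_isolated_node_singleton(self):
        net = net_from_edges([("A", "B")], nodes=["LONE"])
        members, _ = grow_from_seed("LONE", net)
        assert members == frozenset({"LONE"})
        assert cohesiveness(members, net) == 1.0

    def test_bridge_seed_terminates_at_local_max(self, two_cliques_bridged):
        members, _ = grow_from_seed("A0", two_cliques_bridged)
        assert is_growth_local_max(members, two_cliques_bridged)

    def test_unknown_seed_rejected(self):
        net = net_from_edges([("A", "B")])
        with pytest.raises(ValidationError):
            grow_from_seed("NOPE", net)

    @pytest.mark.parametrize("penalty", [0.0, DEFAULT_PENALTY])
    def test_every_growth_ends_at_local_max(self, penalty):
        rng = random.Random(11)
        names = [f"N{i}" for i in range(12)]
        edges = [
            (a, b) for a, b in itertools.combinations(names, 2)
            if rng.random() < 0.25
        ]
        net = net_from_edges(edges, nodes=names)
        for seed in net.nodes:
            members, _ = grow_from_seed(seed, net, penalty)
            assert is_growth_local_max(members, net, penalty)


class TestOverlapScore:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"A", "B", "C"}, 1.0),
            ({"A", "B"}, {"X", "Y"}, 0.0),
            ({"A", "B", "C", "D"}, {"A", "B", "C", "D", "E"}, 16 / 20),
        ],
    )
    def test_match_coefficient(self, a, b, expected):
        assert overlap_score(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        a, b = {"A", "B", "C"}, {"B", "C", "D", "E"}
        assert overlap_score(a, b) == overlap_score(b, a)


class TestSignificance:
    def test_clear_separation_small_p(self):
        # 10-node group: every member has intra-degree 5, boundary 0
        # (e.g. two disjoint 6-cliques would do; build directly)
        names = [f"C{i}" for i in range(6)]
        others = [f"D{i}" for i in range(6)]
        net = net_from_edges(clique_edges(names) + clique_edges(others))
        p = cluster_significance(set(names) | set(), net)
        # intra-degrees all 5, boundary all 0 -> strongest separation
        assert p < 0.01
        ten = net_from_edges(
            clique_edges([f"E{i}" for i in range(10)])
            + clique_edges([f"F{i}" for i in range(10)])
        )
        assert cluster_significance({f"E{i}" for i in range(10)}, ten) < 0.001

    def test_no_separation(self):
        # a 4-cycle half-in half-out: every member has intra 1, boundary 1
        net = net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        p = cluster_significance({"A", "B"}, net)
        assert p >= 0.5

    def test_singleton_returns_one(self, caplog):
        net = net_from_edges([("A", "B")])
        assert cluster_significance({"A"}, net) == 1.0

    def test_exact_agrees_with_full_enumeration(self):
        """Exact path equals itertools enumeration of all U outcomes."""
        rng = random.Random(5)
        for _ in range(8):
            n = rng.randint(3, 8)
            names = [f"N{i}" for i in range(n + rng.randint(2, 5))]
            edges = [
                (a, b) for a, b in itertools.combinations(names, 2)
                if rng.random() < 0.45
            ]
            net = net_from_edges(edges, nodes=names)
            members = set(rng.sample(names, n))
            intra, boundary = [], []
            for u in sorted(members):
                intra.append(sum(1 for w in net.neighbors(u) if w in members))
                boundary.append(sum(1 for w in net.neighbors(u) if w not in members))
            pooled = np.array(intra + boundary, float)
            ranks = sps.rankdata(pooled)
            obs = ranks[: len(intra)].sum()
            hits = total = 0
            for idx in itertools.combinations(range(len(pooled)), len(intra)):
                total += 1
                if ranks[list(idx)].sum() >= obs - 1e-9:
                    hits += 1
            assert cluster_significance(members, net) == pytest.approx(
                hits / total, abs=1e-12
            )

    def test_large_groups_use_tie_corrected_normal(self):
        names = [f"G{i}" for i in range(14)]
        net = net_from_edges(
            clique_edges(names) + [(n, f"OUT{i}") for i, n in enumerate(names[:4])]
        )
        p = cluster_significance(set(names), net)
        expected = sps.mannwhitneyu(
            [13] * 14, [1] * 4 + [0] * 10,
            alternative="greater", method="asymptotic",
        ).pvalue
        assert p == pytest.approx(expected)


class TestClusterOne:
    def test_two_cliques_sharing_one_node(self):
        a = [f"A{i}" for i in range(6)]
        b = [f"B{i}" for i in range(6)]
        shared = "SH"
        net = net_from_edges(
            clique_edges(a + [shared]) + clique_edges(b + [shared])
        )
        result = cluster_one(net)
        member_sets = {c.members for c in result.clusters}
        assert frozenset(a + [shared]) in member_sets
        assert frozenset(b + [shared]) in member_sets

    def test_sparse_path_graph_yields_nothing(self):
        edges = [(f"P{i}", f"P{i+1}") for i in range(12)]
        assert len(cluster_one(net_from_edges(edges)).clusters) == 0

    def test_filters_respected(self):
        rng = random.Random(23)
        names = [f"N{i}" for i in range(25)]
        edges = [
            (a, b) for a, b in itertools.combinations(names, 2)
            if rng.random() < 0.2
        ]
        net = net_from_edges(edges, nodes=names)
        params = ClusterParams()
        for c in cluster_one(net, params).clusters:
            assert len(c.members) >= params.min_size
            assert c.stats.density >= params.min_density

    def test_deterministic_byte_identical(self, two_cliques_bridged):
        r1 = cluster_one(two_cliques_bridged)
        r2 = cluster_one(two_cliques_bridged)
        assert clusters_tsv(r1.clusters) == clusters_tsv(r2.clusters)

    def test_returned_clusters_are_local_maxima(self):
        rng = random.Random(31)
        names = [f"N{i}" for i in range(20)]
        edges = [
            (a, b) for a, b in itertools.combinations(names, 2)
            if rng.random() < 0.25
        ]
        net = net_from_edges(edges, nodes=names)
        for c in cluster_one(net).clusters:
            assert is_growth_local_max(c.members, net)

    def test_seeding_from_module_subset_finds_same_module_clusters(self):
        """Growth seeded only from planted-module nodes recovers the same
        accepted module clusters as seeding from every node."""
        from ppicluster.synthdata import PlantedSpec, planted_network

        spec = PlantedSpec(
            module_sizes=(9, 9), intra_p=0.95, inter_p=0.02,
            n_background=12, background_p=0.02, rng_seed=4,
        )
        net, truth = planted_network(spec)
        module_nodes = sorted(truth.modules[0] | truth.modules[1])
        full = cluster_one(net)
        partial = cluster_one(net, seed_nodes=module_nodes)

        def module_clusters(result):
            out = set()
            for c in result.clusters:
                for mod in truth.modules:
                    if len(mod & c.members) / len(mod | c.members) >= 0.8:
                        out.add(c.members)
            return out

        assert module_clusters(full) == module_clusters(partial)
        assert len(module_clusters(full)) == 2
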