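"""Recursive partitioning, residual subtraction and candidate ranking."""

import json
import random

import pytest

from ppicluster.assembly import SeedList
from ppicluster.discovery import (
    ClusterTree,
    anchor_candidates,
    default_anchors,
    partition_recursive,
    run_discovery,
    select_target_cluster,
    subtract_residual,
    write_report,
)
from ppicluster.graph import Cluster, ClusterStats, ValidationError
from ppicluster.synthdata import discovery_scenario

from conftest import clique_edges, net_from_edges


def mk_cluster(members, quality=1.0, cid="c"):
    n = len(members)
    return Cluster(
        members=frozenset(members),
        stats=ClusterStats(n, 0, 0, 0.0, quality),
        algorithm="test",
        cluster_id=cid,
    )


class TestSelectTarget:
    def test_max_seed_coverage_wins(self):
        seeds = SeedList(("S1", "S2", "S3"))
        c1 = mk_cluster({"S1", "X"}, cid="1")
        c2 = mk_cluster({"S1", "S2", "Y"}, cid="2")
        assert select_target_cluster([c1, c2], seeds).cluster_id == "2"

    def test_single_cluster(self):
        seeds = SeedList(("S1",))
        c = mk_cluster({"S1"})
        assert select_target_cluster([c], seeds) is c

    def test_tie_broken_by_quality(self):
        seeds = SeedList(("S1",))
        lo = mk_cluster({"S1", "A"}, quality=0.4, cid="lo")
        hi = mk_cluster({"S1", "B"}, quality=0.9, cid="hi")
        assert select_target_cluster([lo, hi], seeds).cluster_id == "hi"

    def test_no_seed_anywhere_raises(self):
        seeds = SeedList(("S1",))
        with pytest.raises(ValidationError, match="loosening"):
            select_target_cluster([mk_cluster({"X", "Y"})], seeds)


class TestSubtractResidual:
    def test_set_difference(self):
        parent = mk_cluster(set("ABCDEFGHIJ"))
        kids = [mk_cluster(set("ABCD")), mk_cluster(set("EF"))]
        assert subtract_residual(parent, kids) == set("GHIJ")

    def test_children_covering_parent(self):
        parent = mk_cluster({"A", "B"})
        kids = [mk_cluster({"A"}), mk_cluster({"B"})]
        assert subtract_residual(parent, kids) == set()

    def test_randomized_matches_set_difference_oracle(self):
        rng = random.Random(2)
        for _ in range(20):
            universe = [f"P{i}" for i in range(rng.randint(3, 15))]
            parent = set(rng.sample(universe, rng.randint(2, len(universe))))
            kids = [
                set(rng.sample(sorted(parent), rng.randint(1, len(parent))))
                for _ in range(rng.randint(1, 3))
            ]
            got = subtract_residual(
                mk_cluster(parent), [mk_cluster(k) for k in kids]
            )
            assert got == parent - set().union(*kids)

    def test_stray_child_names_offenders(self):
        parent = mk_cluster({"A", "B"})
        with pytest.raises(ValidationError, match="STRAY"):
            subtract_residual(parent, [mk_cluster({"A", "STRAY"})])


class TestAnchorCandidates:
    def test_planted_satellites_ranked_by_anchor_edges(self):
        # 2 anchors; SATA touches both, SATB and SATC touch one
        edges = (
            clique_edges(["AN1", "AN2", "M1", "M2"])
            + [("SATA", "AN1"), ("SATA", "AN2"), ("SATB", "AN1"), ("SATC", "AN2"),
               ("LOOSE", "M1")]
        )
        net = net_from_edges(edges)
        seeds = SeedList(("AN1", "AN2"))
        report = anchor_candidates(
            {"SATA", "SATB", "SATC", "LOOSE"}, {"AN1", "AN2"}, net, seeds
        )
        assert report.candidate_names == ["SATA", "SATB", "SATC"]
        assert report.candidates[0][1] == 2

    def test_no_anchor_edges_empty(self):
        net = net_from_edges([("A", "B"), ("X", "Y")])
        seeds = SeedList(("A",))
        report = anchor_candidates({"X"}, {"A"}, net, seeds)
        assert report.candidates == []

    def test_empty_anchor_set_rejected(self):
        net = net_from_edges([("A", "B")])
        with pytest.raises(ValidationError):
            anchor_candidates({"B"}, set(), net, SeedList(("A",)))

    def test_seed_candidates_annotated_and_ranked_last(self):
        edges = [("AN1", "SEEDX"), ("AN1", "NEWP"), ("AN1", "M1"), ("M1", "AN1")]
        net = net_from_edges(edges)
        seeds = SeedList(("AN1", "SEEDX"))
        report = anchor_candidates({"SEEDX", "NEWP"}, {"AN1"}, net, seeds)
        assert report.candidate_names == ["NEWP", "SEEDX"]
        assert report.annotations["SEEDX"] == ["seed"]


class TestDefaultAnchors:
    def test_seed_poorest_seeded_child_supplies_anchors(self):
        seeds = SeedList(("S1", "S2", "S3", "A1"))
        rich = mk_cluster({"S1", "S2", "S3", "X"}, cid="rich")
        poor = mk_cluster({"A1", "Y", "Z"}, cid="poor")
        assert default_anchors([rich, poor], seeds) == {"A1"}

    def test_no_seeded_child_gives_empty(self):
        seeds = SeedList(("S1",))
        assert default_anchors([mk_cluster({"X"})], seeds) == frozenset()


class TestPartitionRecursive:
    def test_single_clique_is_unsplittable(self):
        names = [f"C{i}" for i in range(6)]
        net = net_from_edges(clique_edges(names))
        tree = partition_recursive(net, SeedList((names[0],)))
        root = tree.nodes["root"]
        # the clique itself cannot be divided into overlapping sub-graphs:
        # the branch ends with one disjoint split attempt
        assert root.split_algorithm == "mcode"
        assert tree.depth() <= 2

    def test_scenario_tree_contains_satellite_residual(self):
        net, truth, seeds = discovery_scenario(1)
        tree = partition_recursive(net, seeds)
        assert tree.depth() >= 3
        found = False
        for node in tree.mcode_split_nodes():
            kids = tree.children_of(node.node_id)
            residual = subtract_residual(
                node.cluster, [k.cluster for k in kids]
            )
            if truth.satellites <= residual:
                found = True
        assert found

    def test_children_are_subsets_of_parents(self):
        net, _truth, seeds = discovery_scenario(5)
        tree = partition_recursive(net, seeds)
        for node in tree.nodes.values():
            for kid in tree.children_of(node.node_id):
                assert kid.cluster.members <= node.cluster.members

    def test_disjoint_children_counts(self):
        net, _truth, seeds = discovery_scenario(1)
        tree = partition_recursive(net, seeds)
        for node in tree.mcode_split_nodes():
            kids = [k.cluster for k in tree.children_of(node.node_id)]
            covered = set().union(*(k.members for k in kids))
            assert sum(len(k.members) for k in kids) == len(covered)
            residual = subtract_residual(node.cluster, kids)
            assert len(residual) == len(node.cluster.members) - len(covered)


class TestRunDiscovery:
    def test_candidates_subset_of_residual_never_in_children(self):
        net, _truth, seeds = discovery_scenario(1)
        result = run_discovery(net, seeds)
        report = result.primary
        node = result.tree.nodes[report.parent_id]
        kids = result.tree.children_of(report.parent_id)
        child_members = set().union(*(k.cluster.members for k in kids))
        for name in report.candidate_names:
            assert name in report.residual
            assert name not in child_members

    def test_explicit_anchor_override(self):
        net, truth, seeds = discovery_scenario(1)
        result = run_discovery(net, seeds, anchors=sorted(truth.anchors))
        assert result.primary is not None
        assert result.primary.anchors == truth.anchors


class TestWriteReport:
    def test_four_files_byte_identical_on_rerun(self, tmp_path):
        net, _truth, seeds = discovery_scenario(1)
        result = run_discovery(net, seeds)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        files1 = write_report(result.tree, result.primary, str(out1), net)
        result2 = run_discovery(net, seeds)
        files2 = write_report(result2.tree, result2.primary, str(out2), net)
        assert [f.rsplit("/", 1)[-1] for f in files1] == [
            "clusters.tsv", "candidates.tsv", "tree.json", "parent.graphml"
        ]
        for f1, f2 in zip(files1, files2):
            assert open(f1, "rb").read() == open(f2, "rb").read()

    def test_tree_json_round_trips(self, tmp_path):
        net, _truth, seeds = discovery_scenario(1)
        result = run_discovery(net, seeds)
        write_report(result.tree, result.primary, str(tmp_path), net)
        data = json.load(open(tmp_path / "tree.json"))
        assert ClusterTree.from_dict(data) == result.tree

    def test_empty_candidates_header_only(self, tmp_path):
        from ppicluster.discovery import CandidateReport

        net, _truth, seeds = discovery_scenario(1)
        result = run_discovery(net, seeds)
        empty = CandidateReport(
            parent_id=result.primary.parent_id,
            residual=frozenset(),
            anchors=result.primary.anchors,
            candidates=[],
        )
        write_report(result.tree, empty, str(tmp_path), net)
        text = open(tmp_path / "candidates.tsv").read()
        assert text.splitlines() == [
            "protein\tn_edges_to_anchors\tn_edges_to_parent_seeds\tannotations"
        ]
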