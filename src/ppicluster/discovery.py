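"""Recursive partitioning and residual anchor-connected candidate discovery.

The pipeline mirrors how assembly-factor candidates were pulled out of a
complex-centered interaction network: cluster the network into
overlapping cohesive sub-graphs, follow the seed-containing cluster(s)
downward, and when a branch can no longer be split into overlapping
sub-graphs, split it once into disjoint dense complexes.  Subtracting
those complexes from their parent leaves a *residual* of weakly
connected proteins; the ones touching designated *anchor* subunits are
the discovery output, ranked by anchor connectivity.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .assembly import SeedList
from .clusterone import DEFAULT_PENALTY, ClusterParams, cluster_one
from .graph import Cluster, ClusterStats, PPINetwork, ValidationError, cluster_stats
from .io import to_graphml
from .mcode import McodeParams, mcode_complexes

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "ClusterTree",
    "CandidateReport",
    "DiscoveryResult",
    "select_target_cluster",
    "partition_recursive",
    "subtract_residual",
    "default_anchors",
    "anchor_candidates",
    "run_discovery",
    "write_report",
]

#: a single accepted cluster covering at least this fraction of its
#: input is treated as "cannot split further"
COVERAGE_STOP = 0.95


@dataclass
class TreeNode:
    node_id: str
    cluster: Cluster
    parent_id: Optional[str]
    children: list[str] = field(default_factory=list)
    split_algorithm: Optional[str] = None  # how the children were produced


@dataclass
class ClusterTree:
    """Parent/child record of every split performed by the pipeline."""

    nodes: dict[str, TreeNode] = field(default_factory=dict)
    root_id: str = "root"

    def add(self, node: TreeNode) -> None:
        self.nodes[node.node_id] = node
        if node.parent_id is not None:
            self.nodes[node.parent_id].children.append(node.node_id)

    def children_of(self, node_id: str) -> list[TreeNode]:
        return [self.nodes[c] for c in self.nodes[node_id].children]

    def mcode_split_nodes(self) -> list[TreeNode]:
        """Nodes whose children came from the disjoint splitter."""
        return [
            n for n in sorted(self.nodes.values(), key=lambda n: n.node_id)
            if n.split_algorithm == "mcode" and n.children
        ]

    def depth(self) -> int:
        def _d(node_id: str) -> int:
            kids = self.nodes[node_id].children
            return 1 + (max(_d(k) for k in kids) if kids else 0)

        return _d(self.root_id)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for node_id in sorted(self.nodes):
            n = self.nodes[node_id]
            s = n.cluster.stats
            out[node_id] = {
                "members": sorted(n.cluster.members),
                "algorithm": n.cluster.algorithm,
                "parent": n.parent_id,
                "children": list(n.children),
                "split_algorithm": n.split_algorithm,
                "stats": {
                    "n_nodes": s.n_nodes,
                    "m_internal": s.m_internal,
                    "m_boundary": s.m_boundary,
                    "density": s.density,
                    "quality": s.quality,
                    "p_value": s.p_value,
                },
            }
        return {"root": self.root_id, "nodes": out}

    @staticmethod
    def from_dict(data: dict) -> "ClusterTree":
        tree = ClusterTree(root_id=data["root"])
        for node_id, nd in data["nodes"].items():
            s = nd["stats"]
            cluster = Cluster(
                members=frozenset(nd["members"]),
                stats=ClusterStats(
                    n_nodes=s["n_nodes"],
                    m_internal=s["m_internal"],
                    m_boundary=s["m_boundary"],
                    density=s["density"],
                    quality=s["quality"],
                    p_value=s["p_value"],
                ),
                algorithm=nd["algorithm"],
                cluster_id=node_id,
                parent_id=nd["parent"],
            )
            tree.nodes[node_id] = TreeNode(
                node_id=node_id,
                cluster=cluster,
                parent_id=nd["parent"],
                children=list(nd["children"]),
                split_algorithm=nd.get("split_algorithm"),
            )
        return tree

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClusterTree):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def select_target_cluster(clusters: Iterable[Cluster], seeds: SeedList) -> Cluster:
    """The cluster with the largest seed coverage.

    Ties go to higher quality, then smaller size, then lexicographically
    smallest member list.
    """
    clusters = list(clusters)
    if not clusters:
        raise ValidationError("cluster list must be non-empty")
    seed_set = seeds.names

    def coverage(c: Cluster) -> int:
        return len(c.members & seed_set)

    best = max(
        clusters,
        key=lambda c: (
            coverage(c),
            c.stats.quality,
            -len(c.members),
            [chr(0x10FFFF)] if not c.members else sorted(c.members, reverse=True),
        ),
    )
    # lexicographic member tie-break needs an explicit pass: prefer the
    # lexicographically smallest sorted member list among full ties
    full_ties = [
        c for c in clusters
        if coverage(c) == coverage(best)
        and c.stats.quality == best.stats.quality
        and len(c.members) == len(best.members)
    ]
    best = min(full_ties, key=lambda c: sorted(c.members))
    if coverage(best) == 0:
        raise ValidationError(
            "no cluster contains a seed protein; consider loosening the "
            "clustering thresholds (min_density / max_pvalue)"
        )
    return best


def _make_node(
    network: PPINetwork,
    members: frozenset[str],
    node_id: str,
    parent_id: Optional[str],
    algorithm: str,
    stats: Optional[ClusterStats] = None,
) -> TreeNode:
    cluster = Cluster(
        members=members,
        stats=stats if stats is not None else cluster_stats(members, network),
        algorithm=algorithm,
        cluster_id=node_id,
        parent_id=parent_id,
    )
    return TreeNode(node_id=node_id, cluster=cluster, parent_id=parent_id)


def partition_recursive(
    network: PPINetwork,
    seeds: SeedList,
    params: ClusterParams = ClusterParams(),
    mcode_params: McodeParams = McodeParams(),
    max_depth: int = 3,
    expand_all: bool = True,
    penalty: float = DEFAULT_PENALTY,
) -> ClusterTree:
    """Recursively partition the network, recording every split.

    At each tree node the overlapping clustering runs on the induced
    subgraph.  When it yields no accepted cluster, or its largest
    accepted cluster covers at least :data:`COVERAGE_STOP` of the input
    (a child nearly equal to its parent is not a split), the branch is
    considered unsplittable into overlapping sub-graphs and is split
    once with the disjoint complex detector instead, ending the branch.
    Otherwise the accepted clusters become children and recursion
    continues into every seed-containing child (``expand_all=True``,
    default) or only the seed-richest one (``expand_all=False``).
    """
    if max_depth < 1:
        raise ValidationError("max_depth must be >= 1")
    tree = ClusterTree()
    root_members = frozenset(network.nodes)
    tree.nodes["root"] = _make_node(network, root_members, "root", None, "root")

    def expand(node_id: str, depth: int) -> None:
        node = tree.nodes[node_id]
        members = node.cluster.members
        if len(members) < max(params.min_size, 2):
            return
        induced = network.subgraph(members)
        result = cluster_one(induced, params, penalty)
        coverage = max(
            (len(c.members) / len(members) for c in result.clusters),
            default=0.0,
        )
        if len(result.clusters) == 0 or coverage >= COVERAGE_STOP:
            node.split_algorithm = "mcode"
            for i, c in enumerate(mcode_complexes(induced, mcode_params), start=1):
                child_id = f"{node_id}.{i}" if node_id != "root" else str(i)
                tree.add(
                    _make_node(
                        network, c.members, child_id, node_id, "mcode",
                        stats=cluster_stats(c.members, induced),
                    )
                )
            return
        node.split_algorithm = "clusterone"
        children: list[TreeNode] = []
        for i, c in enumerate(result.clusters, start=1):
            child_id = f"{node_id}.{i}" if node_id != "root" else str(i)
            child = _make_node(
                network, c.members, child_id, node_id, "clusterone", stats=c.stats
            )
            tree.add(child)
            children.append(child)
        if depth >= max_depth:
            return
        seed_set = seeds.names
        with_seeds = [c for c in children if c.cluster.members & seed_set]
        if not with_seeds:
            return
        if expand_all:
            targets = with_seeds
        else:
            chosen = select_target_cluster([c.cluster for c in children], seeds)
            targets = [c for c in children if c.cluster.members == chosen.members]
        for child in targets:
            expand(child.node_id, depth + 1)

    expand("root", 1)
    return tree


def subtract_residual(parent: Cluster, children: Iterable[Cluster]) -> set[str]:
    """Parent members minus the union of child members."""
    children = list(children)
    covered: set[str] = set()
    for child in children:
        stray = child.members - parent.members
        if stray:
            raise ValidationError(
                f"child cluster {child.cluster_id or '?'} is not a subset of "
                f"its parent; offending nodes: {sorted(stray)}"
            )
        covered |= child.members
    return set(parent.members) - covered


def default_anchors(children: Iterable[Cluster], seeds: SeedList) -> frozenset[str]:
    """Seeds of the seed-poorest seed-containing child cluster.

    In a complex whose subunits split between two dense sub-complexes,
    the handful of subunits pulled into the *other* sub-complex are the
    natural anchors — the residual candidates reach the complex through
    them.  Ties go to the larger child, then lexicographic members.
    """
    seed_set = seeds.names
    seeded = [c for c in children if c.members & seed_set]
    if not seeded:
        return frozenset()
    chosen = min(
        seeded,
        key=lambda c: (len(c.members & seed_set), -len(c.members), sorted(c.members)),
    )
    return frozenset(chosen.members & seed_set)


@dataclass
class CandidateReport:
    """Residual proteins of one parent cluster, ranked by anchor contact."""

    parent_id: str
    residual: frozenset[str]
    anchors: frozenset[str]
    candidates: list[tuple[str, int, int]]  # (protein, anchor edges, seed edges)
    annotations: dict[str, list[str]] = field(default_factory=dict)

    @property
    def candidate_names(self) -> list[str]:
        return [name for name, _, _ in self.candidates]


def anchor_candidates(
    residual: Iterable[str],
    anchors: Iterable[str],
    network: PPINetwork,
    seeds: SeedList,
    parent_id: str = "",
) -> CandidateReport:
    """Keep residual proteins with at least one edge to an anchor.

    Ranked by anchor-edge count, then seed-edge count, then name; seed
    proteins themselves are annotated and ranked after non-seeds (a
    known subunit is not a *new* candidate).
    """
    residual = frozenset(residual)
    anchors = frozenset(anchors)
    if not anchors:
        raise ValidationError("anchor set must be non-empty")
    missing = anchors - set(network.g.nodes)
    if missing:
        raise ValidationError(f"anchors not in network: {sorted(missing)}")
    seed_set = seeds.names
    rows: list[tuple[str, int, int]] = []
    annotations: dict[str, list[str]] = {}
    for prot in sorted(residual):
        n_anchor = sum(
            1 for a in anchors if a != prot and network.has_edge(prot, a)
        )
        if n_anchor == 0:
            continue
        n_seed = sum(
            1 for s in seed_set if s != prot and s in network and network.has_edge(prot, s)
        )
        rows.append((prot, n_anchor, n_seed))
        if prot in seed_set:
            annotations.setdefault(prot, []).append("seed")
    rows.sort(
        key=lambda r: (r[0] in seed_set, -r[1], -r[2], r[0])
    )
    return CandidateReport(
        parent_id=parent_id,
        residual=residual,
        anchors=anchors,
        candidates=rows,
        annotations=annotations,
    )


@dataclass
class DiscoveryResult:
    tree: ClusterTree
    reports: list[CandidateReport]
    primary: Optional[CandidateReport] = None

    @property
    def candidates(self) -> list[str]:
        """Ranked candidates of the primary report (empty if none)."""
        return self.primary.candidate_names if self.primary is not None else []


def run_discovery(
    network: PPINetwork,
    seeds: SeedList,
    params: ClusterParams = ClusterParams(),
    mcode_params: McodeParams = McodeParams(),
    max_depth: int = 3,
    expand_all: bool = True,
    anchors: Optional[Iterable[str]] = None,
    penalty: float = DEFAULT_PENALTY,
) -> DiscoveryResult:
    """Partition recursively, then report residual anchor candidates.

    One report is produced per tree node that was split disjointly and
    left a non-empty residual; the anchors default to the seeds of the
    seed-poorest child unless given explicitly.  The *primary* report is
    the one whose parent cluster covers the most seed proteins — the
    branch that actually holds the complex under study.
    """
    tree = partition_recursive(
        network, seeds, params, mcode_params, max_depth, expand_all, penalty
    )
    reports: list[CandidateReport] = []
    fixed_anchors = frozenset(anchors) if anchors is not None else None
    for node in tree.mcode_split_nodes():
        children = [c.cluster for c in tree.children_of(node.node_id)]
        residual = subtract_residual(node.cluster, children)
        if not residual:
            continue
        anchor_set = (
            fixed_anchors if fixed_anchors is not None
            else default_anchors(children, seeds)
        )
        if not anchor_set:
            logger.info(
                "node %s: no seed-containing child, no anchors; skipping",
                node.node_id,
            )
            continue
        reports.append(
            anchor_candidates(residual, anchor_set, network, seeds, node.node_id)
        )
    primary = None
    if reports:
        seed_set = seeds.names

        def novelty(r: CandidateReport) -> int:
            # the pipeline exists to propose NEW proteins; a report whose
            # candidates are all known subunits is a null discovery
            return sum(1 for name, _, _ in r.candidates if name not in seed_set)

        primary = max(
            reports,
            key=lambda r: (
                novelty(r),
                len(tree.nodes[r.parent_id].cluster.members & seed_set),
                len(tree.nodes[r.parent_id].cluster.members),
                r.parent_id,
            ),
        )
    return DiscoveryResult(tree=tree, reports=reports, primary=primary)


# -- reporting ---------------------------------------------------------

_CLUSTER_HEADER = (
    "id\talgorithm\tn\tm_internal\tm_boundary\tdensity\tquality\tp_value\tmembers"
)


def clusters_tsv(clusters: Iterable[Cluster]) -> str:
    """One row per cluster — the machine twin of a cluster-summary table."""
    lines = [_CLUSTER_HEADER]
    for c in clusters:
        s = c.stats
        p = "" if s.p_value is None else f"{s.p_value:.3g}"
        lines.append(
            f"{c.cluster_id}\t{c.algorithm}\t{s.n_nodes}\t{s.m_internal}\t"
            f"{s.m_boundary}\t{s.density:.3f}\t{s.quality:.3f}\t{p}\t"
            + ";".join(c.sorted_members)
        )
    return "\n".join(lines) + "\n"


def candidates_tsv(report: CandidateReport) -> str:
    lines = ["protein\tn_edges_to_anchors\tn_edges_to_parent_seeds\tannotations"]
    for name, n_anchor, n_seed in report.candidates:
        notes = ";".join(report.annotations.get(name, []))
        lines.append(f"{name}\t{n_anchor}\t{n_seed}\t{notes}")
    return "\n".join(lines) + "\n"


def write_report(
    tree: ClusterTree,
    report: CandidateReport,
    out_dir: str,
    network: Optional[PPINetwork] = None,
) -> list[str]:
    """Write cluster TSV, candidate TSV, tree JSON and parent GraphML.

    Returns the written paths; output is byte-identical across re-runs.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []

    clusters = [
        tree.nodes[nid].cluster for nid in sorted(tree.nodes) if nid != tree.root_id
    ]
    path = os.path.join(out_dir, "clusters.tsv")
    with open(path, "w") as fh:
        fh.write(clusters_tsv(clusters))
    written.append(path)

    path = os.path.join(out_dir, "candidates.tsv")
    with open(path, "w") as fh:
        fh.write(candidates_tsv(report))
    written.append(path)

    path = os.path.join(out_dir, "tree.json")
    with open(path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    written.append(path)

    if network is not None and report.parent_id in tree.nodes:
        parent = tree.nodes[report.parent_id].cluster
        sub = network.subgraph(parent.members)
        for name in sub.g.nodes:
            sub.g.nodes[name]["candidate"] = name in set(report.candidate_names)
            sub.g.nodes[name]["anchor"] = name in report.anchors
        path = os.path.join(out_dir, "parent.graphml")
        with open(path, "w") as fh:
            fh.write(to_graphml(sub))
        written.append(path)
    return written
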