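"""Disjoint dense-subgraph detection by local-neighborhood k-core weighting.

Molecular-complex detection in the MCODE style: every node is weighted
by the density of the highest-order k-core of its closed neighborhood
(weight = core order × core density), then complexes are expanded
breadth-first from the heaviest unassigned seeds, including neighbors
whose weight stays within a fraction (the vertex-weight percentage) of
the seed's weight.  An optional *haircut* prunes nodes with fewer than
two within-complex neighbors.  Complexes are node-disjoint — a node
assigned to one complex is never re-seeded or re-included — and the
procedure runs with the published defaults (vwp 0.2, haircut on, fluff
off, depth limit 100) unless told otherwise.

Self-loops carry no neighborhood-density information and are ignored
throughout this module.  Density here is the simple-graph density
``2m / (n(n-1))`` (no self-pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .graph import Cluster, PPINetwork, ValidationError, cluster_stats

logger = logging.getLogger(__name__)

__all__ = [
    "McodeParams",
    "core_numbers",
    "vertex_weight",
    "vertex_weights",
    "mcode_complexes",
]

#: complexes smaller than this are suppressed, matching the
#: pipeline-wide minimum cluster size
MIN_OUTPUT_SIZE = 3


@dataclass(frozen=True)
class McodeParams:
    vwp: float = 0.2
    min_core: int = 2
    haircut: bool = True
    fluff: bool = False
    max_depth: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp <= 1.0:
            raise ValidationError("vwp must be in [0, 1]")
        if self.min_core < 1:
            raise ValidationError("min_core must be >= 1")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")


def _simple_graph(network: PPINetwork) -> nx.Graph:
    g = nx.Graph(network.g)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def core_numbers(network: PPINetwork) -> dict[str, int]:
    """Largest k such that each node belongs to a k-core (self-loops ignored)."""
    return dict(nx.core_number(_simple_graph(network)))


def _simple_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _weight_in(g: nx.Graph, node: str, min_core: int) -> float:
    neighborhood = set(g.neighbors(node)) | {node}
    h = g.subgraph(neighborhood)
    if h.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(h)
    k_star = max(cores.values())
    if k_star < min_core:
        return 0.0
    core = nx.k_core(h, k=k_star, core_number=cores)
    return k_star * _simple_density(core)


def vertex_weight(
    node: str, network: PPINetwork, params: McodeParams = McodeParams()
) -> float:
    """Local-neighborhood-density weight of one node.

    The closed neighborhood's highest-order k-core (order ``k*``) gives
    weight ``k* × density(core)``; nodes whose neighborhood supports no
    core of order >= ``min_core`` weigh 0.
    """
    if node not in network:
        raise ValidationError(f"node {node!r} not in network")
    return _weight_in(_simple_graph(network), node, params.min_core)


def vertex_weights(
    network: PPINetwork, params: McodeParams = McodeParams()
) -> dict[str, float]:
    g = _simple_graph(network)
    return {n: _weight_in(g, n, params.min_core) for n in g.nodes}


def _haircut(g: nx.Graph, members: set[str]) -> set[str]:
    """Iteratively drop members with < 2 neighbors inside the set."""
    members = set(members)
    while True:
        sub = g.subgraph(members)
        weak = sorted(n for n in members if sub.degree(n) < 2)
        if not weak:
            return members
        members -= set(weak)


def mcode_complexes(
    network: PPINetwork, params: McodeParams = McodeParams()
) -> list[Cluster]:
    """Extract node-disjoint dense complexes, best-scoring first.

    Seeds are taken in decreasing weight order (name-tie-broken); each
    complex is the breadth-first closure of unassigned neighbors whose
    weight is at least ``(1 - vwp) ×`` the seed weight, up to
    ``max_depth`` hops.  After the optional haircut the connected
    component containing the seed is kept; complexes below the minimum
    output size are suppressed.  Result is sorted by score
    (density × size) descending and is fully deterministic.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("network must be non-empty")
    g = _simple_graph(network)
    weights = {n: _weight_in(g, n, params.min_core) for n in g.nodes}
    order = sorted(g.nodes, key=lambda n: (-weights[n], n))
    assigned: set[str] = set()
    complexes: list[set[str]] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = (1.0 - params.vwp) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for u in frontier:
                for v in sorted(g.neighbors(u)):
                    if v in members or v in assigned:
                        continue
                    if weights[v] >= threshold:
                        members.add(v)
                        nxt.append(v)
            frontier = nxt
            depth += 1
        if params.haircut:
            members = _haircut(g, members)
            if members:
                comp_sub = g.subgraph(members)
                if seed in members:
                    members = set(nx.node_connected_component(comp_sub, seed))
                else:
                    comps = sorted(
                        nx.connected_components(comp_sub),
                        key=lambda c: (-len(c), sorted(c)),
                    )
                    members = set(comps[0])
        if len(members) < MIN_OUTPUT_SIZE:
            continue
        assigned |= members
        complexes.append(members)
    scored = []
    for members in complexes:
        sub = g.subgraph(members)
        score = _simple_density(sub) * len(members)
        scored.append((score, members))
    scored.sort(key=lambda t: (-t[0], -len(t[1]), sorted(t[1])))
    out = []
    for i, (score, members) in enumerate(scored, start=1):
        out.append(
            Cluster(
                members=frozenset(members),
                stats=cluster_stats(members, network),
                algorithm="mcode",
                cluster_id=str(i),
            )
        )
    logger.info("mcode: %d complex(es) extracted", len(out))
    return out
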