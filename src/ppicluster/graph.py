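"""Core data model for un-weighted protein–protein interaction networks.

Proteins are identified by canonical standard gene names (SGD style,
upper-case).  A :class:`PPINetwork` is an un-weighted, undirected simple
graph in which self-interactions (homodimers) are permitted; every edge
carries the set of source databases that reported it and the number of
records that collapsed onto it, but neither is ever used as a weight.

Cluster statistics follow the conventions of seed-growth complex
detection on such networks:

* **density** — internal edges divided by the number of theoretically
  possible edges ``n(n+1)/2``; self-pairs are counted as possible, so a
  single node with a self-loop has density 1.
* **quality (cohesiveness)** — internal edges divided by all edges that
  touch the cluster (internal + boundary); 1 when the cluster has no
  boundary.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ProteinOrigin",
    "ProteinRef",
    "InteractionRecord",
    "PPINetwork",
    "IDMap",
    "ClusterStats",
    "Cluster",
    "canonicalize_pair",
    "build_network",
    "cluster_stats",
    "pair_density",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


class ProteinOrigin(str, enum.Enum):
    SEED = "seed"
    DATABASE = "database"
    EXPANDED = "expanded"


@dataclass(frozen=True)
class ProteinRef:
    """A protein with its canonical name and known alternate identifiers."""

    canonical_name: str
    aliases: frozenset[str] = frozenset()
    origin: ProteinOrigin = ProteinOrigin.DATABASE

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValidationError("canonical_name must be non-empty")


@dataclass(frozen=True)
class InteractionRecord:
    """One physical interaction between two proteins.

    Pairs are unordered: ``(a, b)`` and ``(b, a)`` denote the same
    interaction.  ``evidence_count`` records how many raw records were
    collapsed onto this pair; it is metadata only, never an edge weight.
    """

    partner_a: str
    partner_b: str
    sources: frozenset[str] = frozenset()
    evidence_count: int = 1
    is_physical: bool = True

    def __post_init__(self) -> None:
        if not self.partner_a or not self.partner_b:
            raise ValidationError("interaction partners must be non-empty")
        if self.evidence_count < 1:
            raise ValidationError("evidence_count must be positive")

    def pair(self) -> tuple[str, str]:
        """The lexicographically ordered unordered pair."""
        return canonicalize_pair(self.partner_a, self.partner_b)

    def ordered(self) -> "InteractionRecord":
        """A copy with partner_a <= partner_b lexicographically."""
        a, b = self.pair()
        if (a, b) == (self.partner_a, self.partner_b):
            return self
        return replace(self, partner_a=a, partner_b=b)


def canonicalize_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered protein pair lexicographically (case-sensitive).

    Self-pairs are returned unchanged.
    """
    if not a or not b:
        raise ValidationError("protein identifiers must be non-empty")
    return (a, b) if a <= b else (b, a)


class IDMap:
    """Single-valued alias -> canonical-name mapping.

    Canonical names map to themselves and are upper-cased on ingestion,
    matching the convention that standard gene names are upper-case.
    """

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        self._map: dict[str, str] = {}
        items = entries.items() if isinstance(entries, Mapping) else entries
        for alias, canonical in items:
            self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        if not alias or not canonical:
            raise ValidationError("alias and canonical name must be non-empty")
        canonical = canonical.upper()
        existing = self._map.get(alias)
        if existing is not None and existing != canonical:
            raise ValidationError(
                f"alias {alias!r} maps to both {existing!r} and {canonical!r}"
            )
        self._map[alias] = canonical
        # canonical names are fixed points of the mapping
        prev = self._map.get(canonical)
        if prev is not None and prev != canonical:
            raise ValidationError(
                f"canonical name {canonical!r} already mapped to {prev!r}"
            )
        self._map[canonical] = canonical

    def get(self, identifier: str) -> Optional[str]:
        return self._map.get(identifier)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._map.items()))


class PPINetwork:
    """Un-weighted undirected simple graph over canonical protein names.

    Thin wrapper around :class:`networkx.Graph`; self-loops are allowed.
    Edge attributes: ``sources`` (frozenset of source tags) and
    ``evidence`` (number of collapsed records).
    """

    def __init__(self) -> None:
        self.g = nx.Graph()
        self.refs: dict[str, ProteinRef] = {}

    # -- construction -------------------------------------------------
    def add_protein(self, ref: ProteinRef) -> None:
        name = ref.canonical_name
        for alias in ref.aliases:
            for other in self.refs.values():
                if other.canonical_name != name and alias in other.aliases:
                    raise ValidationError(
                        f"alias {alias!r} appears in two proteins"
                    )
        self.refs[name] = ref
        self.g.add_node(name)

    def add_interaction(self, record: InteractionRecord) -> None:
        a, b = record.pair()
        for name in (a, b):
            if name not in self.g:
                self.g.add_node(name)
                self.refs.setdefault(name, ProteinRef(name))
        if self.g.has_edge(a, b):
            data = self.g.edges[a, b]
            data["sources"] = frozenset(data["sources"] | record.sources)
            data["evidence"] += record.evidence_count
        else:
            self.g.add_edge(
                a, b, sources=frozenset(record.sources), evidence=record.evidence_count
            )

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list[str]:
        return sorted(self.g.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(canonicalize_pair(a, b) for a, b in self.g.edges)

    def number_of_nodes(self) -> int:
        return self.g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.g.number_of_edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.g.has_edge(a, b)

    def neighbors(self, node: str) -> list[str]:
        return sorted(n for n in self.g.neighbors(node) if n != node)

    def has_self_loop(self, node: str) -> bool:
        return self.g.has_edge(node, node)

    def degree(self, node: str) -> int:
        """Number of distinct partners plus 1 if a self-loop exists."""
        d = sum(1 for n in self.g.neighbors(node) if n != node)
        return d + (1 if self.has_self_loop(node) else 0)

    def edge_sources(self, a: str, b: str) -> frozenset[str]:
        return self.g.edges[a, b]["sources"]

    def subgraph(self, members: Iterable[str]) -> "PPINetwork":
        members = set(members)
        missing = members - set(self.g.nodes)
        if missing:
            raise ValidationError(f"nodes not in network: {sorted(missing)}")
        sub = PPINetwork()
        for name in sorted(members):
            sub.add_protein(self.refs.get(name, ProteinRef(name)))
        for a, b in self.edges:
            if a in members and b in members:
                data = self.g.edges[a, b]
                sub.add_interaction(
                    InteractionRecord(a, b, data["sources"], data["evidence"])
                )
        return sub

    def to_records(self) -> list[InteractionRecord]:
        return [
            InteractionRecord(a, b, self.g.edges[a, b]["sources"], self.g.edges[a, b]["evidence"])
            for a, b in self.edges
        ]

    def __contains__(self, node: str) -> bool:
        return node in self.g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"PPINetwork(n={self.number_of_nodes()}, m={self.number_of_edges()})"
        )


def build_network(records: Iterable[InteractionRecord]) -> PPINetwork:
    """Collapse a list of physical interaction records into a network.

    Duplicate pairs (including symmetric duplicates) become one edge;
    per-edge sources are unioned and evidence counts summed.  The result
    is un-weighted by construction.
    """
    net = PPINetwork()
    for rec in records:
        if not rec.is_physical:
            continue
        net.add_interaction(rec)
    return net


def pair_density(n_nodes: int, m_internal: int) -> float:
    """Edge density with self-pairs permitted in the denominator.

    ``m / (n(n+1)/2)`` — the number of theoretically possible edges among
    *n* proteins when homodimer self-interactions count as possible.
    """
    if n_nodes < 1:
        raise ValidationError("density needs at least one node")
    possible = n_nodes * (n_nodes + 1) // 2
    return m_internal / possible


@dataclass(frozen=True)
class ClusterStats:
    n_nodes: int
    m_internal: int
    m_boundary: int
    density: float
    quality: float
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.m_internal > self.n_nodes * (self.n_nodes + 1) // 2:
            raise ValidationError("more internal edges than possible pairs")


@dataclass(frozen=True)
class Cluster:
    """A node set with its statistics and provenance."""

    members: frozenset[str]
    stats: ClusterStats
    algorithm: str = ""
    cluster_id: str = ""
    parent_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("a cluster has at least one member")

    @property
    def sorted_members(self) -> list[str]:
        return sorted(self.members)

    def __len__(self) -> int:
        return len(self.members)


def _edge_counts(members: set[str], network: PPINetwork) -> tuple[int, int]:
    """(internal, boundary) edge counts; a self-loop is 1 internal edge."""
    m_internal = 0
    m_boundary = 0
    for a, b in network.g.edges:
        ina, inb = a in members, b in members
        if ina and inb:
            m_internal += 1
        elif ina or inb:
            m_boundary += 1
    return m_internal, m_boundary


def cluster_stats(
    members: Iterable[str], network: PPINetwork, p_value: Optional[float] = None
) -> ClusterStats:
    """Internal/boundary edge counts, density and quality of a node set.

    Density uses the self-pair-inclusive denominator ``n(n+1)/2``;
    quality is ``m_int / (m_int + m_bnd)``, or 1 when the cluster has no
    incident edges at all.
    """
    members = set(members)
    if not members:
        raise ValidationError("cluster must be non-empty")
    missing = members - set(network.g.nodes)
    if missing:
        raise ValidationError(f"members not in network: {sorted(missing)}")
    m_internal, m_boundary = _edge_counts(members, network)
    n = len(members)
    density = pair_density(n, m_internal)
    total = m_internal + m_boundary
    quality = m_internal / total if total > 0 else 1.0
    return ClusterStats(
        n_nodes=n,
        m_internal=m_internal,
        m_boundary=m_boundary,
        density=density,
        quality=quality,
        p_value=p_value,
    )
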