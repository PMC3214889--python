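"""Five-step construction of the merged seed-centered PPI network.

Starting from a list of seed proteins (the known subunits and assembly
factors of a complex), the merged network is built from two local
interaction-database snapshots:

1. From the first snapshot, take the *level-1.5 neighborhood* of the
   seeds: every interaction touching a seed, plus every interaction
   between two proteins that each interact directly with a seed
   (list 1).
2. Unify identifiers to standard gene names (done upstream via
   :func:`ppicluster.io.apply_idmap`).
3. From the second snapshot, take all direct interactions of the seeds
   (list 2); then add the interactions joining proteins new to list 2
   (absent from list 1) to the non-seed proteins of list 1 (list 3).
4. Merge the lists, keeping each interaction once with the union of its
   source tags.
5. The result is an un-weighted network.

Historical note: on the original database snapshots this procedure
produced a 719-interaction, 136-protein network; those snapshots are
external and unversioned, so synthetic snapshots stand in for testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from .graph import (
    InteractionRecord,
    PPINetwork,
    ValidationError,
    build_network,
    canonicalize_pair,
)
from .io import _as_stream

logger = logging.getLogger(__name__)

__all__ = [
    "SeedList",
    "SourceSnapshot",
    "load_seed_list",
    "level15_neighborhood",
    "direct_interactions",
    "expansion_delta",
    "merge_lists",
    "assemble_network",
    "missing_seeds",
    "provenance_table",
]

_ROLES = ("core", "supernumerary", "assembly_factor")


@dataclass(frozen=True)
class SeedList:
    """Ordered list of canonical seed-protein names with role tags."""

    proteins: tuple[str, ...]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValidationError("seed list must be non-empty")
        if len(set(self.proteins)) != len(self.proteins):
            raise ValidationError("seed list contains duplicates")
        for role in self.roles.values():
            if role not in _ROLES:
                raise ValidationError(f"unknown seed role {role!r}")

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, name: str) -> bool:
        return name in set(self.proteins)

    @property
    def names(self) -> set[str]:
        return set(self.proteins)


def load_seed_list(stream: TextIO | str) -> SeedList:
    """One canonical name per line, optional ``<TAB>role`` tag."""
    proteins: list[str] = []
    roles: dict[str, str] = {}
    for raw in _as_stream(stream):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        name = fields[0].strip().upper()
        proteins.append(name)
        if len(fields) > 1 and fields[1].strip():
            roles[name] = fields[1].strip()
    return SeedList(tuple(proteins), roles)


@dataclass(frozen=True)
class SourceSnapshot:
    """A full local snapshot of one interaction source, canonicalized."""

    name: str
    records: tuple[InteractionRecord, ...]

    @staticmethod
    def from_records(name: str, records: Iterable[InteractionRecord]) -> "SourceSnapshot":
        ordered = tuple(
            r.ordered() for r in records if r.is_physical
        )
        return SourceSnapshot(name, ordered)

    def endpoints(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out.add(r.partner_a)
            out.add(r.partner_b)
        return out


def _dedupe(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse duplicate pairs, merging sources and evidence; sorted."""
    merged: dict[tuple[str, str], InteractionRecord] = {}
    for rec in records:
        key = rec.pair()
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec.ordered()
        else:
            merged[key] = InteractionRecord(
                key[0], key[1],
                prev.sources | rec.sources,
                prev.evidence_count + rec.evidence_count,
            )
    return [merged[k] for k in sorted(merged)]


def _endpoints(records: Iterable[InteractionRecord]) -> set[str]:
    out: set[str] = set()
    for r in records:
        out.add(r.partner_a)
        out.add(r.partner_b)
    return out


def level15_neighborhood(
    snapshot: SourceSnapshot, seeds: SeedList
) -> list[InteractionRecord]:
    """Direct seed interactions plus interactions between seed neighbors.

    Returns the union of (i) records with at least one seed endpoint and
    (ii) records both of whose endpoints interact directly with some
    seed in the snapshot; deduplicated.
    """
    if len(seeds) == 0:
        raise ValidationError("seed list must be non-empty")
    seed_set = seeds.names
    neighbors: set[str] = set()
    for rec in snapshot.records:
        a, b = rec.partner_a, rec.partner_b
        if a in seed_set:
            neighbors.add(b)
        if b in seed_set:
            neighbors.add(a)
    out = []
    for rec in snapshot.records:
        a, b = rec.partner_a, rec.partner_b
        touches_seed = a in seed_set or b in seed_set
        between_neighbors = a in neighbors and b in neighbors
        if touches_seed or between_neighbors:
            out.append(rec)
    return _dedupe(out)


def direct_interactions(
    snapshot: SourceSnapshot, proteins: Iterable[str]
) -> list[InteractionRecord]:
    """Records with at least one endpoint in ``proteins``; deduplicated."""
    query = set(proteins)
    out = [
        rec for rec in snapshot.records
        if rec.partner_a in query or rec.partner_b in query
    ]
    return _dedupe(out)


def expansion_delta(
    list1: Sequence[InteractionRecord],
    list2: Sequence[InteractionRecord],
    snapshot: SourceSnapshot,
    seeds: SeedList,
) -> list[InteractionRecord]:
    """Interactions joining list-2's new proteins to list-1's non-seeds.

    *New* proteins are endpoints of list 2 absent from list 1's
    endpoints.  The join targets are list 1's endpoint proteins
    excluding the seeds, so direct seed edges (already in list 2) are
    not re-added.  Records already present in list 1 or list 2 are
    excluded.  Interactions among the new proteins themselves are not
    admitted; see the module documentation for the rationale.
    """
    ep1 = _endpoints(list1)
    ep2 = _endpoints(list2)
    new_proteins = ep2 - ep1
    targets = ep1 - seeds.names
    known_pairs = {r.pair() for r in list1} | {r.pair() for r in list2}
    out = []
    for rec in snapshot.records:
        a, b = rec.partner_a, rec.partner_b
        joins = (a in new_proteins and b in targets) or (
            b in new_proteins and a in targets
        )
        if joins and rec.pair() not in known_pairs:
            out.append(rec)
    return _dedupe(out)


def merge_lists(*lists: Sequence[InteractionRecord]) -> PPINetwork:
    """Merge record lists into one un-weighted network.

    Each unique pair becomes one edge whose sources are the union of the
    contributing records' source tags; the order of the input lists does
    not change the result.
    """
    all_records: list[InteractionRecord] = []
    for lst in lists:
        all_records.extend(lst)
    return build_network(_dedupe(all_records))


@dataclass(frozen=True)
class AssemblyResult:
    network: PPINetwork
    list1: tuple[InteractionRecord, ...]
    list2: tuple[InteractionRecord, ...]
    list3: tuple[InteractionRecord, ...]
    missing_seeds: tuple[str, ...]


def assemble_network(
    snapshot_a: SourceSnapshot,
    snapshot_b: SourceSnapshot,
    seeds: SeedList,
) -> AssemblyResult:
    """Run the full 5-step assembly from two canonicalized snapshots."""
    list1 = level15_neighborhood(snapshot_a, seeds)
    list2 = direct_interactions(snapshot_b, seeds.names)
    list3 = expansion_delta(list1, list2, snapshot_b, seeds)
    network = merge_lists(list1, list2, list3)
    absent = missing_seeds(network, seeds)
    if absent:
        logger.warning(
            "seed protein(s) absent from all snapshots: %s", ", ".join(absent)
        )
    logger.info(
        "assembled network: list1=%d list2=%d list3=%d -> %d PPI over %d proteins",
        len(list1), len(list2), len(list3),
        network.number_of_edges(), network.number_of_nodes(),
    )
    return AssemblyResult(
        network, tuple(list1), tuple(list2), tuple(list3), tuple(absent)
    )


def missing_seeds(network: PPINetwork, seeds: SeedList) -> list[str]:
    """Seeds not present in the assembled network (reported, not dropped)."""
    return sorted(s for s in seeds if s not in network)


def provenance_table(network: PPINetwork) -> str:
    """TSV of edge, sources, for the merged network (stable ordering)."""
    lines = ["partner_a\tpartner_b\tsources"]
    for a, b in network.edges:
        sources = ";".join(sorted(network.edge_sources(a, b)))
        lines.append(f"{a}\t{b}\t{sources}")
    return "\n".join(lines) + "\n"
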