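"""Synthetic PPI networks with planted structure for pipeline testing.

The generator emulates the statistical shape of a seed-centered
interaction network around a protein complex: a few dense modules
(Bernoulli ``intra_p`` subgraphs, optionally sharing nodes), a sparse
background, designated *anchor* nodes inside one module, and low-degree
*satellite* candidates that attach only to anchors.  Satellites model
the discovery target: proteins too weakly interconnected to survive any
density filter, visible only through their anchor contacts after the
dense sub-clusters are subtracted from their parent.

All generation is a pure function of the spec (including its RNG seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assembly import SeedList, SourceSnapshot
from .graph import (
    InteractionRecord,
    PPINetwork,
    ProteinOrigin,
    ProteinRef,
    ValidationError,
    build_network,
)

__all__ = [
    "PlantedSpec",
    "GroundTruth",
    "planted_network",
    "discovery_scenario",
    "split_snapshots",
]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of one planted-structure network."""

    module_sizes: tuple[int, ...]
    intra_p: float = 0.9
    inter_p: float = 0.05
    overlap_map: dict[tuple[int, int], int] = field(default_factory=dict)
    n_anchors: int = 0
    anchor_module: int = 0
    n_satellites: int = 0
    satellite_degree: int = 1
    n_background: int = 0
    background_p: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.module_sizes or any(s < 1 for s in self.module_sizes):
            raise ValidationError("module_sizes must be positive")
        if not 0.0 <= self.inter_p < 1.0 or not 0.0 < self.intra_p <= 1.0:
            raise ValidationError("probabilities must satisfy 0 <= inter_p < intra_p <= 1")
        if self.inter_p >= self.intra_p:
            raise ValidationError("inter_p must be below intra_p")
        for (i, j), k in self.overlap_map.items():
            if not (0 <= i < j < len(self.module_sizes)) or k < 0:
                raise ValidationError(f"bad overlap entry {(i, j)}: {k}")
        if self.n_satellites > 0:
            if self.satellite_degree < 1:
                raise ValidationError("satellite_degree must be >= 1")
            if self.n_anchors < self.satellite_degree:
                raise ValidationError(
                    "satellite_degree cannot exceed the number of anchors"
                )
        if self.n_anchors > self.module_sizes[self.anchor_module]:
            raise ValidationError("more anchors than anchor-module nodes")

    @property
    def effective_background_p(self) -> float:
        return self.inter_p if self.background_p is None else self.background_p


@dataclass(frozen=True)
class GroundTruth:
    """Planted memberships of a generated network."""

    modules: tuple[frozenset[str], ...]
    anchors: frozenset[str]
    satellites: frozenset[str]
    background: frozenset[str]


def _module_nodes(spec: PlantedSpec) -> list[list[str]]:
    """Deterministic node labels per module, with shared overlap nodes."""
    modules: list[list[str]] = [[] for _ in spec.module_sizes]
    for (i, j) in sorted(spec.overlap_map):
        k = spec.overlap_map[(i, j)]
        for t in range(k):
            name = f"SH{i + 1}{j + 1}N{t + 1:02d}"
            modules[i].append(name)
            modules[j].append(name)
    for i, size in enumerate(spec.module_sizes):
        n_own = size - len(modules[i])
        if n_own < 0:
            raise ValidationError(f"module {i} smaller than its shared nodes")
        for t in range(n_own):
            modules[i].append(f"M{i + 1}N{t + 1:02d}")
    return modules


def planted_network(spec: PlantedSpec) -> tuple[PPINetwork, GroundTruth]:
    """Sample one network from a planted spec; fully seed-determined.

    Module pairs get Bernoulli(``intra_p``) edges, cross-module and
    background pairs Bernoulli(``inter_p``/``background_p``); satellites
    attach to ``satellite_degree`` distinct anchors and nowhere else.
    """
    rng = np.random.default_rng(spec.rng_seed)
    modules = _module_nodes(spec)
    module_sets = [set(m) for m in modules]
    anchor_nodes = sorted(module_sets[spec.anchor_module])[: spec.n_anchors]
    satellites = [f"SAT{t + 1:02d}" for t in range(spec.n_satellites)]
    background = [f"BG{t + 1:02d}" for t in range(spec.n_background)]

    records: list[InteractionRecord] = []

    # intra-module pairs (a pair lying in several shared modules is
    # sampled once)
    intra_pairs: set[tuple[str, str]] = set()
    for members in module_sets:
        nodes = sorted(members)
        for a_i in range(len(nodes)):
            for b_i in range(a_i + 1, len(nodes)):
                intra_pairs.add((nodes[a_i], nodes[b_i]))
    for a, b in sorted(intra_pairs):
        if rng.random() < spec.intra_p:
            records.append(InteractionRecord(a, b, frozenset({"synthetic"})))

    # cross-module pairs: endpoints in different modules with no module
    # in common
    all_module_nodes = sorted(set().union(*module_sets)) if module_sets else []
    membership = {
        n: frozenset(i for i, s in enumerate(module_sets) if n in s)
        for n in all_module_nodes
    }
    for a_i in range(len(all_module_nodes)):
        for b_i in range(a_i + 1, len(all_module_nodes)):
            a, b = all_module_nodes[a_i], all_module_nodes[b_i]
            if membership[a] & membership[b]:
                continue
            if rng.random() < spec.inter_p:
                records.append(InteractionRecord(a, b, frozenset({"synthetic"})))

    # background pairs: background-background and background-module.
    # Anchors receive no random background edges: the anchor-adjacent
    # low-degree proteins must be exactly the planted satellites, or the
    # ground truth would mislabel its own candidates.
    bg_p = spec.effective_background_p
    bg_partners = sorted(
        (set(background) | set(all_module_nodes)) - set(anchor_nodes)
    )
    for a_i, a in enumerate(background):
        for b in bg_partners:
            if b <= a and b in set(background):
                continue  # each background-background pair once
            if b == a:
                continue
            if rng.random() < bg_p:
                records.append(InteractionRecord(a, b, frozenset({"synthetic"})))

    # satellites: anchor edges only
    for sat in satellites:
        chosen = rng.choice(
            np.asarray(anchor_nodes, dtype=object),
            size=spec.satellite_degree,
            replace=False,
        )
        for anchor in sorted(chosen):
            records.append(InteractionRecord(sat, str(anchor), frozenset({"synthetic"})))

    network = build_network(records)
    for name in all_module_nodes + satellites + background:
        if name not in network:
            network.add_protein(ProteinRef(name, origin=ProteinOrigin.DATABASE))
    truth = GroundTruth(
        modules=tuple(frozenset(m) for m in module_sets),
        anchors=frozenset(anchor_nodes),
        satellites=frozenset(satellites),
        background=frozenset(background),
    )
    return network, truth


def discovery_scenario(
    rng_seed: int,
) -> tuple[PPINetwork, GroundTruth, SeedList]:
    """The fixed-shape candidate-discovery instance.

    Two dense modules — A with 17 nodes (containing the 2 anchors) and B
    with 8 nodes — with within-module edge probability 0.85 and 0.15
    between them; 5 satellites with 2 anchor edges each; 60 background
    nodes wired at probability 0.02.  The seed list is module B plus the
    anchors (10 proteins), mirroring a complex whose subunits split
    between two sub-complexes.
    """
    spec = PlantedSpec(
        module_sizes=(17, 8),
        intra_p=0.85,
        inter_p=0.15,
        n_anchors=2,
        anchor_module=0,
        n_satellites=5,
        satellite_degree=2,
        n_background=60,
        background_p=0.02,
        rng_seed=rng_seed,
    )
    network, truth = planted_network(spec)
    seed_names = sorted(truth.modules[1]) + sorted(truth.anchors)
    roles = {name: "core" for name in truth.modules[1]}
    roles.update({name: "supernumerary" for name in truth.anchors})
    seeds = SeedList(tuple(seed_names), roles)
    return network, truth, seeds


def split_snapshots(
    network: PPINetwork, frac_shared: float, rng_seed: int
) -> tuple[SourceSnapshot, SourceSnapshot]:
    """Split a network's edges into two partially overlapping snapshots.

    Each edge lands in both snapshots with probability ``frac_shared``,
    otherwise in exactly one of them (fair coin).  The union of the two
    snapshots always equals the original edge set.
    """
    if not 0.0 <= frac_shared <= 1.0:
        raise ValidationError("frac_shared must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    rec_a: list[InteractionRecord] = []
    rec_b: list[InteractionRecord] = []
    for a, b in network.edges:
        if rng.random() < frac_shared:
            rec_a.append(InteractionRecord(a, b, frozenset({"SRC_A"})))
            rec_b.append(InteractionRecord(a, b, frozenset({"SRC_B"})))
        elif rng.random() < 0.5:
            rec_a.append(InteractionRecord(a, b, frozenset({"SRC_A"})))
        else:
            rec_b.append(InteractionRecord(a, b, frozenset({"SRC_B"})))
    return (
        SourceSnapshot.from_records("SRC_A", rec_a),
        SourceSnapshot.from_records("SRC_B", rec_b),
    )
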