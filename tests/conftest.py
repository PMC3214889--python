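"""Shared helpers: tiny graphs are built programmatically, never stored."""

from __future__ import annotations

import itertools

import pytest

from ppicluster.graph import InteractionRecord, PPINetwork, build_network


def net_from_edges(edges, nodes=()) -> PPINetwork:
    """Build a PPINetwork from (a, b) pairs plus optional isolated nodes."""
    net = build_network(
        [InteractionRecord(a, b, frozenset({"test"})) for a, b in edges]
    )
    from ppicluster.graph import ProteinRef

    for n in nodes:
        if n not in net:
            net.add_protein(ProteinRef(n))
    return net


def clique_edges(names) -> list[tuple[str, str]]:
    return list(itertools.combinations(sorted(names), 2))


@pytest.fixture
def two_cliques_bridged() -> PPINetwork:
    """Two 5-cliques joined by a single bridge edge."""
    a = [f"A{i}" for i in range(5)]
    b = [f"B{i}" for i in range(5)]
    return net_from_edges(clique_edges(a) + clique_edges(b) + [("A0", "B0")])
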