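"""Directed TF–TF regulatory network container.

Networks are simple directed graphs over TF symbols: no self-loops, no
duplicate edges. Edge direction always runs regulator -> target (the
regulator's binding motif occurs in the target's promoter). The container is
deliberately small; anything algorithmic lives in the topology / motifs / ffl
modules, and :meth:`DirectedNetwork.to_networkx` bridges to networkx where a
standard graph algorithm is the right tool.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

Edge = tuple[str, str]


@dataclass
class DirectedNetwork:
    """A simple digraph of regulator -> target edges among TF symbols.

    Parameters
    ----------
    nodes
        TF symbols. Always a superset of the endpoints of ``edges``; isolated
        nodes are allowed (they arise when a TF loses all its support in a
        grade but the caller wants to keep it in the symbol space).
    edges
        Ordered (regulator, target) pairs. Self-loops are rejected.
    grade
        Optional grade label (e.g. ``"II"``) for grade-specific networks.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        self.nodes = set(self.nodes)
        self.edges = set(self.edges)
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v} not allowed")
        self.nodes |= {n for e in self.edges for n in e}

    @classmethod
    def from_edges(cls, edges: Iterable[Edge], grade: Optional[str] = None,
                   drop_self_loops: bool = False) -> "DirectedNetwork":
        edges = set(edges)
        if drop_self_loops:
            edges = {(u, v) for u, v in edges if u != v}
        return cls(nodes=set(), edges=edges, grade=grade)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self.edges

    def out_degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for u, _ in self.edges:
            deg[u] += 1
        return deg

    def in_degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for _, v in self.edges:
            deg[v] += 1
        return deg

    def subgraph_nodes(self) -> set[str]:
        """Nodes incident to at least one edge."""
        return {n for e in self.edges for n in e}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        if self.grade is not None:
            g.graph["grade"] = self.grade
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph, grade: Optional[str] = None) -> "DirectedNetwork":
        return cls(nodes=set(g.nodes), edges=set(g.edges),
                   grade=grade if grade is not None else g.graph.get("grade"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges
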