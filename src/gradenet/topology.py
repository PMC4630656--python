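"""Degree structure, hubs, connectivity and cross-grade edge overlap."""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .network import DirectedNetwork


@dataclass(frozen=True)
class DegreeRecord:
    tf: str
    out_degree: int
    in_degree: int

    @property
    def total_degree(self) -> int:
        return self.out_degree + self.in_degree


def degree_table(net: DirectedNetwork) -> list[DegreeRecord]:
    """One (out-degree, in-degree) record per node; sums equal |edges|."""
    out_deg = net.out_degree()
    in_deg = net.in_degree()
    return [DegreeRecord(tf=n, out_degree=out_deg[n], in_degree=in_deg[n])
            for n in sorted(net.nodes)]


def degree_frame(net: DirectedNetwork) -> pd.DataFrame:
    recs = degree_table(net)
    return pd.DataFrame({"tf": [r.tf for r in recs],
                         "out_degree": [r.out_degree for r in recs],
                         "in_degree": [r.in_degree for r in recs]})


def multiplicity_fractions(net: DirectedNetwork,
                           denominator: str = "all") -> tuple[float, float]:
    """Fractions of TFs regulating >= 2 targets / co-regulated by >= 2 TFs.

    ``denominator="all"`` uses every network node (the default reading of
    "% of the TFs"); ``"active"`` restricts to nodes with out-degree >= 1
    (resp. in-degree >= 1).
    """
    if net.n_nodes == 0:
        raise ConfigurationError("empty network")
    recs = degree_table(net)
    if denominator == "all":
        d_out = d_in = len(recs)
    elif denominator == "active":
        d_out = sum(1 for r in recs if r.out_degree >= 1) or 1
        d_in = sum(1 for r in recs if r.in_degree >= 1) or 1
    else:
        raise ConfigurationError(f"unknown denominator {denominator!r}")
    multi_target = sum(1 for r in recs if r.out_degree >= 2)
    multi_reg = sum(1 for r in recs if r.in_degree >= 2)
    return multi_target / d_out, multi_reg / d_in


def hubs(net: DirectedNetwork, top_fraction: float = 0.10,
         degree: str = "total") -> set[str]:
    """TFs whose degree reaches the top ``top_fraction`` of the network.

    The cutoff is the (1 - top_fraction) quantile of the degree distribution;
    every node tied with the cutoff is included, so the result is
    order-independent. ``degree`` is "total" (in + out, the default) or
    "out".
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ConfigurationError("top_fraction must be in (0, 1]")
    recs = degree_table(net)
    if not recs:
        return set()
    if degree == "total":
        values = np.array([r.total_degree for r in recs], dtype=float)
    elif degree == "out":
        values = np.array([r.out_degree for r in recs], dtype=float)
    else:
        raise ConfigurationError(f"unknown degree kind {degree!r}")
    cutoff = np.quantile(values, 1.0 - top_fraction)
    return {r.tf for r, v in zip(recs, values) if v >= cutoff}


def edge_overlap(nets: list[DirectedNetwork]) -> dict:
    """Cross-grade edge sharing over the union of edges.

    Returns the per-edge grade membership plus summary fractions: the share
    of union edges present in >= 2 networks and, per network, the fraction
    of its edges unique to it.
    """
    if len(nets) < 2:
        raise ConfigurationError("need at least two networks")
    labels = [net.grade if net.grade is not None else f"net{i}"
              for i, net in enumerate(nets)]
    membership: dict[tuple[str, str], set[str]] = {}
    for label, net in zip(labels, nets):
        for e in net.edges:
            membership.setdefault(e, set()).add(label)
    union = len(membership)
    shared = sum(1 for grades in membership.values() if len(grades) >= 2)
    specific = {}
    for label, net in zip(labels, nets):
        if net.n_edges:
            unique = sum(1 for e in net.edges if len(membership[e]) == 1)
            specific[label] = unique / net.n_edges
        else:
            specific[label] = 0.0
    return {
        "labels": labels,
        "union_edges": union,
        "shared_fraction": shared / union if union else 0.0,
        "grade_specific_fraction": specific,
        "edge_grades": membership,
    }


def largest_weak_component(net: DirectedNetwork) -> tuple[int, float]:
    """Size and node fraction of the largest weakly connected component."""
    if net.n_nodes == 0:
        raise ConfigurationError("empty network")
    g = net.to_networkx()
    size = max(len(c) for c in nx.weakly_connected_components(g))
    return size, size / net.n_nodes
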