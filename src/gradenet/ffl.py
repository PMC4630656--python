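"""Feedforward-loop enumeration, positional frequencies and cross-grade
motif conservation.

An FFL is the triad top -> middle, top -> bottom, middle -> bottom: signal
propagates from the top TF through the middle TF to the bottom TF with
direct top-to-bottom reinforcement. Enumeration is *induced* by default
(no other edge may exist among the triple), consistent with the triad-census
convention — the FFL count then equals the census's feedforward class. A
non-induced mode counts every (top, middle, bottom) assignment whose three
edges are present regardless of extra edges.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd

from .errors import UndefinedProfileError
from .motifs import (TriadProfile, _PAIR_BIT, connected_triples, ffl_class_id,
                     motif_zscores, _tables)
from .network import DirectedNetwork
from .synth import FFLInstance

__all__ = ["FFLInstance", "find_ffls", "position_frequencies",
           "motif_instance_overlap", "conserved_edge_motifs"]

_FFL_CODE = _PAIR_BIT[(0, 1)] | _PAIR_BIT[(0, 2)] | _PAIR_BIT[(1, 2)]


@dataclass(frozen=True)
class PositionFrequency:
    """How often a TF occupies each FFL position in one network."""

    tf: str
    n_ffls: int
    freq_top: float
    freq_middle: float
    freq_bottom: float
    grade: str | None = None


def find_ffls(net: DirectedNetwork, induced: bool = True) -> list[FFLInstance]:
    """All FFL instances, in lexicographic (top, middle, bottom) order.

    Induced mode: the triple's induced subgraph must be exactly the FFL
    pattern (one instance per triple). Non-induced mode: every ordered
    assignment with the three FFL edges present counts, so a single triple
    can yield several instances (a 3-clique yields six).
    """
    nodes = sorted(net.nodes)
    found: list[FFLInstance] = []
    if induced:
        _, table = _tables()
        ffl_idx = ffl_class_id() - 1
        for (a, b, c), code in connected_triples(net):
            if table[code] != ffl_idx:
                continue
            triple = (nodes[a], nodes[b], nodes[c])
            out_deg = {t: sum(1 for u in triple if u != t and net.has_edge(t, u))
                       for t in triple}
            in_deg = {t: sum(1 for u in triple if u != t and net.has_edge(u, t))
                      for t in triple}
            top = next(t for t in triple if out_deg[t] == 2)
            bottom = next(t for t in triple if in_deg[t] == 2)
            middle = next(t for t in triple if t not in (top, bottom))
            found.append(FFLInstance(top, middle, bottom))
    else:
        for a, b, c in combinations(nodes, 3):
            for top, mid, bot in permutations((a, b, c)):
                if (net.has_edge(top, mid) and net.has_edge(top, bot)
                        and net.has_edge(mid, bot)):
                    found.append(FFLInstance(top, mid, bot))
    found.sort(key=lambda f: f.tfs)
    return found


def position_frequencies(ffls: list[FFLInstance],
                         grade: str | None = None) -> list[PositionFrequency]:
    """Per TF, the relative frequency of appearing top / middle / bottom."""
    counts: dict[str, np.ndarray] = {}
    for f in ffls:
        for pos, tf in enumerate(f.tfs):
            counts.setdefault(tf, np.zeros(3))[pos] += 1
    out = []
    for tf in sorted(counts):
        c = counts[tf]
        total = int(c.sum())
        out.append(PositionFrequency(tf=tf, n_ffls=total,
                                     freq_top=c[0] / total,
                                     freq_middle=c[1] / total,
                                     freq_bottom=c[2] / total, grade=grade))
    return out


def position_frequency_frame(freqs: list[PositionFrequency]) -> pd.DataFrame:
    return pd.DataFrame({
        "tf": [f.tf for f in freqs],
        "grade": [f.grade for f in freqs],
        "n_ffls": [f.n_ffls for f in freqs],
        "freq_top": [f.freq_top for f in freqs],
        "freq_middle": [f.freq_middle for f in freqs],
        "freq_bottom": [f.freq_bottom for f in freqs],
    })


def motif_instance_overlap(net_a: DirectedNetwork, net_b: DirectedNetwork) -> dict:
    """Cross-grade conservation of three-node motif instances.

    For each triad class: how many node triples realize the class in both
    networks with identical wiring, and the fraction of the class's triple
    union that does. Also reports combination maintenance — triples that are
    connected in both networks regardless of class — as a fraction of the
    union of connected triples. Symmetric in its arguments.
    """
    classes, table = _tables()

    def triple_map(net: DirectedNetwork) -> dict[tuple[str, str, str], tuple[int, int]]:
        nodes = sorted(net.nodes)
        return {tuple(nodes[i] for i in triple): (int(table[code]), code)
                for triple, code in connected_triples(net)}

    map_a, map_b = triple_map(net_a), triple_map(net_b)
    common_triples = set(map_a) & set(map_b)
    union_triples = set(map_a) | set(map_b)
    per_class = []
    for ci, cls in enumerate(classes):
        in_a = {t for t, (c, _) in map_a.items() if c == ci}
        in_b = {t for t, (c, _) in map_b.items() if c == ci}
        identical = sum(1 for t in in_a & in_b if map_a[t][1] == map_b[t][1])
        union = len(in_a | in_b)
        per_class.append({
            "class_id": cls.class_id,
            "name": cls.name,
            "alias": cls.alias,
            "n_identical": identical,
            "n_union": union,
            "identical_fraction": identical / union if union else 0.0,
        })
    return {
        "per_class": per_class,
        "n_common_combinations": len(common_triples),
        "n_union_combinations": len(union_triples),
        "combination_fraction": (len(common_triples) / len(union_triples)
                                 if union_triples else 0.0),
    }


def conserved_edge_motifs(net_a: DirectedNetwork, net_b: DirectedNetwork,
                          n_random: int = 1000, seed: int = 0,
                          swaps_per_edge: int = 100) -> TriadProfile:
    """Triad significance profile of the edge-intersection network.

    Builds the network of edges present in both grades and runs the motif
    Z-score pipeline on it; an empty intersection has no profile.
    """
    edges = net_a.edges & net_b.edges
    if not edges:
        raise UndefinedProfileError("edge intersection is empty")
    inter = DirectedNetwork.from_edges(edges)
    return motif_zscores(inter, n_random=n_random, seed=seed,
                         swaps_per_edge=swaps_per_edge)
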