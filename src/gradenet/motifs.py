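"""Directed triad census, degree-preserving randomization and triad
significance profiles (TSPs).

Exactly 13 isomorphism classes of weakly connected simple digraphs on three
nodes exist (no self-loops); they are enumerated here from scratch by
exhausting all 64 labeled 3-node digraphs and grouping by isomorphism. The
census counts *induced* subgraphs: every unordered node triple whose induced
subgraph is weakly connected increments exactly one class, so class counts
are disjoint and sum to the number of connected triples.

The null model is Milo-style degree-preserving edge switching: repeated
random swaps (a->b, c->d) => (a->d, c->b) that keep every node's in- and
out-degree; by default mutual (reciprocal) dyads are switched separately
from single edges so the count of mutual dyads is also invariant. Z-scores
of the real counts against the randomized ensemble, normalized to unit
Euclidean length, form the triad significance profile.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterator, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedProfileError
from .network import DirectedNetwork

# fixed bit order for the 6 ordered node pairs of a labeled 3-node digraph
_PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))
_PAIR_BIT = {p: 1 << i for i, p in enumerate(_PAIRS)}

#: triad class count for connected 3-node digraphs
N_TRIAD_CLASSES = 13

# conventional names for the classes biologists refer to most
_ALIASES = {
    "030T": "feedforward_loop",
    "030C": "cycle",
    "300": "clique",
    "201": "regulated_mutual",
}

# MAN-style labels for the 13 connected classes, keyed by canonical code
# (computed lazily the first time classes are enumerated)


def _permute_code(code: int, perm: Sequence[int]) -> int:
    """Code of the digraph after relabeling node i -> perm[i]."""
    out = 0
    for (u, v), bit in _PAIR_BIT.items():
        if code & _PAIR_BIT[(u, v)]:
            out |= _PAIR_BIT[(perm[u], perm[v])]
    return out


def _is_weakly_connected(code: int) -> bool:
    und = ((1 if code & (_PAIR_BIT[(0, 1)] | _PAIR_BIT[(1, 0)]) else 0)
           + (1 if code & (_PAIR_BIT[(0, 2)] | _PAIR_BIT[(2, 0)]) else 0)
           + (1 if code & (_PAIR_BIT[(1, 2)] | _PAIR_BIT[(2, 1)]) else 0))
    return und >= 2


def _canonical_code(code: int) -> int:
    return min(_permute_code(code, perm) for perm in permutations(range(3)))


def _man_label(code: int) -> str:
    """Standard sociometric triad label (e.g. 030T) via networkx."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(3))
    g.add_edges_from(p for p, bit in _PAIR_BIT.items() if code & bit)
    return nx.triad_type(g)


@dataclass(frozen=True)
class TriadClass:
    """One isomorphism class of connected 3-node digraphs."""

    class_id: int            # 1..13, in canonical-code order
    canonical_code: int      # minimal 6-bit adjacency encoding
    canonical_edges: frozenset[tuple[int, int]]
    name: str                # MAN-style label, e.g. "030T"
    alias: Optional[str] = None  # e.g. "feedforward_loop"


def enumerate_triad_classes() -> list[TriadClass]:
    """The 13 connected triad classes, in a stable canonical order.

    Exhausts all 64 labeled digraphs on 3 nodes, keeps the weakly connected
    ones and groups them by isomorphism (all 6 node relabelings); classes
    are ordered by their minimal adjacency encoding so profiles are
    comparable across runs.
    """
    canonicals = sorted({_canonical_code(code) for code in range(64)
                         if _is_weakly_connected(code)})
    classes = []
    for i, code in enumerate(canonicals, start=1):
        edges = frozenset(p for p, bit in _PAIR_BIT.items() if code & bit)
        name = _man_label(code)
        classes.append(TriadClass(class_id=i, canonical_code=code,
                                  canonical_edges=edges, name=name,
                                  alias=_ALIASES.get(name)))
    return classes


_CLASSES = None
_CODE_TO_CLASS = None


def _tables() -> tuple[list[TriadClass], np.ndarray]:
    """Cached (classes, 64-entry code -> class index) lookup tables."""
    global _CLASSES, _CODE_TO_CLASS
    if _CLASSES is None:
        _CLASSES = enumerate_triad_classes()
        canon_to_idx = {c.canonical_code: c.class_id - 1 for c in _CLASSES}
        table = np.full(64, -1, dtype=np.int64)
        for code in range(64):
            if _is_weakly_connected(code):
                table[code] = canon_to_idx[_canonical_code(code)]
        _CODE_TO_CLASS = table
    return _CLASSES, _CODE_TO_CLASS


def triad_classes() -> list[TriadClass]:
    return list(_tables()[0])


def ffl_class_id() -> int:
    """class_id of the feedforward loop among the 13 classes."""
    return next(c.class_id for c in _tables()[0] if c.alias == "feedforward_loop")


# ---------------------------------------------------------------------------
# Census


def _indexed(net: DirectedNetwork) -> tuple[list[str], dict[str, int], set[int], int]:
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    edge_codes = {idx[u] * n + idx[v] for u, v in net.edges}
    return nodes, idx, edge_codes, n


def connected_triples(net: DirectedNetwork) -> Iterator[tuple[tuple[int, int, int], int]]:
    """Yield ((i, j, k) sorted node indices, 6-bit induced code) for every
    unordered triple whose induced subgraph is weakly connected."""
    nodes, idx, edge_codes, n = _indexed(net)
    und: dict[int, set[int]] = {i: set() for i in range(n)}
    for u, v in net.edges:
        iu, iv = idx[u], idx[v]
        und[iu].add(iv)
        und[iv].add(iu)
    seen: set[tuple[int, int, int]] = set()
    for iu in range(n):
        for iv in und[iu]:
            if iv <= iu:
                continue
            for iw in und[iu] | und[iv]:
                if iw == iu or iw == iv:
                    continue
                triple = tuple(sorted((iu, iv, iw)))
                if triple in seen:
                    continue
                seen.add(triple)
                a, b, c = triple
                code = 0
                if a * n + b in edge_codes:
                    code |= _PAIR_BIT[(0, 1)]
                if a * n + c in edge_codes:
                    code |= _PAIR_BIT[(0, 2)]
                if b * n + a in edge_codes:
                    code |= _PAIR_BIT[(1, 0)]
                if b * n + c in edge_codes:
                    code |= _PAIR_BIT[(1, 2)]
                if c * n + a in edge_codes:
                    code |= _PAIR_BIT[(2, 0)]
                if c * n + b in edge_codes:
                    code |= _PAIR_BIT[(2, 1)]
                yield triple, code


def triad_census(net: DirectedNetwork) -> np.ndarray:
    """Induced counts over the 13 connected triad classes (index = class_id - 1)."""
    _, table = _tables()
    counts = np.zeros(N_TRIAD_CLASSES, dtype=np.int64)
    for _, code in connected_triples(net):
        counts[table[code]] += 1
    return counts


# ---------------------------------------------------------------------------
# Randomization


def randomize(net: DirectedNetwork, seed, swaps_per_edge: int = 100,
              preserve_mutual: bool = True) -> DirectedNetwork:
    """Degree-preserving edge-switching null sample.

    Random swaps (a->b, c->d) => (a->d, c->b) preserve every node's in/out
    degree; swaps that would create a self-loop or duplicate edge are
    rejected. With ``preserve_mutual`` (default), single edges and mutual
    dyads are switched in separate pools — mutual pairs are rewired as
    undirected edges — so the number of reciprocal dyads is invariant too.
    ``seed`` is anything :func:`numpy.random.default_rng` accepts.
    """
    if net.n_edges < 2:
        raise ConfigurationError("need at least 2 edges to randomize")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    edges = {(idx[u], idx[v]) for u, v in net.edges}
    edge_set = {u * n + v for u, v in edges}

    if preserve_mutual:
        mutual = sorted({(min(u, v), max(u, v)) for u, v in edges
                         if (v, u) in edges})
        singles = sorted(e for e in edges if (e[1], e[0]) not in edges)
    else:
        mutual = []
        singles = sorted(edges)

    check_reverse = preserve_mutual

    def switch_singles(pool: list[tuple[int, int]]) -> None:
        if len(pool) < 2:
            return
        arr = [list(e) for e in pool]
        m = len(arr)
        n_attempts = swaps_per_edge * m
        ii = rng.integers(0, m, size=n_attempts)
        jj = rng.integers(0, m, size=n_attempts)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if i == j:
                continue
            a, b = arr[i]
            c, d = arr[j]
            if a == d or c == b:
                continue
            nad, ncb = a * n + d, c * n + b
            if nad in edge_set or ncb in edge_set:
                continue
            if check_reverse and (d * n + a in edge_set or b * n + c in edge_set):
                continue
            edge_set.discard(a * n + b)
            edge_set.discard(c * n + d)
            edge_set.add(nad)
            edge_set.add(ncb)
            arr[i][1] = d
            arr[j][1] = b

    def switch_mutual(pool: list[tuple[int, int]]) -> None:
        if len(pool) < 2:
            return
        arr = [list(e) for e in pool]
        m = len(arr)
        n_attempts = swaps_per_edge * m
        ii = rng.integers(0, m, size=n_attempts)
        jj = rng.integers(0, m, size=n_attempts)
        flip = rng.random(n_attempts) < 0.5
        for i, j, fl in zip(ii.tolist(), jj.tolist(), flip.tolist()):
            if i == j:
                continue
            a, b = arr[i]
            c, d = arr[j]
            if fl:
                c, d = d, c
            if len({a, b, c, d}) < 4:
                continue
            # rewire {a,b},{c,d} -> {a,d},{c,b}; no edge may exist either way
            if (a * n + d in edge_set or d * n + a in edge_set
                    or c * n + b in edge_set or b * n + c in edge_set):
                continue
            for u, v in ((a, b), (c, d)):
                edge_set.discard(u * n + v)
                edge_set.discard(v * n + u)
            for u, v in ((a, d), (c, b)):
                edge_set.add(u * n + v)
                edge_set.add(v * n + u)
            arr[i] = [a, d]
            arr[j] = [c, b]

    switch_singles(singles)
    switch_mutual(mutual)

    out_edges = {(nodes[code // n], nodes[code % n]) for code in edge_set}
    return DirectedNetwork(nodes=set(nodes), edges=out_edges, grade=net.grade)


# ---------------------------------------------------------------------------
# Z-scores and significance profiles


@dataclass
class TriadProfile:
    """Real counts, randomized-null statistics and the normalized profile."""

    counts: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    z_scores: np.ndarray
    normalized_profile: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(N_TRIAD_CLASSES, bool))
    n_random: int = 0

    @property
    def classes(self) -> list[TriadClass]:
        return triad_classes()

    def to_dict(self) -> dict:
        classes = self.classes
        return {
            "n_random": self.n_random,
            "classes": [{
                "class_id": c.class_id,
                "name": c.name,
                "alias": c.alias,
                "count": int(self.counts[i]),
                "null_mean": float(self.null_mean[i]),
                "null_sd": float(self.null_sd[i]),
                "z": float(self.z_scores[i]),
                "normalized": float(self.normalized_profile[i]),
                "degenerate": bool(self.degenerate[i]),
            } for i, c in enumerate(classes)],
        }


def normalize_profile(z: np.ndarray) -> np.ndarray:
    """Unit-Euclidean-length version of a Z-score vector."""
    z = np.asarray(z, dtype=float)
    norm = float(np.linalg.norm(z))
    if norm == 0.0:
        raise UndefinedProfileError("all Z-scores are zero; profile undefined")
    return z / norm


def motif_zscores(net: DirectedNetwork, n_random: int = 1000, seed: int = 0,
                  swaps_per_edge: int = 100,
                  preserve_mutual: bool = True) -> TriadProfile:
    """Triad significance profile of a network against its switching null.

    Z_i = (count_i - null_mean_i) / null_sd_i per class, estimated from
    ``n_random`` independent randomizations of the input (sample sd, ddof 1).
    Classes with zero null sd get Z = 0 when the real count equals the null
    mean and are flagged degenerate otherwise. The normalized profile is the
    Z vector scaled to unit length (an all-zero Z yields an all-zero
    profile; :func:`normalize_profile` raises on that case instead).
    """
    if n_random < 2:
        raise ConfigurationError("n_random must be >= 2")
    if net.n_edges == 0:
        raise UndefinedProfileError("empty network")
    counts = triad_census(net).astype(float)
    null = np.empty((n_random, N_TRIAD_CLASSES))
    for i in range(n_random):
        rnd = randomize(net, seed=[seed, i], swaps_per_edge=swaps_per_edge,
                        preserve_mutual=preserve_mutual)
        null[i] = triad_census(rnd)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.zeros(N_TRIAD_CLASSES)
    degenerate = np.zeros(N_TRIAD_CLASSES, dtype=bool)
    nonzero = sd > 0
    z[nonzero] = (counts[nonzero] - mean[nonzero]) / sd[nonzero]
    degenerate[~nonzero & (counts != mean)] = True
    norm = float(np.linalg.norm(z))
    normalized = z / norm if norm > 0 else np.zeros_like(z)
    return TriadProfile(counts=counts.astype(np.int64), null_mean=mean,
                        null_sd=sd, z_scores=z, normalized_profile=normalized,
                        degenerate=degenerate, n_random=n_random)


def classify_enrichment(normalized_profile: np.ndarray) -> list[str]:
    """Per class: 'enriched' (> 0), 'depleted' (< 0) or 'neutral' (== 0)."""
    out = []
    for v in np.asarray(normalized_profile, dtype=float):
        out.append("enriched" if v > 0 else ("depleted" if v < 0 else "neutral"))
    return out
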