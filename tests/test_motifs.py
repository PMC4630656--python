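"""Triad classes, census, randomization null and significance profiles.

Census correctness is checked against an independent brute force that walks
every node triple, tests weak connectivity by hand and classifies the
induced pattern by explicit isomorphism testing over all six relabelings.
"""
from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gradenet.errors import ConfigurationError, UndefinedProfileError
from gradenet.motifs import (N_TRIAD_CLASSES, classify_enrichment,
                             enumerate_triad_classes, ffl_class_id,
                             motif_zscores, normalize_profile, randomize,
                             triad_census, triad_classes)
from gradenet.network import DirectedNetwork
from conftest import random_network


def brute_force_census(net: DirectedNetwork) -> np.ndarray:
    """Exhaustive per-triple classification with explicit isomorphism tests."""
    classes = triad_classes()
    counts = np.zeros(N_TRIAD_CLASSES, dtype=int)
    nodes = sorted(net.nodes)
    for triple in combinations(nodes, 3):
        sub = {(a, b) for a in triple for b in triple
               if a != b and net.has_edge(a, b)}
        touched = {x for e in sub for x in e}
        # weak connectivity by hand: grow a component from one node
        if len(touched) < 3:
            continue
        comp = {triple[0]}
        changed = True
        while changed:
            changed = False
            for a, b in sub:
                if (a in comp) != (b in comp):
                    comp |= {a, b}
                    changed = True
        if len(comp) < 3:
            continue
        idx = {t: i for i, t in enumerate(triple)}
        pattern = {(idx[a], idx[b]) for a, b in sub}
        for cls in classes:
            if any({(perm[a], perm[b]) for a, b in pattern} == set(cls.canonical_edges)
                   for perm in permutations(range(3))):
                counts[cls.class_id - 1] += 1
                break
        else:  # pragma: no cover - would mean a 14th class exists
            raise AssertionError(f"unclassifiable pattern {pattern}")
    return counts


class TestTriadClasses:
    def test_exactly_thirteen_connected_classes(self):
        classes = enumerate_triad_classes()
        assert len(classes) == 13
        assert len({c.canonical_code for c in classes}) == 13

    def test_classes_mutually_non_isomorphic(self):
        codes = [set(c.canonical_edges) for c in enumerate_triad_classes()]
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                assert not any(
                    {(p[u], p[v]) for u, v in a} == b
                    for p in permutations(range(3)))

    def test_ffl_and_clique_are_classes(self):
        aliases = {c.alias for c in enumerate_triad_classes()}
        assert {"feedforward_loop", "clique", "cycle"} <= aliases
        ffl = next(c for c in enumerate_triad_classes()
                   if c.alias == "feedforward_loop")
        assert set(ffl.canonical_edges) == {(0, 1), (0, 2), (1, 2)}
        clique = next(c for c in enumerate_triad_classes() if c.alias == "clique")
        assert len(clique.canonical_edges) == 6


class TestCensus:
    def test_pure_ffl_graph(self):
        net = DirectedNetwork.from_edges({("A", "B"), ("A", "C"), ("B", "C")})
        counts = triad_census(net)
        assert counts[ffl_class_id() - 1] == 1
        assert counts.sum() == 1

    def test_three_cycle(self):
        net = DirectedNetwork.from_edges({("A", "B"), ("B", "C"), ("C", "A")})
        counts = triad_census(net)
        cyc = next(c for c in triad_classes() if c.alias == "cycle")
        assert counts[cyc.class_id - 1] == 1
        assert counts.sum() == 1

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(12):
            n = int(rng.integers(6, 16))
            net = random_network(rng, n, float(rng.uniform(0.05, 0.4)))
            assert (triad_census(net) == brute_force_census(net)).all()

    def test_total_equals_connected_triple_count(self, rng):
        net = random_network(rng, 15, 0.2)
        assert triad_census(net).sum() == brute_force_census(net).sum()


class TestRandomize:
    def test_degree_sequences_always_preserved(self, rng):
        net = random_network(rng, 25, 0.15)
        for i in range(20):
            rnd = randomize(net, seed=[5, i], swaps_per_edge=10)
            assert rnd.out_degree() == net.out_degree()
            assert rnd.in_degree() == net.in_degree()
            assert all(u != v for u, v in rnd.edges)
            assert len(rnd.edges) == len(net.edges)

    def test_mutual_dyad_count_preserved_by_default(self, rng):
        net = random_network(rng, 25, 0.25)

        def n_mutual(n):
            return sum(1 for u, v in n.edges if (v, u) in n.edges) // 2

        base = n_mutual(net)
        assert base > 0  # the test graph must actually contain mutual dyads
        for i in range(20):
            assert n_mutual(randomize(net, seed=[6, i], swaps_per_edge=10)) == base

    def test_four_cycle_stays_valid_simple_digraph(self):
        net = DirectedNetwork.from_edges(
            {("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")})
        for i in range(10):
            rnd = randomize(net, seed=i, swaps_per_edge=50)
            assert rnd.out_degree() == net.out_degree()
            assert rnd.in_degree() == net.in_degree()
            assert all(u != v for u, v in rnd.edges)

    def test_randomization_actually_moves_edges(self, rng):
        net = random_network(rng, 40, 0.1)
        rnd = randomize(net, seed=1, swaps_per_edge=100)
        assert rnd.edges != net.edges

    def test_too_small_graph_rejected(self):
        with pytest.raises(ConfigurationError):
            randomize(DirectedNetwork.from_edges({("A", "B")}), seed=0)


class TestZScoresAndProfiles:
    def test_ffl_rich_graph_has_positive_ffl_zscore(self, rng):
        edges = set()
        for k in range(30):
            a, b, c = f"t{k}", f"m{k}", f"b{k}"
            edges |= {(a, b), (a, c), (b, c)}
        # stitch the FFLs together so switching has room to destroy them
        for k in range(29):
            edges.add((f"b{k}", f"t{k+1}"))
        net = DirectedNetwork.from_edges(edges)
        prof = motif_zscores(net, n_random=100, seed=2, swaps_per_edge=10)
        assert prof.z_scores[ffl_class_id() - 1] > 2.0

    def test_count_equal_to_null_mean_gives_zero_z(self):
        # a graph whose structure switching cannot change: single FFL
        net = DirectedNetwork.from_edges({("A", "B"), ("A", "C"), ("B", "C")})
        prof = motif_zscores(net, n_random=20, seed=0)
        i = ffl_class_id() - 1
        assert prof.null_sd[i] == 0.0 and prof.z_scores[i] == 0.0
        assert not prof.degenerate[i]

    def test_unit_norm_profile(self, rng):
        net = random_network(rng, 30, 0.1)
        prof = motif_zscores(net, n_random=50, seed=3, swaps_per_edge=10)
        assert np.linalg.norm(prof.normalized_profile) == pytest.approx(1.0, abs=1e-12)

    def test_n_random_lower_bound(self, rng):
        with pytest.raises(ConfigurationError):
            motif_zscores(random_network(rng, 10, 0.3), n_random=1)


class TestNormalizeProfile:
    def test_already_unit(self):
        z = np.zeros(13)
        z[0] = 1.0
        assert normalize_profile(z).tolist() == z.tolist()

    def test_three_four_five(self):
        z = np.zeros(13)
        z[0], z[1] = 3.0, 4.0
        out = normalize_profile(z)
        assert out[0] == pytest.approx(0.6) and out[1] == pytest.approx(0.8)

    @given(st.lists(st.floats(-100, 100, allow_subnormal=False), min_size=13,
                    max_size=13).filter(lambda v: any(abs(x) > 1e-6 for x in v)))
    def test_always_unit_norm(self, values):
        assert np.linalg.norm(normalize_profile(np.array(values))) == pytest.approx(
            1.0, abs=1e-9)

    def test_all_zero_is_undefined(self):
        with pytest.raises(UndefinedProfileError):
            normalize_profile(np.zeros(13))


def test_tsp_similar_across_grades_but_not_for_unfiltered_prior(small_bundle):
    """Networks with the same planted motif composition have nearly parallel
    significance profiles; the unfiltered binding prior does not share them."""
    truth = small_bundle.truth
    nets = {g: DirectedNetwork.from_edges(truth.active_edges_by_grade[g])
            for g in ("II", "IV")}
    profs = {g: motif_zscores(n, n_random=100, seed=1, swaps_per_edge=10)
             for g, n in nets.items()}
    cos_grades = float(np.dot(profs["II"].normalized_profile,
                              profs["IV"].normalized_profile))
    assert cos_grades > 0.8
    # the planted networks carry strong motif signal (the FFL class above all)
    assert max(np.abs(profs["IV"].z_scores)) > 5.0

    # the unfiltered prior is an ER digraph: no class deviates from its own
    # degree-preserving null, so the grade profiles cannot come from it
    keep = set(sorted(small_bundle.prior.nodes)[:40])
    sub = DirectedNetwork.from_edges(
        {(u, v) for u, v in small_bundle.prior.edges if u in keep and v in keep})
    prior_prof = motif_zscores(sub, n_random=60, seed=2, swaps_per_edge=5)
    assert max(np.abs(prior_prof.z_scores)) < 3.0


def test_classify_enrichment_sign_rule():
    profile = np.zeros(13)
    profile[0], profile[1] = 0.3, -0.1
    labels = classify_enrichment(profile)
    assert labels[0] == "enriched"
    assert labels[1] == "depleted"
    assert labels[2] == "neutral"
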