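from itertools import combinations
from math import comb

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regulonminer.evaluate import (
    best_ease,
    clustering_coefficient,
    ease_score,
    edge_density,
    efficiency_curve,
    evaluate_predictions,
    ncc,
    pcs,
    regulon_coverage,
    true_pair_set,
    wilcoxon_compare,
)
from regulonminer.model import PhyleticProfile, RegulonBenchmark


# --- EASE ------------------------------------------------------------------


def subset_enumeration_ease(M, R, P, k):
    """Oracle: enumerate all P-subsets of a size-M universe with R = first
    R elements, count overlap outcomes, apply the jackknife tail."""
    if k <= 1 or P == 0 or R == 0:
        return 1.0
    counts = {}
    total = 0
    for mask in combinations(range(M), P):
        i = sum(1 for x in mask if x < R)
        counts[i] = counts.get(i, 0) + 1
        total += 1
    return sum(c for i, c in counts.items() if i >= max(k - 1, 1)) / total


def test_ease_matches_subset_enumeration_small_universes():
    for M in (5, 8, 11):
        for R in range(1, M + 1):
            for P in range(1, M + 1):
                for k in range(0, min(P, R) + 1):
                    got = ease_score(P, R, k, M)
                    want = subset_enumeration_ease(M, R, P, k)
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-15), (
                        M, R, P, k,
                    )


def test_ease_frozen_example():
    # |M|=20, |R|=5, |P|=4, k=3: tail from i=2 of the hypergeometric pmf
    want = sum(
        comb(5, i) * comb(15, 4 - i) for i in range(2, 5)
    ) / comb(20, 4)
    assert ease_score(4, 5, 3, 20) == pytest.approx(want)


def test_ease_single_overlap_never_significant():
    assert ease_score(10, 10, 1, 100) == 1.0
    assert ease_score(0, 5, 0, 100) == 1.0


def test_ease_forced_overlap_is_one():
    assert ease_score(20, 20, 20, 20) == 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_ease_monotone_in_overlap(data):
    M = data.draw(st.integers(4, 40))
    R = data.draw(st.integers(1, M))
    P = data.draw(st.integers(1, M))
    scores = [
        ease_score(P, R, k, M) for k in range(max(0, P + R - M), min(P, R) + 1)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))


def test_best_ease_matching_and_disjoint():
    bench = RegulonBenchmark(
        regulons={"CRP": set("abcdefghij"), "FNR": set("xyz")}
    )
    tf, e = best_ease(set("abcdefghij"), bench, universe_size=100)
    assert tf == "CRP" and e < 1e-6
    tf, e = best_ease({"q1", "q2"}, bench, universe_size=100)
    assert tf is None and e == 1.0


def test_best_ease_tie_goes_to_first_tf():
    bench = RegulonBenchmark(regulons={"B": {"a", "b"}, "A": {"a", "b"}})
    tf, _ = best_ease({"a", "b"}, bench, universe_size=10)
    assert tf == "A"


# --- coverage --------------------------------------------------------------


def test_regulon_coverage_basics():
    R = set(map(str, range(10)))
    clusters = [set("0123"), set("456"), {"x"}]
    assert regulon_coverage(R, clusters) == pytest.approx(0.7)
    assert regulon_coverage(R, []) == 0.0
    assert regulon_coverage(R, [R]) == 1.0


def test_regulon_coverage_monotone_in_n():
    R = set(map(str, range(10)))
    clusters = [{str(i)} for i in range(10)]
    vals = [regulon_coverage(R, clusters[:n]) for n in range(11)]
    assert vals == sorted(vals)


# --- graph statistics ------------------------------------------------------


def test_graph_stats_triangle_path_k4_minus_edge():
    tri = nx.complete_graph(3)
    assert clustering_coefficient(tri) == 1.0
    assert edge_density(tri) == 1.0
    assert ncc(tri) == 1.0

    path = nx.path_graph(3)
    assert clustering_coefficient(path) == 0.0
    assert ncc(path) == 0.0

    k4e = nx.complete_graph(4)
    k4e.remove_edge(0, 1)
    # 2 triangles, 8 connected triplets (triplet enumeration oracle)
    assert clustering_coefficient(k4e) == pytest.approx(0.75)
    assert edge_density(k4e) == pytest.approx(5 / 6)
    assert ncc(k4e) == pytest.approx(0.9)


def test_ncc_degenerate_graphs_are_zero():
    g = nx.Graph()
    g.add_nodes_from([1, 2, 3])
    assert ncc(g) == 0.0
    assert ncc(nx.Graph()) == 0.0


# --- efficiency curves -----------------------------------------------------


def test_efficiency_curve_all_true_prefix():
    pairs = [((f"a{i}", f"b{i}"), 10.0 - i) for i in range(5)]
    known = {frozenset((f"a{i}", f"b{i}")) for i in range(5)}
    curve = dict(efficiency_curve(pairs, known, [0, 2, 5, 100]))
    assert curve == {0: 0, 2: 2, 5: 5, 100: 5}


def test_efficiency_curve_random_scores_match_density(rng):
    ids = [f"o{i}" for i in range(40)]
    pairs = list(combinations(ids, 2))
    known = {frozenset(p) for p in pairs[:156]}  # 20% true
    scored = [(p, float(r)) for p, r in zip(pairs, rng.random(len(pairs)))]
    curve = dict(efficiency_curve(scored, known, [400]))
    assert curve[400] == pytest.approx(400 * 0.2, abs=4 * np.sqrt(400 * 0.2 * 0.8))


def test_true_pair_set_counts():
    bench = RegulonBenchmark(regulons={"A": {"x", "y", "z"}, "B": {"x", "q"}})
    pairs = true_pair_set(bench)
    assert pairs == {
        frozenset(("x", "y")), frozenset(("x", "z")), frozenset(("y", "z")),
        frozenset(("x", "q")),
    }


# --- PCS -------------------------------------------------------------------


def _profile(oid, vec):
    return PhyleticProfile(oid, tuple(f"g{i}" for i in range(len(vec))), np.array(vec))


def test_pcs_identical_and_complementary():
    a = _profile("a", [1, 0, 1, 0, 1])
    b = _profile("b", [1, 0, 1, 0, 1])
    c = _profile("c", [0, 1, 0, 1, 0])
    assert pcs(a, b) == pytest.approx(1.0)
    assert pcs(a, c) == pytest.approx(-1.0)


def test_pcs_constant_profile_is_zero():
    a = _profile("a", [1, 1, 1, 1])
    b = _profile("b", [1, 0, 1, 0])
    assert pcs(a, b) == 0.0


def test_pcs_partial_correlation_removes_confounder():
    # two profiles correlated mainly through a shared trend: conditioning on
    # the mean profile lowers the correlation (closed-form check)
    z = [1, 1, 1, 1, 0, 0, 0, 0]
    a = _profile("a", [1, 1, 1, 0, 0, 0, 0, 0])
    b = _profile("b", [0, 1, 1, 1, 0, 0, 0, 0])
    cond = [_profile("z1", z), _profile("z2", z)]
    plain = pcs(a, b)
    partial = pcs(a, b, cond)
    x, y, zz = (np.array(v, dtype=float) for v in ([1,1,1,0,0,0,0,0], [0,1,1,1,0,0,0,0], z))
    def r(u, v):
        return float(np.corrcoef(u, v)[0, 1])
    want = (r(x, y) - r(x, zz) * r(y, zz)) / np.sqrt(
        (1 - r(x, zz) ** 2) * (1 - r(y, zz) ** 2)
    )
    assert partial == pytest.approx(want)
    assert abs(partial) < abs(plain)


# --- rank-sum --------------------------------------------------------------


def test_wilcoxon_strong_shift_detected(rng):
    x = rng.normal(3, 1, 20)
    y = rng.normal(0, 1, 20)
    assert wilcoxon_compare(x, y) < 1e-4


def test_wilcoxon_no_shift_near_half(rng):
    x = rng.normal(0, 1, 30)
    assert 0.2 < wilcoxon_compare(x, x + 0.0) < 0.8


def test_wilcoxon_tiny_samples_exact():
    # n < 3 per group: exact enumeration gives the extreme permutation p
    assert wilcoxon_compare([2.0, 3.0], [0.0, 1.0]) == pytest.approx(1 / 6)


# --- report ----------------------------------------------------------------


def test_evaluate_predictions_report_shape():
    bench = RegulonBenchmark(regulons={"A": {"x", "y", "z"}})
    clusters = [{"x", "y"}, {"q"}]
    rep = evaluate_predictions(clusters, bench, universe_size=20,
                               coverage_grid=[1, 2])
    assert len(rep.best_ease_per_prediction) == 2
    assert rep.best_ease_per_prediction[0][1] == "A"
    assert rep.coverage_per_regulon["A"] == [
        pytest.approx(2 / 3), pytest.approx(2 / 3)
    ]
    d = rep.to_dict()
    assert set(d) == {"best_ease_per_prediction", "coverage_grid",
                      "coverage_per_regulon"}
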