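import networkx as nx
import numpy as np
import pytest

from regulonminer import cliques as cq
from regulonminer.coreg import CoRegEdge, CoRegGraph
from regulonminer.model import MotifSet, PromoterSet
from regulonminer.similarity import SimilarityMatrix

from conftest import site_pwm


def _edge(a, b, matrix, labels):
    m = np.asarray(matrix, dtype=float)
    return CoRegEdge(
        operons=(a, b), crs=1.0, labels=set(labels), omega_max=float(m.max()),
        sim=SimilarityMatrix(a, b, m),
    )


# --- blow-up ---------------------------------------------------------------


def test_blowup_one_gprime_edge_per_label():
    g = CoRegGraph(operon_ids=["A", "B"])
    m = np.array([[0.9, 0.1, 0.1], [0.1, 0.1, 0.1], [0.1, 0.8, 0.1]])
    g.edges[("A", "B")] = _edge("A", "B", m, [(0, 0), (2, 1)])
    gp = cq.blowup(g)
    assert set(gp.nodes()) == {("A", 0), ("B", 0), ("A", 2), ("B", 1)}
    assert gp.number_of_edges() == 2
    assert gp[("A", 0)][("B", 0)]["weight"] > 0


def test_blowup_motif_outside_labels_absent():
    g = CoRegGraph(operon_ids=["A", "B"])
    g.edges[("A", "B")] = _edge("A", "B", np.full((5, 5), 0.1), [(1, 1)])
    gp = cq.blowup(g)
    assert ("A", 0) not in gp and ("A", 2) not in gp


def test_blowup_weights_clipped_at_zero():
    g = CoRegGraph(operon_ids=["A", "B"])
    m = np.array([[0.9, 0.5], [0.1, 0.3]])
    g.edges[("A", "B")] = _edge("A", "B", m, [(0, 0), (1, 0)])
    gp = cq.blowup(g)
    assert gp[("A", 1)][("B", 0)]["weight"] >= 0.0


# --- reweighting -----------------------------------------------------------


def test_reweight_clique_edges_unchanged():
    g = nx.complete_graph(5)
    nx.set_edge_attributes(g, 2.0, "weight")
    out = cq.reweight(g)
    for u, v in out.edges():
        assert out[u][v]["weight"] == pytest.approx(2.0)


def test_reweight_bridge_zeroed():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)], weight=1.0)
    g.add_edge(2, 3, weight=1.0)  # bridge between two triangles
    out = cq.reweight(g)
    assert out[2][3]["weight"] == pytest.approx(0.0)
    assert out[0][1]["weight"] == pytest.approx(1.0)


def test_reweight_pendant_edge_downweighted():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2)], weight=1.0)
    g.add_edge(2, 9, weight=1.0)  # pendant
    out = cq.reweight(g)
    assert out[2][9]["weight"] < out[0][1]["weight"]


def test_reweight_uses_premodification_adjacency():
    # simultaneous update: the pendant's zero weight must not influence the
    # triangle edges' factors within the same pass
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2)], weight=1.0)
    g.add_edge(0, 9, weight=5.0)
    out = cq.reweight(g)
    assert out[1][2]["weight"] == pytest.approx(1.0)


# --- edge filtering --------------------------------------------------------


def _weighted_graph(rng, n_edges=100, n_nodes=30):
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=7)
    for i, (u, v) in enumerate(sorted(g.edges())):
        g[u][v]["weight"] = float(rng.random())
    return g


def test_filter_keeps_at_least_alpha_percent(rng):
    g = _weighted_graph(rng)
    out = cq.filter_edges(g, alpha_pct=20, beta=0)
    assert out.number_of_edges() >= 20


def test_filter_restores_starved_vertex_edges(rng):
    # a vertex whose 4 edges all fall below the cut keeps all 4 (beta=10 > 4)
    g = nx.star_graph(4)
    for u, v in g.edges():
        g[u][v]["weight"] = 0.001
    big = nx.complete_graph(range(10, 20))
    for u, v in big.edges():
        big[u][v]["weight"] = 1.0
    merged = nx.compose(g, big)
    out = cq.filter_edges(merged, alpha_pct=20, beta=10)
    assert out.degree(0) == 4


def test_filter_high_degree_vertex_capped_at_beta(rng):
    # a hub with 30 weak edges, whose neighbors all have strong edges of
    # their own, is restored to exactly beta incident edges
    g = nx.star_graph(30)
    for i, (u, v) in enumerate(sorted(g.edges())):
        g[u][v]["weight"] = 0.001 + 1e-5 * i
    big = nx.complete_graph(range(1, 31))  # leaves strongly interconnected
    for u, v in big.edges():
        big[u][v]["weight"] = 1.0
    merged = nx.compose(g, big)
    out = cq.filter_edges(merged, alpha_pct=20, beta=10)
    assert out.degree(0) == 10


def test_filter_rejects_bad_alpha(rng):
    with pytest.raises(ValueError):
        cq.filter_edges(nx.Graph(), alpha_pct=150)


# --- greedy cliques --------------------------------------------------------


def _set_unit_weights(g):
    nx.set_edge_attributes(g, 1.0, "weight")
    return g


def test_single_k4_extracted_whole():
    g = _set_unit_weights(nx.complete_graph(4))
    out = cq.greedy_cliques(g)
    assert [sorted(c) for c in out] == [[0, 1, 2, 3]]


def test_two_disjoint_triangles():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (5, 6), (6, 7), (5, 7)])
    _set_unit_weights(g)
    out = cq.greedy_cliques(g)
    assert sorted(sorted(c) for c in out) == [[0, 1, 2], [5, 6, 7]]


def test_k4_sharing_vertex_with_k3():
    g = nx.complete_graph(4)
    g.add_edges_from([(3, 4), (4, 5), (3, 5)])
    _set_unit_weights(g)
    out = cq.greedy_cliques(g)
    assert sorted(out[0]) == [0, 1, 2, 3]
    assert sorted(out[1]) == [4, 5]  # K3 lost vertex 3; an edge remains


def test_max_cliques_limit():
    g = nx.Graph()
    for i in range(6):
        g.add_edge(10 * i, 10 * i + 1, weight=1.0)
    out = cq.greedy_cliques(g, max_cliques=3)
    assert len(out) == 3


def test_greedy_cliques_random_graphs_verified_against_oracle():
    # every output is a clique, vertex-disjoint, and maximal within the
    # residual graph at its extraction step (brute-force maximal-clique oracle)
    rng = np.random.default_rng(0)
    for trial in range(60):
        n = int(rng.integers(4, 13))
        p = float(rng.uniform(0.2, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges():
            g[u][v]["weight"] = float(rng.random())
        out = cq.greedy_cliques(g.copy())
        seen = set()
        residual = g.copy()
        for clique in out:
            cs = set(clique)
            assert not (cs & seen), "cliques must be vertex-disjoint"
            seen |= cs
            maximal = [set(c) for c in nx.find_cliques(residual)]
            assert cs in maximal, "clique must be maximal in its residual graph"
            residual.remove_nodes_from(cs)


# --- refinement ------------------------------------------------------------


def _fake_scan(pvalues):
    def fake(pwm, promoters, bg=None, combine="footprint", _dist=None):
        return pvalues[promoters.operon_id]
    return fake


def _toy_sets(ids):
    motif_sets = {}
    promoter_sets = {}
    rng = np.random.default_rng(5)
    for oid in ids:
        motif_sets[oid] = MotifSet(oid, [site_pwm(rng, 10)])
        motif_sets[oid].motifs[0].motif_id = f"{oid}|m0"
        promoter_sets[oid] = PromoterSet(
            operon_id=oid, records=[("t", "ACGT" * 30)], target_genome_id="t"
        )
    return motif_sets, promoter_sets


def test_refine_membership_rules_at_the_cut(monkeypatch):
    ids = ["a", "b", "c", "d"]
    motif_sets, promoter_sets = _toy_sets(ids)
    # a: member with exactly 0.05 (kept: removal needs p > 0.05)
    # b: member with 0.2 (removed); c: outsider 0.01 (added);
    # d: outsider exactly 0.05 (not added: addition needs p < 0.05)
    pvals = {"a": 0.05, "b": 0.2, "c": 0.01, "d": 0.05}
    monkeypatch.setattr(cq, "operon_scan_pvalue", _fake_scan(pvals))
    pred = cq.refine_clique([("a", 0), ("b", 0)], motif_sets, promoter_sets)
    assert pred.operons == {"a", "c"}
    assert pred.member_pvalues == {"a": 0.05, "c": 0.01}


def test_refine_empty_result_dropped(monkeypatch):
    ids = ["a", "b"]
    motif_sets, promoter_sets = _toy_sets(ids)
    monkeypatch.setattr(cq, "operon_scan_pvalue", _fake_scan({"a": 0.9, "b": 0.9}))
    assert cq.refine_clique([("a", 0)], motif_sets, promoter_sets) is None


def test_refine_representative_is_most_significant(monkeypatch):
    ids = ["a", "b"]
    motif_sets, promoter_sets = _toy_sets(ids)
    motif_sets["a"].motifs[0].discovery_pvalue = 0.04
    motif_sets["b"].motifs[0].discovery_pvalue = 0.01
    monkeypatch.setattr(cq, "operon_scan_pvalue", _fake_scan({"a": 0.01, "b": 0.01}))
    pred = cq.refine_clique([("a", 0), ("b", 0)], motif_sets, promoter_sets)
    assert pred.representative_motif.motif_id == "b|m0"


def test_refine_idempotent(monkeypatch):
    ids = ["a", "b", "c"]
    motif_sets, promoter_sets = _toy_sets(ids)
    pvals = {"a": 0.001, "b": 0.3, "c": 0.02}
    monkeypatch.setattr(cq, "operon_scan_pvalue", _fake_scan(pvals))
    first = cq.refine_clique([("a", 0), ("b", 0)], motif_sets, promoter_sets)
    again = cq.refine_clique(
        [("a", 0), ("b", 0)], motif_sets, promoter_sets
    )
    assert first.operons == again.operons == {"a", "c"}
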