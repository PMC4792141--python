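"""Regulon identification by clique finding on the motif-level graph G′.

Each operon vertex of the co-regulation graph G is blown up into one
vertex per motif occurring in any of its label sets; label pairs become
G′ edges weighted by the per-edge similarity z-score (clipped at 0). An
operon regulated by two different factors contributes two G′ vertices
that land in different neighborhoods, so the dense "meta-clusters" of G
decompose. Edge weights are then scaled by the Jaccard similarity of the
two endpoints' neighborhoods, the graph is thinned to the strongest
edges, vertex-disjoint cliques are extracted greedily, and each clique is
refined into a regulon by scanning its most significant motif against
every operon's promoter.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .coreg import CoRegGraph, MotifRef
from .model import MotifSet, PromoterSet, Pwm, RegulonPrediction
from .motifs import ScoreDistribution, background_frequencies, operon_scan_pvalue

logger = logging.getLogger(__name__)

_SD_EPS = 1e-9


def blowup(g: CoRegGraph, weight: str = "zscore") -> nx.Graph:
    """Build the motif-level graph G′ from the label sets of G.

    Vertices are (operon_id, motif_index) pairs occurring in at least one
    label set. With ``weight='zscore'`` (default) the edge (A_i, B_j)
    carries the pair's jackknife-standardized similarity clipped at 0
    (see :meth:`SimilarityMatrix.zscores`); ``weight='omega'`` uses the
    raw similarity instead.
    """
    gp = nx.Graph()
    for (a, b), edge in sorted(g.edges.items()):
        sim = edge.sim
        z = sim.zscores() if sim is not None and not sim.is_empty else None
        for i, j in sorted(edge.labels):
            if weight == "zscore":
                w = max(0.0, float(z[i, j])) if z is not None else 0.0
            elif weight == "omega":
                w = float(sim.omega[i, j]) if sim is not None else 0.0
            else:
                raise ValueError(f"unknown weight scheme {weight!r}")
            u: MotifRef = (a, i)
            v: MotifRef = (b, j)
            gp.add_edge(u, v, weight=w)
    return gp


def reweight(gp: nx.Graph) -> nx.Graph:
    """Scale every edge weight by the neighborhood Jaccard of its endpoints.

    For edge (u, v) the factor is |N(u)∩N(v)| / |N(u)∪N(v)| computed on
    the neighborhoods with the opposite endpoint removed (so an edge
    inside a clique keeps its weight) and on the pre-modification
    adjacency for all edges simultaneously. Returns a new graph.
    """
    out = nx.Graph()
    out.add_nodes_from(gp.nodes())
    neigh = {v: set(gp.neighbors(v)) for v in gp.nodes()}
    for u, v, data in gp.edges(data=True):
        nu = neigh[u] - {v}
        nv = neigh[v] - {u}
        union = nu | nv
        jac = len(nu & nv) / len(union) if union else 1.0
        out.add_edge(u, v, weight=data.get("weight", 0.0) * jac)
    return out


def filter_edges(gp: nx.Graph, alpha_pct: float = 20.0, beta: int = 10) -> nx.Graph:
    """Keep the globally strongest edges, then re-arm sparse vertices.

    The top ``alpha_pct`` percent of edges by weight survive (at least one
    when any edge exists); afterwards every vertex left with fewer than
    ``beta`` incident edges gets its ``beta`` strongest original edges
    restored (all of them if its degree is below ``beta``).
    """
    if not (0 < alpha_pct <= 100):
        raise ValueError("alpha_pct must lie in (0, 100]")
    edges = sorted(
        gp.edges(data=True),
        key=lambda e: (-e[2].get("weight", 0.0), min(e[0], e[1]), max(e[0], e[1])),
    )
    if not edges:
        return gp.copy()
    k = max(1, int(np.ceil(len(edges) * alpha_pct / 100.0)))
    kept = set()
    for u, v, _ in edges[:k]:
        kept.add(frozenset((u, v)))
    # restoration: vertices starved by the global cut get their best edges back
    incident: Dict[object, List[Tuple[object, object, float]]] = {v: [] for v in gp.nodes()}
    for u, v, data in edges:
        w = data.get("weight", 0.0)
        incident[u].append((u, v, w))
        incident[v].append((v, u, w))
    for vtx in sorted(gp.nodes()):
        surviving = sum(1 for (a, b, _) in incident[vtx] if frozenset((a, b)) in kept)
        if surviving < beta:
            ranked = sorted(
                incident[vtx], key=lambda e: (-e[2], min(e[0], e[1]), max(e[0], e[1]))
            )
            for a, b, _ in ranked[:beta]:
                kept.add(frozenset((a, b)))
    out = nx.Graph()
    out.add_nodes_from(gp.nodes())
    for pair in kept:
        u, v = tuple(pair)
        out.add_edge(u, v, weight=gp[u][v].get("weight", 0.0))
    return out


def _pick_edge(g: nx.Graph) -> Optional[Tuple[object, object]]:
    """Edge with the largest common neighborhood; ties broken by larger
    weight, then lexicographic endpoint ids."""
    best = None
    best_key = None
    for u, v, data in g.edges(data=True):
        a, b = (u, v) if u <= v else (v, u)
        common = len(set(g.neighbors(u)) & set(g.neighbors(v)))
        key = (-common, -data.get("weight", 0.0), a, b)
        if best_key is None or key < best_key:
            best_key = key
            best = (a, b)
    return best


def greedy_cliques(gp: nx.Graph, max_cliques: int = 300) -> List[List[object]]:
    """Extract up to ``max_cliques`` vertex-disjoint cliques.

    Repeatedly: take the edge with the largest common neighborhood, grow
    the clique inside the induced common-neighborhood subgraph until it is
    empty, then remove the clique's vertices. An edgeless but non-empty
    common neighborhood contributes its vertex with the largest summed
    weight to the clique (which then closes). Every output is a clique
    and maximal within the residual graph it was extracted from; all
    tie-breaks are deterministic.
    """
    g = gp.copy()
    cliques: List[List[object]] = []
    for _ in range(max_cliques):
        if g.number_of_edges() == 0:
            break
        edge = _pick_edge(g)
        if edge is None:
            break
        u, v = edge
        clique = [u, v]
        sub = g.subgraph(set(g.neighbors(u)) & set(g.neighbors(v))).copy()
        while True:
            if sub.number_of_edges() == 0:
                if sub.number_of_nodes() > 0:
                    # edgeless remainder: absorb the single best vertex
                    best = min(
                        sub.nodes(),
                        key=lambda x: (
                            -sum(g[x][c].get("weight", 0.0) for c in clique if g.has_edge(x, c)),
                            x,
                        ),
                    )
                    clique.append(best)
                break
            e2 = _pick_edge(sub)
            u2, v2 = e2
            clique.extend([u2, v2])
            sub = sub.subgraph(
                set(sub.neighbors(u2)) & set(sub.neighbors(v2))
            ).copy()
        cliques.append(sorted(clique))
        g.remove_nodes_from(clique)
    return cliques


def refine_clique(
    clique: Sequence[MotifRef],
    motif_sets: Dict[str, MotifSet],
    promoter_sets: Dict[str, PromoterSet],
    rank: int = 0,
    p_cut: float = 0.05,
    combine: str = "footprint",
) -> Optional[RegulonPrediction]:
    """Turn a motif-level clique into a regulon prediction.

    The representative motif m_c is the clique motif with the smallest
    discovery p-value. Membership is decided in a single pass over every
    operon in the universe with the same scan values: members of the seed
    clique stay unless their scan p-value exceeds ``p_cut`` (strictly);
    non-members join when theirs is strictly below ``p_cut``. Returns
    None (and logs) when the refined regulon is empty.
    """
    if not clique:
        raise ValueError("cannot refine an empty clique")
    pwms = [motif_sets[oid].motifs[idx] for oid, idx in clique]
    # smallest discovery p-value wins, ties broken by motif id
    m_c = min(pwms, key=lambda p: (p.discovery_pvalue, p.motif_id))
    seed_operons = {oid for oid, _ in clique}
    # one score distribution per (motif, background); background pooled over
    # all target promoters so every operon is scanned on the same scale
    all_seqs = [
        ps.target_promoter()
        for ps in promoter_sets.values()
        if ps.target_promoter() is not None
    ]
    bg = (
        background_frequencies([s for s in all_seqs if s])
        if all_seqs
        else np.full(4, 0.25)
    )
    dist = ScoreDistribution(m_c, bg)
    members: Set[str] = set()
    pvalues: Dict[str, float] = {}
    for oid in sorted(promoter_sets):
        p = operon_scan_pvalue(
            m_c, promoter_sets[oid], bg=bg, combine=combine, _dist=dist
        )
        pvalues[oid] = p
        if oid in seed_operons:
            if not (p > p_cut):
                members.add(oid)
        else:
            if p < p_cut:
                members.add(oid)
    if not members:
        logger.info("clique %d refined to an empty regulon; dropped", rank)
        return None
    return RegulonPrediction(
        rank=rank,
        operons=members,
        representative_motif=m_c,
        member_pvalues={o: pvalues[o] for o in sorted(members)},
        seed_clique=[tuple(x) for x in clique],
    )


def predict_regulons(
    g: CoRegGraph,
    motif_sets: Dict[str, MotifSet],
    promoter_sets: Dict[str, PromoterSet],
    alpha_pct: float = 20.0,
    beta: int = 10,
    max_cliques: int = 300,
    p_cut: float = 0.05,
    blowup_weight: str = "zscore",
    combine: str = "footprint",
) -> Tuple[List[RegulonPrediction], List[List[MotifRef]]]:
    """Full clustering stage: G → G′ → reweight → filter → cliques → refine.

    Returns (refined predictions ranked by clique extraction order, the
    primary seed cliques themselves). Cliques whose refinement empties are
    dropped from the predictions but kept in the primary list.
    """
    gp = blowup(g, weight=blowup_weight)
    logger.info("G' has %d vertices, %d edges", gp.number_of_nodes(), gp.number_of_edges())
    gp = reweight(gp)
    gp = filter_edges(gp, alpha_pct=alpha_pct, beta=beta)
    logger.info("filtered G' has %d edges", gp.number_of_edges())
    cliques = greedy_cliques(gp, max_cliques=max_cliques)
    logger.info("extracted %d cliques", len(cliques))
    predictions = []
    for rank, clique in enumerate(cliques):
        pred = refine_clique(
            clique, motif_sets, promoter_sets, rank=rank, p_cut=p_cut, combine=combine
        )
        if pred is not None:
            predictions.append(pred)
    return predictions, cliques
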