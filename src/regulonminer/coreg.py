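"""Co-regulation score (CRS) and the operon co-regulation graph G.

CRS standardizes the best motif-pair similarity between two operons
against the bulk of their pairwise similarities:

    CRS(A, B) = (ω_max − ω̄) / σ      if ω_max > ω_threshold and σ > 0
    CRS(A, B) = 0                     otherwise

with ω̄ and σ the mean and population standard deviation of the s·t
motif-pair similarities excluding the maximum itself (jackknifed, so the
shared-motif signal does not inflate its own null — see
:meth:`SimilarityMatrix.null_stats`). The label set L of an edge records which motif
index pairs carry the signal: initially every argmax pair, then expanded
with any pair whose z-score exceeds ``z_threshold`` provided at least one
of its motifs is *effective* (already appears in some label set of G),
iterated to a fixpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import MotifSet
from .similarity import SimilarityMatrix, similarity_matrix

_SD_EPS = 1e-9

MotifRef = Tuple[str, int]  # (operon_id, motif index)


@dataclass
class CoRegEdge:
    """An operon pair with its CRS and label set of motif-index pairs.

    Labels are 0-based (i, j) indices into the two operons' motif lists,
    stored with ``operons`` in the order given at construction.
    """

    operons: Tuple[str, str]
    crs: float
    labels: Set[Tuple[int, int]] = field(default_factory=set)
    omega_max: float = 0.0
    sim: Optional[SimilarityMatrix] = None

    def transposed(self) -> "CoRegEdge":
        return CoRegEdge(
            operons=(self.operons[1], self.operons[0]),
            crs=self.crs,
            labels={(j, i) for i, j in self.labels},
            omega_max=self.omega_max,
            sim=self.sim,
        )


def crs(sim: SimilarityMatrix, omega_threshold: float = 0.5) -> CoRegEdge:
    """Score one operon pair from its ω matrix.

    CRS is 0 when the matrix is empty, when ω_max fails the threshold,
    when σ is degenerate, or when there are fewer than three entries (too
    few similarities to estimate a null for the maximum). Otherwise the
    label set holds every argmax index pair.
    """
    pair = (sim.operon_a, sim.operon_b)
    if sim.is_empty:
        return CoRegEdge(operons=pair, crs=0.0, sim=sim)
    omega = sim.omega
    omega_max = float(omega.max())
    mu, sd = sim.null_stats()
    if omega_max <= omega_threshold or sd <= _SD_EPS or omega.size < 3:
        return CoRegEdge(operons=pair, crs=0.0, omega_max=omega_max, sim=sim)
    score = (omega_max - mu) / sd
    labels = {
        (int(i), int(j)) for i, j in zip(*np.nonzero(omega == omega_max))
    }
    return CoRegEdge(operons=pair, crs=score, labels=labels, omega_max=omega_max, sim=sim)


@dataclass
class CoRegGraph:
    """Sparse representation of the complete co-regulation graph: only
    edges with CRS > 0 are stored (an absent edge has weight 0)."""

    operon_ids: List[str]
    edges: Dict[Tuple[str, str], CoRegEdge] = field(default_factory=dict)

    def effective_motifs(self) -> Set[MotifRef]:
        """Motifs appearing in at least one label set."""
        out: Set[MotifRef] = set()
        for (a, b), edge in self.edges.items():
            for i, j in edge.labels:
                out.add((a, i))
                out.add((b, j))
        return out

    def edge(self, a: str, b: str) -> Optional[CoRegEdge]:
        if (a, b) in self.edges:
            return self.edges[(a, b)]
        if (b, a) in self.edges:
            return self.edges[(b, a)].transposed()
        return None


def build_graph(
    motif_sets: Dict[str, MotifSet],
    omega_threshold: float = 0.5,
    min_overlap: int = 6,
) -> CoRegGraph:
    """Compute CRS for every operon pair and keep the positive edges.

    ``motif_sets`` maps every operon of the universe to its (possibly
    empty) motif set; operons with empty sets contribute no edges.
    """
    ids = sorted(motif_sets)
    g = CoRegGraph(operon_ids=ids)
    nonempty = [o for o in ids if motif_sets[o]]
    for a, b in combinations(nonempty, 2):
        sim = similarity_matrix(motif_sets[a], motif_sets[b], min_overlap=min_overlap)
        edge = crs(sim, omega_threshold=omega_threshold)
        if edge.crs > 0:
            g.edges[(a, b)] = edge
    return g


def expand_labels(g: CoRegGraph, z_threshold: float = 2.0) -> CoRegGraph:
    """Grow label sets with secondary significant motif pairs.

    A pair (i, j) on edge (A, B) is added when its per-edge z-score
    (ω_ij − ω̄)/σ exceeds ``z_threshold`` AND at least one of the two
    motifs is effective. Newly added labels can make more motifs
    effective, so the rule is iterated to a fixpoint (labels are only ever
    added, and each edge has at most s·t of them, so this terminates).
    Mutates and returns ``g``.
    """
    # precompute candidate pairs passing the z criterion per edge
    candidates: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for key, edge in g.edges.items():
        sim = edge.sim
        if sim is None or sim.is_empty:
            continue
        z = sim.zscores()
        pairs = [
            (int(i), int(j))
            for i, j in zip(*np.nonzero(z > z_threshold))
            if (int(i), int(j)) not in edge.labels
        ]
        if pairs:
            candidates[key] = pairs
    effective = g.effective_motifs()
    changed = True
    while changed:
        changed = False
        for (a, b), pairs in candidates.items():
            edge = g.edges[(a, b)]
            remaining = []
            for i, j in pairs:
                if (a, i) in effective or (b, j) in effective:
                    edge.labels.add((i, j))
                    effective.add((a, i))
                    effective.add((b, j))
                    changed = True
                else:
                    remaining.append((i, j))
            candidates[(a, b)] = remaining
    return g
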