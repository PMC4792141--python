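"""Benchmark statistics for regulon predictions.

EASE is the jackknifed hypergeometric tail used to match a predicted
operon cluster P against a documented regulon R inside the operon
universe M: the observed overlap k is penalized by one before the tail is
summed, so single-operon overlaps are never significant. The regulon
coverage score measures how much of a known regulon the union of the
top-n predictions recovers. nCC = CC/ED compares a vertex set's
clustering coefficient with its edge density (in an Erdős–Rényi graph the
two coincide in expectation, so ratios above 1 mark cluster-able sets).
Efficiency curves count truly co-regulated pairs among the top-n pairs of
a score ranking. PCS is the first-order partial correlation of two
phyletic profiles given a conditioning profile (by default the mean
profile), the co-evolution score CRS is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
from scipy import stats

from .model import PhyleticProfile, RegulonBenchmark


# ---------------------------------------------------------------------------
# EASE (modified Fisher exact test)


def ease_score(p_size: int, r_size: int, overlap: int, universe_size: int) -> float:
    """EASE score for a predicted cluster of size ``p_size`` overlapping a
    known regulon of size ``r_size`` in ``overlap`` operons, within a
    universe of ``universe_size`` operons.

    EASE = Σ_{i=max(k−1,1)}^{min(|P|,|R|)} C(|R|,i) C(|M|−|R|,|P|−i) / C(|M|,|P|),
    the hypergeometric tail with the observed overlap k discounted by one;
    k <= 1 (or an empty P or R) scores 1. Exact integer arithmetic.
    """
    M, R, P, k = universe_size, r_size, p_size, overlap
    if P <= 0 or R <= 0 or k <= 1:
        return 1.0
    if not (R <= M and P <= M and k <= min(P, R)):
        raise ValueError("inconsistent set sizes for EASE")
    m = min(P, R)
    num = 0
    for i in range(max(k - 1, 1), m + 1):
        if P - i > M - R:
            continue
        num += comb(R, i) * comb(M - R, P - i)
    return min(1.0, num / comb(M, P))


def best_ease(
    predicted: Set[str], benchmark: RegulonBenchmark, universe_size: int
) -> Tuple[Optional[str], float]:
    """Smallest EASE over all documented regulons, with the matching TF
    (lexicographically first on ties); (None, 1.0) when nothing overlaps."""
    best_tf, best_p = None, 1.0
    for tf in sorted(benchmark.regulons):
        members = benchmark.regulons[tf]
        e = ease_score(
            len(predicted), len(members), len(predicted & members), universe_size
        )
        if e < best_p:
            best_tf, best_p = tf, e
    return best_tf, best_p


# ---------------------------------------------------------------------------
# Regulon coverage


def regulon_coverage(regulon: Set[str], clusters: Sequence[Set[str]]) -> float:
    """Fraction of the known regulon covered by the union of the given
    (top-n) predicted clusters."""
    if not regulon:
        return 0.0
    union: Set[str] = set()
    for c in clusters:
        union |= c
    return len(regulon & union) / len(regulon)


# ---------------------------------------------------------------------------
# Clustering coefficient / edge density / nCC


def clustering_coefficient(h: nx.Graph) -> float:
    """Global (transitivity) clustering coefficient: 3·#triangles over the
    number of connected triplets; 0 when there are no connected triplets."""
    return float(nx.transitivity(h))


def edge_density(h: nx.Graph) -> float:
    n = h.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * h.number_of_edges() / (n * (n - 1))


def ncc(h: nx.Graph) -> float:
    """Normalized clustering coefficient CC/ED (0 when either part is
    degenerate)."""
    ed = edge_density(h)
    if ed <= 0:
        return 0.0
    return clustering_coefficient(h) / ed


# ---------------------------------------------------------------------------
# Efficiency curves


def efficiency_curve(
    scored_pairs: Iterable[Tuple[Tuple[str, str], float]],
    known_pairs: Set[frozenset],
    n_grid: Sequence[int],
) -> List[Tuple[int, int]]:
    """Count truly co-regulated pairs among the top-n pairs of a ranking.

    ``scored_pairs`` yields ((a, b), score); ``known_pairs`` holds
    frozensets of operon pairs co-occurring in at least one documented
    regulon. Ties are broken deterministically by operon ids. Grid points
    beyond the number of pairs saturate at the final count.
    """
    ranked = sorted(
        scored_pairs, key=lambda t: (-t[1], tuple(sorted(t[0])))
    )
    flags = [frozenset(pair) in known_pairs for pair, _ in ranked]
    cum = np.concatenate([[0], np.cumsum(flags)])
    out = []
    for n in n_grid:
        out.append((int(n), int(cum[min(max(n, 0), len(flags))])))
    return out


def true_pair_set(benchmark: RegulonBenchmark) -> Set[frozenset]:
    """All unordered operon pairs sharing at least one documented regulon."""
    pairs: Set[frozenset] = set()
    for members in benchmark.regulons.values():
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1:]:
                pairs.add(frozenset((a, b)))
    return pairs


# ---------------------------------------------------------------------------
# Phylogenetic profile comparison score (PCS)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx < 1e-12 or sy < 1e-12:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def pcs(
    a: PhyleticProfile,
    b: PhyleticProfile,
    condition_set: Sequence[PhyleticProfile] = (),
) -> float:
    """Partial correlation of two 0/1 phyletic profiles.

    The correlation between the profiles is partialed on the mean profile
    of ``condition_set`` (first-order partial correlation), removing the
    shared trend that makes unrelated widespread operons look co-evolved.
    Degenerate (constant) profiles give 0; an empty condition set gives
    the plain Pearson correlation.
    """
    x = a.vector.astype(float)
    y = b.vector.astype(float)
    r_xy = _pearson(x, y)
    if not condition_set:
        return r_xy
    z = np.mean([p.vector.astype(float) for p in condition_set], axis=0)
    r_xz = _pearson(x, z)
    r_yz = _pearson(y, z)
    denom = (1 - r_xz ** 2) * (1 - r_yz ** 2)
    if denom <= 1e-12:
        return 0.0
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


# ---------------------------------------------------------------------------
# Rank-sum comparison


def wilcoxon_compare(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for x stochastically greater
    than y (exact enumeration for small samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if min(len(x), len(y)) < 3 else "auto"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


# ---------------------------------------------------------------------------
# Report container


@dataclass
class EvalReport:
    """Evaluation of a prediction list against a benchmark."""

    best_ease_per_prediction: List[Tuple[int, Optional[str], float]] = field(
        default_factory=list
    )
    coverage_grid: List[int] = field(default_factory=list)
    coverage_per_regulon: Dict[str, List[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "best_ease_per_prediction": [
                {"rank": r, "tf": tf, "ease": e}
                for r, tf, e in self.best_ease_per_prediction
            ],
            "coverage_grid": list(self.coverage_grid),
            "coverage_per_regulon": {
                tf: list(v) for tf, v in self.coverage_per_regulon.items()
            },
        }


def evaluate_predictions(
    clusters: Sequence[Set[str]],
    benchmark: RegulonBenchmark,
    universe_size: int,
    coverage_grid: Optional[Sequence[int]] = None,
) -> EvalReport:
    """Best-EASE per predicted cluster and coverage per known regulon on a
    top-n grid (defaults to 10, 20, ... up to the number of clusters)."""
    if coverage_grid is None:
        top = max(10, len(clusters))
        coverage_grid = list(range(10, top + 1, 10))
    report = EvalReport(coverage_grid=list(coverage_grid))
    for rank, cluster in enumerate(clusters):
        tf, e = best_ease(set(cluster), benchmark, universe_size)
        report.best_ease_per_prediction.append((rank, tf, e))
    for tf in sorted(benchmark.regulons):
        regulon = benchmark.regulons[tf]
        report.coverage_per_regulon[tf] = [
            regulon_coverage(regulon, [set(c) for c in clusters[:n]])
            for n in coverage_grid
        ]
    return report
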