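"""Phylogenetic-footprinting support: orthologous operon groups and promoters.

For a target operon A, reference operons containing orthologs of A's genes
are collected into an orthologous graph G_A (edges between operons that
share an orthologous gene, where "share" between two reference operons
means they contain orthologs of a common target gene). Markov clustering of
G_A yields the orthologous operon group O_A, whose upstream regions form the
promoter set used for motif discovery. Promoters are the 300 bp (or the
whole intergenic region, if shorter) immediately upstream of the operon's
translation start, strand-aware.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from .model import (
    Genome,
    Operon,
    OrthologyMap,
    PhyleticProfile,
    PromoterSet,
    ValidationError,
    reverse_complement,
)

# ---------------------------------------------------------------------------
# Orthologous graph G_A


def build_ortho_graph(
    A: Operon, ref_operons: Sequence[Operon], orth: OrthologyMap
) -> nx.Graph:
    """Build the orthologous graph G_A for target operon ``A``.

    Vertices: A plus every reference operon containing an ortholog of at
    least one of A's genes. Edges join operons sharing an orthologous gene;
    for two reference operons the shared gene is anchored through a common
    target gene (only target<->reference orthology is available).

    Vertex attribute ``anchors`` records which of A's genes connect each
    member (provenance of the orthology relation).
    """
    ref_to_targets = orth.targets_of()
    a_genes = set(A.gene_ids)

    g = nx.Graph()
    g.add_node(A.operon_id, anchors=frozenset(A.gene_ids), genome=A.genome_id)

    anchors: Dict[str, Set[str]] = {}  # ref operon id -> anchoring target genes of A
    members: List[Operon] = []
    for op in ref_operons:
        hit = set()
        for gene in op.gene_ids:
            hit |= ref_to_targets.get(gene, set()) & a_genes
        if hit:
            anchors[op.operon_id] = hit
            members.append(op)
            g.add_node(op.operon_id, anchors=frozenset(hit), genome=op.genome_id)

    ids = [op.operon_id for op in members]
    for oid in ids:
        g.add_edge(A.operon_id, oid)
    for i, u in enumerate(ids):
        for v in ids[i + 1:]:
            if anchors[u] & anchors[v]:
                g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# Minimal Markov clustering (MCL)


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> List[Set[str]]:
    """Markov clustering of an undirected graph.

    Dense re-implementation of the classic flow algorithm: add unit
    self-loops, column-normalize, then alternate expansion (matrix power)
    and inflation (entrywise power + renormalization) until the matrix
    change drops below ``tol``. Clusters are read off as connected
    components of the limit matrix's support. Deterministic: vertices are
    processed in sorted order.
    """
    nodes = sorted(g.nodes())
    if not nodes:
        raise ValidationError("cannot cluster an empty graph")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.eye(n)
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded ** inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        inflated[inflated < 1e-12] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-9)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [set(nodes[i] for i in c) for c in nx.connected_components(support)]
    return sorted(comps, key=lambda c: sorted(c)[0])


def orthologous_operon_group(A: Operon, g: nx.Graph, **mcl_kwargs) -> Set[str]:
    """The MCL cluster of G_A containing A (the orthologous operon group O_A)."""
    if A.operon_id not in g:
        raise ValidationError(f"operon {A.operon_id} is not a vertex of its graph")
    for cluster in mcl_cluster(g, **mcl_kwargs):
        if A.operon_id in cluster:
            return cluster
    raise AssertionError("MCL clusters must partition the vertex set")


# ---------------------------------------------------------------------------
# Promoter extraction


def extract_promoter(op: Operon, genome: Genome, max_len: int = 300) -> str:
    """Up to ``max_len`` bp immediately upstream of the operon's translation
    start, truncated at the nearest annotated upstream operon (intergenic
    rule) and reverse-complemented for minus-strand operons.

    Returns "" for operons with a zero-length intergenic region
    (promoterless).
    """
    n = len(genome.sequence)
    if op.strand == "+":
        # nearest upstream feature end (1-based); 0 if none
        limit = 0
        for other in genome.operons:
            if other.operon_id != op.operon_id and other.end < op.start:
                limit = max(limit, other.end)
        lo = max(op.start - max_len, limit + 1, 1)
        hi = op.start - 1
        if hi < lo:
            return ""
        return genome.sequence[lo - 1: hi]
    else:
        limit = n + 1
        for other in genome.operons:
            if other.operon_id != op.operon_id and other.start > op.end:
                limit = min(limit, other.start)
        lo = op.end + 1
        hi = min(op.end + max_len, limit - 1, n)
        if hi < lo:
            return ""
        return reverse_complement(genome.sequence[lo - 1: hi])


# ---------------------------------------------------------------------------
# Promoter redundancy removal (greedy identity clustering)


def _ungapped_identity(a: str, b: str) -> float:
    """Best ungapped sliding-offset identity, relative to the shorter
    sequence. O(len(a)*len(b)); promoters are <= 300 bp."""
    if len(a) < len(b):
        a, b = b, a
    la, lb = len(a), len(b)
    best = 0
    for off in range(-(lb - 1), la):
        s = max(0, off)
        e = min(la, off + lb)
        if e - s <= best:  # cannot beat current best matches
            continue
        matches = sum(1 for i in range(s, e) if a[i] == b[i - off])
        if matches > best:
            best = matches
    return best / lb


def dedup_promoters(seqs: Sequence[str], identity: float = 0.9) -> List[str]:
    """Greedy redundancy removal: sequences are visited by descending length
    (stable), each joining the first representative with ungapped identity
    >= ``identity``; representatives are returned in first-seen order."""
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: List[str] = []
    for i in order:
        s = seqs[i]
        if not any(_ungapped_identity(r, s) >= identity for r in reps):
            reps.append(s)
    return reps


# ---------------------------------------------------------------------------
# Phyletic profiles


def phyletic_profiles(
    operon_ids: Sequence[str],
    groups: Dict[str, Set[str]],
    ref_genomes: Sequence[str],
    ref_operon_genomes: Dict[str, str],
) -> List[PhyleticProfile]:
    """Presence/absence of orthologous operons across reference genomes.

    ``groups`` maps each target operon to its orthologous operon group O_A;
    ``ref_operon_genomes`` maps reference operon ids to their genome.
    """
    genome_ids = tuple(ref_genomes)
    gidx = {gid: i for i, gid in enumerate(genome_ids)}
    out = []
    for oid in operon_ids:
        v = np.zeros(len(genome_ids), dtype=int)
        for member in groups.get(oid, set()):
            gid = ref_operon_genomes.get(member)
            if gid in gidx:
                v[gidx[gid]] = 1
        out.append(PhyleticProfile(operon_id=oid, genome_ids=genome_ids, vector=v))
    return out


# ---------------------------------------------------------------------------
# End-to-end promoter collection


def collect_promoter_sets(
    target_genome: Genome,
    ref_operons: Sequence[Operon],
    orth: OrthologyMap,
    ref_promoters: Dict[str, str],
    max_len: int = 300,
    identity: float = 0.9,
) -> Tuple[Dict[str, PromoterSet], Dict[str, Set[str]]]:
    """Build the orthologous promoter set P_A for every target operon.

    ``ref_promoters`` maps reference operon ids to pre-extracted promoter
    sequences (reference genome sequences themselves are not required).
    Returns (promoter sets by operon id, orthologous groups O_A by operon id).
    Promoterless target operons stay in the universe with the reference
    promoters only; redundant promoters are removed at ``identity``.
    """
    ref_by_id = {op.operon_id: op for op in ref_operons}
    sets: Dict[str, PromoterSet] = {}
    groups: Dict[str, Set[str]] = {}
    for A in target_genome.operons:
        g = build_ortho_graph(A, ref_operons, orth)
        group = orthologous_operon_group(A, g)
        groups[A.operon_id] = group
        records: List[Tuple[str, str]] = []
        target_seq = extract_promoter(A, target_genome, max_len=max_len)
        if target_seq:
            records.append((target_genome.genome_id, target_seq))
        ref_records = []
        for member in sorted(group):
            if member == A.operon_id:
                continue
            seq = ref_promoters.get(member, "")
            if seq:
                gid = ref_by_id[member].genome_id if member in ref_by_id else "?"
                ref_records.append((gid, seq[:max_len]))
        kept = dedup_promoters([s for _, s in ref_records], identity=identity)
        kept_set = set(kept)
        seen: Set[str] = set()
        for gid, seq in ref_records:
            if seq in kept_set and seq not in seen:
                records.append((gid, seq))
                seen.add(seq)
        sets[A.operon_id] = PromoterSet(
            operon_id=A.operon_id,
            records=records,
            target_genome_id=target_genome.genome_id,
        )
    return sets, groups
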