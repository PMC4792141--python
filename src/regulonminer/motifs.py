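"""Motif discovery and PWM scanning for orthologous promoter sets.

Discovery is a deterministic seed-and-refine search: overrepresented
k-mer cores seed a position weight matrix which is refined by hard
(Viterbi) EM at each candidate width; candidates are ranked by mean
per-column relative entropy against the promoter set's 0-order background
and the top non-overlapping ones are kept. Discovery significance is a
permutation p-value: the fraction of per-sequence shuffled promoter sets
whose best rediscovered motif is at least as informative, with add-one
smoothing.

Scanning computes the best log-odds hit of a PWM in a promoter over both
strands, with a site p-value from the exact PWM score distribution
(dynamic programming over score-rounded columns) and a sequence-level
p-value via the independence approximation 1-(1-p_site)^(2(L-w+1)).
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .model import MotifSet, PromoterSet, Pwm, ScanHit, ValidationError

SCORE_GRANULARITY = 1e-3  # bits; integer grid for the exact score distribution
_PSEUDOCOUNT = 0.5  # per PWM cell when estimating from sites
_SEED_K = 8  # k-mer core length for seeding
_N_SEEDS = 5
_MAX_EM_ITER = 30

_ENC = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
    _ENC[_b + 32] = _i


def encode(seq: str) -> np.ndarray:
    """DNA string -> int64 array with A,C,G,T = 0..3 and anything else = 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def background_frequencies(seqs: Iterable[str], pseudocount: float = 1.0) -> np.ndarray:
    """0-order background over A,C,G,T with a pseudocount per base."""
    counts = np.full(4, pseudocount, dtype=float)
    for s in seqs:
        e = encode(s)
        counts += np.bincount(e[e < 4], minlength=4)
    return counts / counts.sum()


def relative_entropy(pwm: Pwm, bg: np.ndarray) -> float:
    """Mean per-column relative entropy (bits/column) of a PWM vs background."""
    m = np.clip(pwm.matrix, 1e-12, None)
    return float((m * np.log2(m / bg)).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Hard-EM refinement


def _windows(enc_seqs: List[np.ndarray], w: int) -> List[np.ndarray]:
    """Sliding windows of width w per sequence (may be empty arrays)."""
    out = []
    for e in enc_seqs:
        if len(e) >= w:
            out.append(np.lib.stride_tricks.sliding_window_view(e, w))
        else:
            out.append(np.empty((0, w), dtype=e.dtype))
    return out


def _pwm_from_positions(
    enc_seqs: List[np.ndarray], positions: List[int], w: int
) -> np.ndarray:
    counts = np.full((w, 4), _PSEUDOCOUNT)
    for e, p in zip(enc_seqs, positions):
        if p < 0:
            continue
        win = e[p: p + w]
        for j in range(w):
            if win[j] < 4:
                counts[j, win[j]] += 1.0
    return counts / counts.sum(axis=1, keepdims=True)


def _hard_em(
    enc_seqs: List[np.ndarray],
    win_list: List[np.ndarray],
    init_matrix: np.ndarray,
    bg: np.ndarray,
    max_iter: int = _MAX_EM_ITER,
) -> Tuple[np.ndarray, List[int]]:
    """One-occurrence-per-sequence hard EM: alternate best-window assignment
    and PWM re-estimation until site positions stabilize."""
    w = init_matrix.shape[0]
    matrix = init_matrix
    positions = [-2] * len(enc_seqs)
    cols = np.arange(w)
    for _ in range(max_iter):
        lut = np.zeros((w, 5))
        lut[:, :4] = np.log2(np.clip(matrix, 1e-12, None) / bg)
        new_positions = []
        for wins in win_list:
            if wins.shape[0] == 0:
                new_positions.append(-1)
                continue
            scores = lut[cols, wins].sum(axis=1)
            new_positions.append(int(scores.argmax()))
        if new_positions == positions:
            break
        positions = new_positions
        matrix = _pwm_from_positions(enc_seqs, positions, w)
    return matrix, positions


def _top_seed_kmers(
    enc_seqs: List[np.ndarray], bg: np.ndarray, k: int = _SEED_K, n: int = _N_SEEDS
) -> List[np.ndarray]:
    """Most overrepresented exact k-mers (count over 0-order expectation)."""
    packed = []
    for e in enc_seqs:
        if len(e) < k:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(e, k)
        ok = (wins < 4).all(axis=1)
        wins = wins[ok]
        if wins.shape[0]:
            packed.append((wins * (4 ** np.arange(k - 1, -1, -1))).sum(axis=1))
    if not packed:
        return []
    allp = np.concatenate(packed)
    vals, counts = np.unique(allp, return_counts=True)
    logbg = np.log(bg)
    digits = (vals[:, None] // (4 ** np.arange(k - 1, -1, -1))) % 4
    expect = np.exp(logbg[digits].sum(axis=1)) * len(allp)
    enrich = counts / expect
    # rank by enrichment, then count, then lexicographic (ascending packed value)
    order = np.lexsort((vals, -counts, -enrich))
    # diverse seeds: a near-duplicate (or shifted copy) of an already-chosen
    # core would converge to the same alignment and waste a motif slot
    chosen: List[np.ndarray] = []
    for i in order:
        cand = digits[i]
        if all(_kmer_identity(cand, c) < 0.75 for c in chosen):
            chosen.append(cand)
        if len(chosen) == n:
            break
    return chosen


def _kmer_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Best ungapped-offset identity between two equal-length k-mers,
    relative to k."""
    k = len(a)
    best = 0
    for off in range(-(k - 1), k):
        s, e = max(0, off), min(k, k + off)
        if e - s <= best:
            continue
        m = int((a[s:e] == b[s - off: e - off]).sum())
        if m > best:
            best = m
    return best / k


def _seed_matrix(seed: np.ndarray, w: int, bg: np.ndarray) -> np.ndarray:
    """Extend a k-mer core to width w: strong consensus probabilities in the
    core, background elsewhere (centered extension)."""
    k = len(seed)
    m = np.tile(bg, (w, 1)).astype(float)
    left = (w - k) // 2 if w >= k else 0
    for j in range(min(k, w)):
        col = np.full(4, 0.1 / 3)
        col[seed[j]] = 0.9
        m[left + j] = col
    return m / m.sum(axis=1, keepdims=True)


def _site_interval_overlap(p1: int, w1: int, p2: int, w2: int) -> int:
    return max(0, min(p1 + w1, p2 + w2) - max(p1, p2))


def _best_null_statistic(
    enc_seqs: List[np.ndarray], bg: np.ndarray, width: int
) -> float:
    """Best rediscovered-motif information content in one (shuffled) set:
    top enriched core seed, hard EM at the given width."""
    seeds = _top_seed_kmers(enc_seqs, bg, n=1)
    win_list = _windows(enc_seqs, width)
    if not seeds or all(w.shape[0] == 0 for w in win_list):
        return 0.0
    init = _seed_matrix(seeds[0], width, bg)
    matrix, _ = _hard_em(enc_seqs, win_list, init, bg, max_iter=10)
    m = np.clip(matrix, 1e-12, None)
    return float((m * np.log2(m / bg)).sum(axis=1).mean())


def discovery_pvalue(
    pwm: Pwm,
    promoters: PromoterSet,
    n_shuffles: int = 200,
    seed: int = 0,
    _null_cache: Optional[Dict[int, np.ndarray]] = None,
) -> float:
    """Permutation discovery p-value with add-one smoothing: (k+1)/(n+1)
    where k counts shuffled promoter sets whose best rediscovered motif is
    at least as informative as ``pwm``.

    Shuffling permutes the bases independently within each promoter,
    preserving per-sequence composition. ``_null_cache`` (keyed by width)
    lets callers reuse the null distribution across same-width motifs of
    one promoter set.
    """
    if n_shuffles <= 0:
        raise ValidationError("n_shuffles must be positive")
    seqs = promoters.sequences
    if len(seqs) < 2:
        return 1.0
    enc_seqs = [encode(s) for s in seqs]
    bg = background_frequencies(seqs)
    observed = relative_entropy(pwm, bg)
    w = pwm.width
    null = None if _null_cache is None else _null_cache.get(w)
    if null is None or len(null) != n_shuffles:
        rng = np.random.default_rng(seed)
        null = np.empty(n_shuffles)
        for t in range(n_shuffles):
            shuffled = [rng.permutation(e) for e in enc_seqs]
            null[t] = _best_null_statistic(shuffled, bg, w)
        if _null_cache is not None:
            _null_cache[w] = null
    k = int((null >= observed).sum())
    return (k + 1) / (n_shuffles + 1)


_N_CALIB_SHUFFLES = 20


def discover_motifs(
    promoters: PromoterSet,
    widths: Sequence[int] = tuple(range(8, 21)),
    s: int = 5,
    seed: int = 0,
    n_shuffles: int = 200,
) -> MotifSet:
    """De novo motif discovery in one orthologous promoter set.

    Candidates from every width compete on a null-calibrated scale: each
    width's hard-EM alignments of shuffled promoters define the expected
    informativeness of a spurious motif at that width (short alignments
    overfit more), and candidates are ranked by their z-score against that
    null. Returns up to ``s`` non-overlapping PWMs ordered by ascending
    permutation discovery p-value. Deterministic given ``seed`` (which
    drives only the permutation nulls). Fewer than two promoters yield an
    empty set.
    """
    seqs = promoters.sequences
    if len(seqs) < 2:
        return MotifSet(operon_id=promoters.operon_id, motifs=[])
    enc_seqs = [encode(x) for x in seqs]
    bg = background_frequencies(seqs)
    seeds = _top_seed_kmers(enc_seqs, bg)
    # per-width null calibration: what does a spurious alignment score?
    rng = np.random.default_rng(seed)
    shuffled_sets = [
        [rng.permutation(e) for e in enc_seqs] for _ in range(_N_CALIB_SHUFFLES)
    ]
    candidates = []  # (zscore, matrix, positions, width)
    for w in widths:
        win_list = _windows(enc_seqs, w)
        if sum(x.shape[0] > 0 for x in win_list) < 2:
            continue
        null = np.array(
            [_best_null_statistic(sh, bg, w) for sh in shuffled_sets]
        )
        null_mean = float(null.mean())
        null_sd = max(float(null.std()), 1e-6)
        for sd in seeds:
            init = _seed_matrix(sd, w, bg)
            matrix, positions = _hard_em(enc_seqs, win_list, init, bg)
            m = np.clip(matrix, 1e-12, None)
            score = float((m * np.log2(m / bg)).sum(axis=1).mean())
            z = (score - null_mean) / null_sd
            candidates.append((z, matrix, positions, w))
    # greedy non-overlap selection by descending informativeness
    candidates.sort(key=lambda c: (-c[0], c[3]))
    chosen = []
    for score, matrix, positions, w in candidates:
        redundant = False
        for _, _, pos2, w2 in chosen:
            shared = sum(
                1
                for p1, p2 in zip(positions, pos2)
                if p1 >= 0
                and p2 >= 0
                and _site_interval_overlap(p1, w, p2, w2) >= min(w, w2) / 2
            )
            denom = sum(1 for p1, p2 in zip(positions, pos2) if p1 >= 0 and p2 >= 0)
            if denom and shared / denom > 0.5:
                redundant = True
                break
        if not redundant:
            chosen.append((score, matrix, positions, w))
        if len(chosen) == s:
            break
    null_cache: Dict[int, np.ndarray] = {}
    motifs = []
    for rank, (score, matrix, positions, w) in enumerate(chosen):
        n_sites = sum(1 for p in positions if p >= 0)
        pwm = Pwm(matrix=matrix, n_instances=n_sites)
        pwm.discovery_pvalue = discovery_pvalue(
            pwm, promoters, n_shuffles=n_shuffles, seed=seed, _null_cache=null_cache
        )
        pwm.motif_id = f"{promoters.operon_id}|m{rank}"
        motifs.append(pwm)
    motifs.sort(key=lambda p: (p.discovery_pvalue, -relative_entropy(p, bg), p.motif_id))
    for i, pwm in enumerate(motifs):
        pwm.motif_id = f"{promoters.operon_id}|m{i}"
    return MotifSet(operon_id=promoters.operon_id, motifs=motifs)


# ---------------------------------------------------------------------------
# Scanning with exact score-distribution p-values


def _int_lut(pwm: Pwm, bg: np.ndarray) -> np.ndarray:
    """Per-column integer log-odds (units of SCORE_GRANULARITY bits); the
    5th symbol (N) scores 0."""
    lo = np.log2(np.clip(pwm.matrix, 1e-12, None) / bg)
    lut = np.zeros((pwm.width, 5), dtype=np.int64)
    lut[:, :4] = np.rint(lo / SCORE_GRANULARITY).astype(np.int64)
    return lut


class ScoreDistribution:
    """Exact distribution of a PWM's integer-rounded log-odds score for a
    random word drawn from the 0-order background."""

    def __init__(self, pwm: Pwm, bg: np.ndarray):
        self.lut = _int_lut(pwm, bg)
        ints = self.lut[:, :4]
        lo_min = int(ints.min(axis=1).sum())
        lo_max = int(ints.max(axis=1).sum())
        probs = np.zeros(lo_max - lo_min + 1)
        # DP: start with the empty prefix at score 0, then add one column at
        # a time, shifting by that column's 4 possible scores.
        cur = np.array([1.0])
        cur_min = 0
        for j in range(ints.shape[0]):
            col = ints[j]
            new_min = cur_min + int(col.min())
            new_max = cur_min + len(cur) - 1 + int(col.max())
            new = np.zeros(new_max - new_min + 1)
            for b in range(4):
                off = cur_min + int(col[b]) - new_min
                new[off: off + len(cur)] += bg[b] * cur
            cur, cur_min = new, new_min
        self.min_score = cur_min
        self.pmf = cur
        # survival: P(S >= s)
        self.sf = np.cumsum(cur[::-1])[::-1]

    def tail(self, score_int: int) -> float:
        """P(score >= score_int) under the background."""
        i = score_int - self.min_score
        if i <= 0:
            return 1.0
        if i >= len(self.sf):
            return 0.0
        return float(self.sf[i])


def scan_pvalue(
    pwm: Pwm,
    seq: str,
    bg: np.ndarray,
    both_strands: bool = True,
    operon_id: str = "",
    _dist: Optional[ScoreDistribution] = None,
) -> ScanHit:
    """Best hit of a PWM in a sequence with site and sequence p-values.

    The site p-value is the exact background tail probability of the best
    score; the sequence p-value corrects for the 2*(L-w+1) scanned
    positions under independence. Sequences shorter than the motif return
    the no-hit sentinel (p-value 1).
    """
    w = pwm.width
    e = encode(seq)
    if len(e) < w:
        return ScanHit.no_hit(operon_id)
    dist = _dist if _dist is not None else ScoreDistribution(pwm, bg)
    wins = np.lib.stride_tricks.sliding_window_view(e, w)
    cols = np.arange(w)
    fwd = dist.lut[cols, wins].sum(axis=1)
    best_int = int(fwd.max())
    best_pos = int(fwd.argmax())
    best_strand = "+"
    n_candidates = len(fwd)
    if both_strands:
        rc_lut = dist.lut[::-1, [3, 2, 1, 0, 4]]
        rev = rc_lut[cols, wins].sum(axis=1)
        n_candidates *= 2
        if int(rev.max()) > best_int:
            best_int = int(rev.max())
            best_pos = int(rev.argmax())
            best_strand = "-"
    p_site = dist.tail(best_int)
    if p_site >= 1.0:
        p_seq = 1.0
    else:
        p_seq = -math.expm1(n_candidates * math.log1p(-p_site))
    return ScanHit(
        operon_id=operon_id,
        best_score=best_int * SCORE_GRANULARITY,
        position=best_pos,
        strand=best_strand,
        pvalue=min(max(p_seq, 0.0), 1.0),
        site_pvalue=p_site,
    )


def operon_scan_pvalue(
    pwm: Pwm,
    promoters: PromoterSet,
    bg: Optional[np.ndarray] = None,
    combine: str = "target",
    _dist: Optional[ScoreDistribution] = None,
) -> float:
    """Scan p-value deciding whether an operon carries a motif.

    ``combine='footprint'`` (default) is an intersection-union test of the
    two claims phylogenetic footprinting makes about a regulated operon:
    the motif occurs in the target genome's own promoter (p_target, the
    sequence-level scan p-value there) AND the occurrence is confirmed in
    the orthologous promoter set (p_support = C(n,2)·p_(2)², the
    order-statistic tail of the second-smallest per-promoter p-value, so
    one chance hit cannot confirm). The IUT p-value is the maximum of the
    two components. ``combine='supported'`` uses the confirmation term
    alone; ``combine='target'`` the target promoter alone;
    ``combine='min_bonferroni'`` the Bonferroni-corrected minimum over
    all promoters. Operons without a usable promoter return 1.0.
    """
    if bg is None:
        if not promoters.records:
            return 1.0
        bg = background_frequencies(promoters.sequences)
    dist = _dist if _dist is not None else ScoreDistribution(pwm, bg)
    if combine in ("supported", "footprint"):
        ps = sorted(
            scan_pvalue(pwm, s, bg, operon_id=promoters.operon_id, _dist=dist).pvalue
            for s in promoters.sequences
        )
        n = len(ps)
        if n == 0:
            return 1.0
        p_support = ps[0] if n == 1 else min(1.0, math.comb(n, 2) * ps[1] ** 2)
        if combine == "supported":
            return p_support
        target = promoters.target_promoter()
        p_target = (
            1.0
            if target is None
            else scan_pvalue(
                pwm, target, bg, operon_id=promoters.operon_id, _dist=dist
            ).pvalue
        )
        return max(p_target, p_support)
    if combine == "target":
        target = promoters.target_promoter()
        if target is None:
            return 1.0
        return scan_pvalue(
            pwm, target, bg, operon_id=promoters.operon_id, _dist=dist
        ).pvalue
    elif combine == "min_bonferroni":
        ps = [
            scan_pvalue(pwm, s, bg, operon_id=promoters.operon_id, _dist=dist).pvalue
            for s in promoters.sequences
        ]
        if not ps:
            return 1.0
        return min(1.0, min(ps) * len(ps))
    raise ValidationError(f"unknown combine rule {combine!r}")
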