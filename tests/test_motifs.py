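import itertools

import numpy as np
import pytest

from regulonminer.model import PromoterSet, Pwm, ValidationError
from regulonminer.motifs import (
    SCORE_GRANULARITY,
    ScoreDistribution,
    _int_lut,
    background_frequencies,
    discover_motifs,
    discovery_pvalue,
    operon_scan_pvalue,
    relative_entropy,
    scan_pvalue,
)

from conftest import random_pwm, site_pwm


def _random_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def _pset(seqs, operon_id="op", target="t"):
    return PromoterSet(
        operon_id=operon_id,
        records=[(f"g{i}" if i else target, s) for i, s in enumerate(seqs)],
        target_genome_id=target,
    )


# --- score distribution ----------------------------------------------------


def enumerate_tail(pwm, bg):
    """Exact tail probabilities by brute force over all 4^w words, on the
    same integer score grid as the DP."""
    lut = _int_lut(pwm, bg)
    w = pwm.width
    scores = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(lut[j, b] for j, b in enumerate(word)))
        p = float(np.prod([bg[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    return scores


@pytest.mark.parametrize("width", [4, 6, 8])
def test_dp_distribution_matches_exhaustive_enumeration(rng, width):
    pwm = random_pwm(rng, width)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    dist = ScoreDistribution(pwm, bg)
    pmf = enumerate_tail(pwm, bg)
    for s in sorted(pmf):
        exact_tail = sum(p for t, p in pmf.items() if t >= s)
        assert dist.tail(s) == pytest.approx(exact_tail, abs=1e-9)


def test_dp_distribution_monte_carlo_width_12(rng):
    pwm = site_pwm(rng, 12, n_sites=8)
    bg = np.full(4, 0.25)
    dist = ScoreDistribution(pwm, bg)
    lut = _int_lut(pwm, bg)
    n = 100_000
    words = rng.integers(0, 4, size=(n, 12))
    scores = lut[np.arange(12), words].sum(axis=1)
    for q in (0.5, 0.9, 0.99):
        t = int(np.quantile(scores, q))
        p_mc = float((scores >= t).mean())
        se = np.sqrt(p_mc * (1 - p_mc) / n)
        assert abs(dist.tail(t) - p_mc) <= 3 * se + 1e-12


# --- scanning --------------------------------------------------------------


def test_uniform_pwm_scores_zero_everywhere(rng):
    pwm = Pwm(matrix=np.full((8, 4), 0.25))
    hit = scan_pvalue(pwm, _random_seq(rng, 50), np.full(4, 0.25))
    assert hit.best_score == pytest.approx(0.0)
    assert hit.pvalue == pytest.approx(1.0)


def test_scan_shorter_than_motif_is_no_hit(rng):
    pwm = random_pwm(rng, 8)
    hit = scan_pvalue(pwm, "ACGTACG", np.full(4, 0.25), operon_id="op")
    assert hit.position == -1 and hit.pvalue == 1.0 and hit.strand == "."


def test_consensus_site_in_background_is_significant(rng):
    pwm = site_pwm(rng, 12, n_sites=30)
    bg = np.full(4, 0.25)
    seq = _random_seq(rng, 150) + pwm.consensus() + _random_seq(rng, 138)
    hit = scan_pvalue(pwm, seq, bg)
    assert hit.pvalue < 0.05
    assert hit.position == 150 and hit.strand == "+"


def test_scan_finds_reverse_strand_site(rng):
    from regulonminer.model import reverse_complement

    pwm = site_pwm(rng, 12, n_sites=30)
    bg = np.full(4, 0.25)
    seq = _random_seq(rng, 100) + reverse_complement(pwm.consensus()) + _random_seq(rng, 100)
    hit = scan_pvalue(pwm, seq, bg)
    assert hit.strand == "-" and hit.position == 100


def test_scan_site_pvalues_uniform_under_null(rng):
    from scipy import stats

    pwm = site_pwm(rng, 10, n_sites=12)
    bg = np.full(4, 0.25)
    dist = ScoreDistribution(pwm, bg)
    ps = [
        scan_pvalue(pwm, _random_seq(rng, 10), bg, both_strands=False, _dist=dist).pvalue
        for _ in range(1000)
    ]
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# --- operon-level scan -----------------------------------------------------


def test_operon_scan_pvalue_planted_vs_empty(rng):
    pwm = site_pwm(rng, 12, n_sites=30)
    site = pwm.consensus()
    seqs = [
        _random_seq(rng, 100) + site + _random_seq(rng, 100) for _ in range(6)
    ]
    ps = _pset(seqs)
    assert operon_scan_pvalue(pwm, ps) < 0.05
    empty = PromoterSet(operon_id="none", records=[], target_genome_id="t")
    assert operon_scan_pvalue(pwm, empty) == 1.0


def test_operon_scan_pvalue_deterministic(rng):
    pwm = site_pwm(rng, 10)
    ps = _pset([_random_seq(rng, 120) for _ in range(4)])
    assert operon_scan_pvalue(pwm, ps) == operon_scan_pvalue(pwm, ps)


def test_operon_scan_pvalue_unknown_rule(rng):
    pwm = site_pwm(rng, 10)
    ps = _pset([_random_seq(rng, 60)])
    with pytest.raises(ValidationError):
        operon_scan_pvalue(pwm, ps, combine="nope")


# --- discovery -------------------------------------------------------------


def _planted_promoters(rng, n, length, pwm, conservation_sites=True):
    out = []
    for _ in range(n):
        site = "".join(
            "ACGT"[rng.choice(4, p=col)] for col in pwm.matrix
        )
        pos = int(rng.integers(0, length - pwm.width + 1))
        seq = list(_random_seq(rng, length))
        seq[pos: pos + pwm.width] = site
        out.append("".join(seq))
    return out


def test_discover_recovers_planted_consensus(rng):
    truth = site_pwm(rng, 14, n_sites=200)  # sharp planted model
    # sharpen to ~0.9 conservation per column
    m = truth.matrix * 0.1 + np.eye(4)[truth.matrix.argmax(axis=1)] * 0.9
    truth = Pwm(matrix=m / m.sum(axis=1, keepdims=True))
    proms = _planted_promoters(rng, 20, 120, truth)
    found = discover_motifs(_pset(proms), seed=1)
    assert found.motifs, "a planted motif must be discovered"
    top = found.motifs[0]
    # compare consensus columns over the best ungapped alignment
    best = 0
    for off in range(-(top.width - 6), 15 - 6):
        s, e = max(0, off), min(14, off + top.width)
        agree = sum(
            truth.consensus()[j] == top.consensus()[j - off] for j in range(s, e)
        )
        best = max(best, agree)
    assert best >= 12


def test_discover_requires_two_promoters(rng):
    found = discover_motifs(_pset([_random_seq(rng, 200)]))
    assert len(found) == 0


def test_discover_seed_reproducible(rng):
    proms = [_random_seq(rng, 150) for _ in range(6)]
    a = discover_motifs(_pset(proms), seed=5)
    b = discover_motifs(_pset(proms), seed=5)
    assert [m.motif_id for m in a.motifs] == [m.motif_id for m in b.motifs]
    for x, y in zip(a.motifs, b.motifs):
        np.testing.assert_array_equal(x.matrix, y.matrix)
        assert x.discovery_pvalue == y.discovery_pvalue


def test_discovery_pvalue_floor_for_perfect_site(rng):
    truth = Pwm(matrix=np.eye(4)[rng.integers(0, 4, 14)] * 0.97 + 0.0075)
    proms = [
        _random_seq(rng, 60) + truth.consensus() + _random_seq(rng, 60)
        for _ in range(30)
    ]
    pwm = Pwm.from_sites([truth.consensus()] * 30)
    p = discovery_pvalue(pwm, _pset(proms), n_shuffles=200, seed=3)
    assert p == pytest.approx(1 / 201)


def test_discovery_pvalue_zero_shuffles_rejected(rng):
    pwm = site_pwm(rng, 8)
    with pytest.raises(ValidationError):
        discovery_pvalue(pwm, _pset([_random_seq(rng, 50)] * 3), n_shuffles=0)


def test_discovery_pvalue_null_motif_not_significant(rng):
    # a flat, uninformative matrix cannot beat rediscovered motifs from
    # shuffled data: its permutation p-value is near 1
    proms = [_random_seq(rng, 150) for _ in range(8)]
    flat = Pwm(matrix=np.full((10, 4), 0.25))
    p = discovery_pvalue(flat, _pset(proms), n_shuffles=50, seed=2)
    assert p > 0.9


def test_recovery_power_increases_with_conservation(rng):
    # spec-level property at reduced scale: stronger planted conservation
    # gives a more faithful consensus recovery
    def planted_accuracy(cons):
        local = np.random.default_rng(17)
        consensus = local.integers(0, 4, 12)
        m = np.full((12, 4), (1 - cons) / 3)
        m[np.arange(12), consensus] = cons
        truth = Pwm(matrix=m)
        proms = _planted_promoters(local, 16, 100, truth)
        found = discover_motifs(_pset(proms), widths=(10, 12, 14), seed=2)
        if not found.motifs:
            return 0.0
        top = found.motifs[0]
        best = 0
        for off in range(-(top.width - 6), 12 - 6):
            s, e = max(0, off), min(12, off + top.width)
            agree = sum(
                truth.consensus()[j] == top.consensus()[j - off]
                for j in range(s, e)
            )
            best = max(best, agree)
        return best / 12

    accs = [planted_accuracy(c) for c in (0.55, 0.75, 0.95)]
    assert accs[0] <= accs[1] <= accs[2] or (accs[2] - accs[0]) >= 0.25
    assert accs[2] >= 0.9


def test_background_frequencies_with_pseudocount():
    bg = background_frequencies(["AAAA"], pseudocount=1.0)
    np.testing.assert_allclose(bg, [5 / 8, 1 / 8, 1 / 8, 1 / 8])


def test_relative_entropy_zero_for_background(rng):
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    pwm = Pwm(matrix=np.tile(bg, (6, 1)))
    assert relative_entropy(pwm, bg) == pytest.approx(0.0, abs=1e-12)
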