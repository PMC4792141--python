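"""Synthetic benchmark generator with planted regulons and motifs.

Builds a complete, self-contained study system: a target genome whose
operons are laid out with realistic intergenic gaps, a panel of reference
genomes each carrying orthologous operons with diverged promoters,
gene-level orthology pairs, and a set of ground-truth regulons whose
members carry binding sites sampled from per-regulon PWMs. Every stage of
the prediction pipeline is therefore testable against known truth without
any external download.

The generator emulates: operon structure (1-3 genes), the 300 bp / whole
intergenic region promoter rule on both strands, ortholog presence as an
independent Bernoulli per reference genome, promoter divergence as
per-base substitution (no indels, no tree-structured phylogeny), and
binding-site conservation via Dirichlet-perturbed consensus columns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from . import io as rio
from .model import (
    BASES,
    Genome,
    Operon,
    OrthologyMap,
    Pwm,
    RegulonBenchmark,
    ValidationError,
    reverse_complement,
)
from .orthology import extract_promoter


@dataclass
class FixtureConfig:
    """Study conditions for a synthetic benchmark."""

    n_target_operons: int = 60
    n_reference_genomes: int = 30
    ortholog_presence_prob: float = 0.6
    n_regulons: int = 5
    regulon_size: int = 10
    motif_width: int = 14
    conservation: float = 0.85
    planting_rate: float = 0.9
    promoter_length: int = 300
    gc_content: float = 0.5
    divergence: float = 0.3
    overlap_regulons: int = 1
    min_gap: int = 120
    max_gap: int = 350
    genes_per_operon: Tuple[int, int] = (1, 3)
    gene_length: int = 300
    seed: int = 7

    def validate(self) -> None:
        probs = {
            "ortholog_presence_prob": self.ortholog_presence_prob,
            "conservation": self.conservation,
            "planting_rate": self.planting_rate,
            "gc_content": self.gc_content,
            "divergence": self.divergence,
        }
        for name, v in probs.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_target_operons < 1 or self.n_reference_genomes < 0:
            raise ValidationError("sizes must be >= 1")
        distinct = self.n_regulons * self.regulon_size - self.overlap_regulons
        if distinct > self.n_target_operons:
            raise ValidationError(
                f"{self.n_regulons} regulons of {self.regulon_size} need "
                f"{distinct} operons but only {self.n_target_operons} exist"
            )
        if self.overlap_regulons > self.n_regulons - 1:
            raise ValidationError("at most n_regulons-1 operons can be shared")
        if self.min_gap < 2 * self.motif_width + 8:
            raise ValidationError("min_gap too small to host planted sites")


@dataclass
class PlantedSite:
    """One binding site planted in a promoter (coding-strand coordinates)."""

    operon_id: str
    genome_id: str
    regulon: str
    position: int  # 0-based offset within the extracted promoter
    site: str


@dataclass
class Fixture:
    """A generated benchmark: inputs plus ground truth."""

    config: FixtureConfig
    target_genome: Genome
    ref_operons: List[Operon]
    orthology: OrthologyMap
    ref_promoters: Dict[str, str]
    benchmark: RegulonBenchmark
    truth_motifs: Dict[str, Pwm]
    planted_sites: List[PlantedSite]

    @property
    def operon_ids(self) -> List[str]:
        return [op.operon_id for op in self.target_genome.operons]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def _truth_pwm(rng: np.random.Generator, width: int, conservation: float, motif_id: str) -> Pwm:
    """Dirichlet-perturbed consensus columns: the consensus base has mean
    probability ``conservation``, the rest share the remainder."""
    concentration = 60.0
    cols = np.empty((width, 4))
    for j in range(width):
        consensus = rng.integers(0, 4)
        alpha = np.full(4, (1 - conservation) * concentration / 3)
        alpha[consensus] = conservation * concentration
        cols[j] = rng.dirichlet(alpha)
    return Pwm(matrix=cols, n_instances=0, discovery_pvalue=0.0, motif_id=motif_id)


def _sample_site(rng: np.random.Generator, pwm: Pwm) -> str:
    return "".join(
        BASES[rng.choice(4, p=col / col.sum())] for col in pwm.matrix
    )


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def generate(config: FixtureConfig) -> Fixture:
    """Generate a complete synthetic benchmark (deterministic per seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_target_operons
    w = config.motif_width

    # --- regulon membership -------------------------------------------------
    regulon_names = [f"R{i + 1}" for i in range(config.n_regulons)]
    membership: Dict[str, Set[int]] = {}
    cursor = 0
    for i, name in enumerate(regulon_names):
        if i > 0 and i <= config.overlap_regulons:
            start = cursor - 1  # share the previous regulon's last operon
        else:
            start = cursor
        members = set(range(start, start + config.regulon_size))
        membership[name] = members
        cursor = start + config.regulon_size
    truth_motifs = {
        name: _truth_pwm(rng, w, config.conservation, motif_id=name)
        for name in regulon_names
    }
    operon_regulons: Dict[int, List[str]] = {}
    for name, members in membership.items():
        for m in members:
            operon_regulons.setdefault(m, []).append(name)

    # --- target genome layout ----------------------------------------------
    # each operon slot: [gap_left | genes | gap_right]; minus-strand
    # promoters live in gap_right, plus-strand promoters in gap_left, so
    # planted sites can never collide across neighboring operons.
    gaps_left = rng.integers(config.min_gap, config.max_gap + 1, size=n)
    gaps_right = rng.integers(config.min_gap, config.max_gap + 1, size=n)
    n_genes = rng.integers(
        config.genes_per_operon[0], config.genes_per_operon[1] + 1, size=n
    )
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    operons: List[Operon] = []
    pos = 0
    coords = []
    for i in range(n):
        pos += int(gaps_left[i])
        start = pos + 1
        end = pos + int(n_genes[i]) * config.gene_length
        pos = end + int(gaps_right[i])
        oid = f"op{i:03d}"
        coords.append((start, end))
        operons.append(
            Operon(
                operon_id=oid,
                genome_id="target",
                gene_ids=tuple(f"{oid}_g{k}" for k in range(int(n_genes[i]))),
                strand=str(strands[i]),
                start=start,
                end=end,
            )
        )
    genome_len = pos + int(rng.integers(config.min_gap, config.max_gap + 1))
    seq = list(_random_seq(rng, genome_len, config.gc_content))

    # --- plant sites in the target genome ----------------------------------
    planted: List[PlantedSite] = []
    target_site_layout: Dict[str, List[Tuple[str, int]]] = {}  # oid -> [(regulon, gap offset)]
    for i, op in enumerate(operons):
        regs = operon_regulons.get(i, [])
        carried = [r for r in regs if rng.random() < config.planting_rate]
        if not carried:
            continue
        gap = int(gaps_left[i]) if op.strand == "+" else int(gaps_right[i])
        window = min(gap, config.promoter_length)
        # non-overlapping positions within the operon's own gap window
        placed: List[Tuple[str, int]] = []
        for reg in carried:
            for _attempt in range(200):
                p = int(rng.integers(0, window - w + 1))
                if all(abs(p - q) >= w for _, q in placed):
                    placed.append((reg, p))
                    break
        target_site_layout[op.operon_id] = placed
        for reg, p in placed:
            site = _sample_site(rng, truth_motifs[reg])
            if op.strand == "+":
                # p counts from the near (3') edge of the gap: genome
                # positions start-1-p-w+1 .. start-1-p hold the site
                g_hi = op.start - 1 - p  # 1-based inclusive
                g_lo = g_hi - w + 1
                seq[g_lo - 1: g_hi] = list(site)
            else:
                g_lo = op.end + 1 + p
                g_hi = g_lo + w - 1
                seq[g_lo - 1: g_hi] = list(reverse_complement(site))
            planted.append(
                PlantedSite(
                    operon_id=op.operon_id,
                    genome_id="target",
                    regulon=reg,
                    position=-1,  # promoter coordinates filled in below
                    site=site,
                )
            )
    genome = Genome(genome_id="target", sequence="".join(seq), operons=operons)

    # resolve promoter-coordinate positions and verify sites in place
    target_promoters = {
        op.operon_id: extract_promoter(op, genome, max_len=config.promoter_length)
        for op in operons
    }
    by_operon: Dict[str, List[PlantedSite]] = {}
    for s in planted:
        by_operon.setdefault(s.operon_id, []).append(s)
    for oid, sites in by_operon.items():
        prom = target_promoters[oid]
        lp = len(prom)
        for s, (reg, p) in zip(sites, target_site_layout[oid]):
            pos0 = lp - p - w  # gap offset -> promoter 0-based offset
            assert prom[pos0: pos0 + w] == s.site, "planted site must match sequence"
            s.position = pos0

    # --- reference genomes, orthology, promoters ----------------------------
    ref_operons: List[Operon] = []
    orth_pairs: List[Tuple[str, str, str]] = []
    ref_promoters: Dict[str, str] = {}
    for r in range(config.n_reference_genomes):
        gid = f"ref{r:02d}"
        offset = 1
        for i, op in enumerate(operons):
            if rng.random() >= config.ortholog_presence_prob:
                continue
            roid = f"{gid}:{op.operon_id}"
            length = len(op.gene_ids) * config.gene_length
            ref_operons.append(
                Operon(
                    operon_id=roid,
                    genome_id=gid,
                    gene_ids=tuple(f"{roid}:g{k}" for k in range(len(op.gene_ids))),
                    strand=op.strand,
                    start=offset,
                    end=offset + length - 1,
                )
            )
            offset += length + 200
            for k, tgene in enumerate(op.gene_ids):
                orth_pairs.append((tgene, f"{roid}:g{k}", gid))
            prom = target_promoters[op.operon_id]
            if not prom:
                continue
            mutated = _mutate(rng, prom, config.divergence)
            # conserve the binding sites: fresh PWM samples at the same spot
            out = list(mutated)
            for s in by_operon.get(op.operon_id, []):
                fresh = _sample_site(rng, truth_motifs[s.regulon])
                out[s.position: s.position + w] = list(fresh)
                planted.append(
                    PlantedSite(
                        operon_id=roid,
                        genome_id=gid,
                        regulon=s.regulon,
                        position=s.position,
                        site=fresh,
                    )
                )
            ref_promoters[roid] = "".join(out)

    benchmark = RegulonBenchmark(
        regulons={
            name: {operons[i].operon_id for i in members}
            for name, members in membership.items()
        }
    )
    return Fixture(
        config=config,
        target_genome=genome,
        ref_operons=ref_operons,
        orthology=OrthologyMap.from_pairs(orth_pairs),
        ref_promoters=ref_promoters,
        benchmark=benchmark,
        truth_motifs=truth_motifs,
        planted_sites=planted,
    )


def standard_fixture() -> Fixture:
    """The canonical benchmark: 60 target operons, 30 reference genomes,
    5 regulons of 10 (one operon shared by two regulons), width-14 motifs
    at conservation 0.85, planting rate 0.9, seed 7."""
    return generate(FixtureConfig())


def write_fixture(fixture: Fixture, outdir) -> None:
    """Write the fixture as standard-format input files plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_operon_table(fixture.target_genome.operons, outdir / "operons_target.tsv")
    rio.write_operon_table(fixture.ref_operons, outdir / "operons_ref.tsv")
    rio.write_orthology(fixture.orthology, outdir / "orthology.tsv")
    rio.write_fasta(
        [(fixture.target_genome.genome_id, fixture.target_genome.sequence)],
        outdir / "genome_target.fa",
    )
    rio.write_fasta(sorted(fixture.ref_promoters.items()), outdir / "ref_promoters.fa")
    rio.write_regulon_benchmark(fixture.benchmark, outdir / "benchmark.tsv")
    rio.write_meme_pwm(
        [fixture.truth_motifs[k] for k in sorted(fixture.truth_motifs)],
        outdir / "truth_motifs.meme",
    )
    truth = {
        "config": asdict(fixture.config),
        "regulons": {
            tf: sorted(m) for tf, m in fixture.benchmark.regulons.items()
        },
        "planted_sites": [asdict(s) for s in fixture.planted_sites],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
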