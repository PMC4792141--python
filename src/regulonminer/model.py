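"""Core domain types for bacterial regulon prediction.

The objects here mirror the biology: an :class:`Operon` is a transcription
unit (one or more tandem same-strand genes sharing a promoter), a
:class:`Pwm` is the probabilistic model of a transcription-factor binding
motif, a :class:`PromoterSet` is the collection of orthologous upstream
regions gathered for one operon by phylogenetic footprinting, and a
:class:`RegulonPrediction` is a predicted set of co-regulated operons with
the motif that binds them.

All containers validate their invariants at construction time so that
malformed data fails loudly at the boundary rather than deep inside the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ValidationError(ValueError):
    """An input object violates a domain invariant."""


@dataclass(frozen=True)
class Operon:
    """A transcription unit: ordered genes on one strand of a genome.

    Coordinates are 1-based inclusive (GFF convention) and span the whole
    transcribed region, ``start <= end`` regardless of strand.
    """

    operon_id: str
    genome_id: str
    gene_ids: Tuple[str, ...]
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if not self.gene_ids:
            raise ValidationError(f"operon {self.operon_id}: empty gene list")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"operon {self.operon_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"operon {self.operon_id}: invalid coordinates {self.start}..{self.end}"
            )
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))


@dataclass
class Genome:
    """A (single-replicon) genome sequence with its operon annotation."""

    genome_id: str
    sequence: str
    operons: List[Operon] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        seen = set()
        for op in self.operons:
            if op.operon_id in seen:
                raise ValidationError(f"duplicate operon id {op.operon_id}")
            seen.add(op.operon_id)
            if op.end > n:
                raise ValidationError(
                    f"operon {op.operon_id} end {op.end} exceeds replicon length {n}"
                )


@dataclass
class Pwm:
    """Position weight matrix over {A,C,G,T}, one probability 4-vector per column.

    ``n_instances`` is the number of aligned sites the matrix was estimated
    from; ``discovery_pvalue`` is the significance of the motif's discovery
    (permutation-based for de novo motifs).
    """

    matrix: np.ndarray  # shape (width, 4), rows sum to 1
    n_instances: int = 0
    discovery_pvalue: float = 1.0
    motif_id: str = ""

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValidationError("PWM matrix must have shape (width, 4)")
        if m.shape[0] < 4:
            raise ValidationError("PWM width must be >= 4")
        if (m < 0).any():
            raise ValidationError("PWM entries must be non-negative")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("PWM columns must sum to 1 (within 1e-9)")
        if not (0.0 <= self.discovery_pvalue <= 1.0):
            raise ValidationError("discovery_pvalue must lie in [0,1]")
        self.matrix = m

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            matrix=self.matrix[::-1, ::-1].copy(),
            n_instances=self.n_instances,
            discovery_pvalue=self.discovery_pvalue,
            motif_id=self.motif_id,
        )

    @classmethod
    def from_sites(
        cls,
        sites: Sequence[str],
        pseudocount: float = 0.5,
        discovery_pvalue: float = 1.0,
        motif_id: str = "",
    ) -> "Pwm":
        """Estimate a PWM from equal-length aligned sites.

        Non-ACGT symbols are excluded from the counts; each cell receives
        ``pseudocount`` before normalization.
        """
        if not sites:
            raise ValidationError("cannot build a PWM from zero sites")
        w = len(sites[0])
        if any(len(s) != w for s in sites):
            raise ValidationError("sites must have equal length")
        counts = np.full((w, 4), pseudocount, dtype=float)
        for s in sites:
            for j, c in enumerate(s.upper()):
                i = BASE_INDEX.get(c)
                if i is not None:
                    counts[j, i] += 1.0
        counts /= counts.sum(axis=1, keepdims=True)
        return cls(
            matrix=counts,
            n_instances=len(sites),
            discovery_pvalue=discovery_pvalue,
            motif_id=motif_id,
        )


@dataclass
class PromoterSet:
    """Orthologous promoters collected for one target operon.

    ``records`` holds ``(source_genome_id, sequence)`` pairs, sequences 5'->3'
    on the operon's coding strand, at most 300 bp after the intergenic rule.
    The target genome's own promoter (if any) is the record whose source is
    the target genome.
    """

    operon_id: str
    records: List[Tuple[str, str]] = field(default_factory=list)
    target_genome_id: Optional[str] = None

    def __post_init__(self):
        for g, s in self.records:
            if not s:
                raise ValidationError(
                    f"promoter set {self.operon_id}: empty sequence from {g}"
                )

    @property
    def sequences(self) -> List[str]:
        return [s for _, s in self.records]

    def target_promoter(self) -> Optional[str]:
        for g, s in self.records:
            if g == self.target_genome_id:
                return s
        return None

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MotifSet:
    """The motifs discovered in one operon's orthologous promoter set,
    ordered by ascending discovery p-value."""

    operon_id: str
    motifs: List[Pwm] = field(default_factory=list)

    def __post_init__(self):
        ps = [m.discovery_pvalue for m in self.motifs]
        if any(a > b for a, b in zip(ps, ps[1:])):
            raise ValidationError(
                f"motif set {self.operon_id}: p-values must be non-decreasing"
            )

    def __len__(self) -> int:
        return len(self.motifs)

    def __bool__(self) -> bool:
        return bool(self.motifs)


@dataclass
class RegulonBenchmark:
    """Documented regulons: TF name -> set of member operon ids."""

    regulons: Dict[str, Set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regulons)


@dataclass(frozen=True)
class OrthologyMap:
    """Gene-level orthology between the target genome and reference genomes.

    Each pair is ``(target_gene_id, reference_gene_id, reference_genome_id)``;
    a target gene maps to at most one gene per reference genome.
    """

    pairs: frozenset

    @classmethod
    def from_pairs(cls, pairs) -> "OrthologyMap":
        seen: Dict[Tuple[str, str], str] = {}
        for tgene, rgene, rgenome in pairs:
            key = (tgene, rgenome)
            prev = seen.get(key)
            if prev is not None and prev != rgene:
                raise ValidationError(
                    f"target gene {tgene} maps to both {prev} and {rgene} in {rgenome}"
                )
            seen[key] = rgene
        return cls(pairs=frozenset((t, r, g) for (t, g), r in seen.items()))

    def targets_of(self) -> Dict[str, Set[str]]:
        """reference gene id -> set of target gene ids it is orthologous to."""
        out: Dict[str, Set[str]] = {}
        for t, r, _ in self.pairs:
            out.setdefault(r, set()).add(t)
        return out


@dataclass
class PhyleticProfile:
    """0/1 presence vector of an operon's orthologs across reference genomes."""

    operon_id: str
    genome_ids: Tuple[str, ...]
    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=int)
        if v.shape != (len(self.genome_ids),):
            raise ValidationError("profile vector length must match genome list")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("profile entries must be 0/1")
        self.vector = v


@dataclass
class ScanHit:
    """Best match of a PWM in one promoter, with site and sequence p-values."""

    operon_id: str
    best_score: float  # log-odds, bits
    position: int  # 0-based offset of the best site, -1 for no-hit
    strand: str  # '+', '-' or '.' for no-hit
    pvalue: float  # sequence-level p-value
    site_pvalue: float = 1.0

    NO_HIT_POSITION = -1

    @classmethod
    def no_hit(cls, operon_id: str) -> "ScanHit":
        return cls(
            operon_id=operon_id,
            best_score=float("-inf"),
            position=cls.NO_HIT_POSITION,
            strand=".",
            pvalue=1.0,
            site_pvalue=1.0,
        )


@dataclass
class RegulonPrediction:
    """A predicted regulon: operons sharing the representative motif ``m_c``.

    ``seed_clique`` records the motif-level clique the prediction grew from;
    ``member_pvalues`` are the scan p-values that decided membership.
    """

    rank: int
    operons: Set[str]
    representative_motif: Pwm
    member_pvalues: Dict[str, float] = field(default_factory=dict)
    seed_clique: List[Tuple[str, int]] = field(default_factory=list)
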