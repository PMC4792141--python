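"""End-to-end orchestration: promoters → motifs → graph → regulons.

The :class:`RunConfig` carries every stage parameter with its default
(ω threshold 0.5, label z threshold 2, edge filter α=20%/β=10, M=300
cliques, refinement p cutoff 0.05, motif widths 8–20, up to 5 motifs per
operon) and round-trips through YAML. :func:`run_pipeline` is the single
in-memory entry point; the CLI wraps it with file IO, atomic writes and a
manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import yaml

from .cliques import predict_regulons
from .coreg import CoRegGraph, build_graph, expand_labels
from .model import (
    Genome,
    MotifSet,
    Operon,
    OrthologyMap,
    PromoterSet,
    RegulonPrediction,
    ValidationError,
)
from .motifs import discover_motifs
from .orthology import collect_promoter_sets

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, at their standard defaults."""

    omega_threshold: float = 0.5
    z_threshold: float = 2.0
    alpha_pct: float = 20.0
    beta: int = 10
    max_cliques: int = 300
    p_cut: float = 0.05
    width_min: int = 8
    width_max: int = 20
    motifs_per_operon: int = 5
    n_shuffles: int = 200
    promoter_length: int = 300
    dedup_identity: float = 0.9
    min_overlap: int = 6
    blowup_weight: str = "zscore"
    scan_combine: str = "footprint"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha_pct <= 100):
            raise ValidationError(f"alpha_pct must lie in (0, 100], got {self.alpha_pct}")
        if not (0 <= self.omega_threshold <= 1):
            raise ValidationError("omega_threshold must lie in [0, 1]")
        if not (0 < self.p_cut < 1):
            raise ValidationError("p_cut must lie in (0, 1)")
        if self.beta < 0 or self.max_cliques < 1:
            raise ValidationError("beta must be >= 0 and max_cliques >= 1")
        if not (4 <= self.width_min <= self.width_max):
            raise ValidationError("need 4 <= width_min <= width_max")
        if self.motifs_per_operon < 1 or self.n_shuffles < 1:
            raise ValidationError("motifs_per_operon and n_shuffles must be >= 1")
        if self.blowup_weight not in ("zscore", "omega"):
            raise ValidationError("blowup_weight must be 'zscore' or 'omega'")
        if self.scan_combine not in ("footprint", "supported", "target", "min_bonferroni"):
            raise ValidationError(
                "scan_combine must be one of footprint, supported, target, min_bonferroni"
            )

    @property
    def widths(self) -> Tuple[int, ...]:
        return tuple(range(self.width_min, self.width_max + 1))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline produced, stage by stage."""

    config: RunConfig
    promoter_sets: Dict[str, PromoterSet]
    groups: Dict[str, Set[str]]
    motif_sets: Dict[str, MotifSet]
    graph: CoRegGraph
    predictions: List[RegulonPrediction]
    primary_cliques: List[List[Tuple[str, int]]]
    timings: Dict[str, float] = field(default_factory=dict)

    def primary_clusters(self) -> List[Set[str]]:
        """Operon sets of the seed cliques (the unrefined predictions)."""
        return [{oid for oid, _ in c} for c in self.primary_cliques]


def discover_all_motifs(
    promoter_sets: Dict[str, PromoterSet], config: RunConfig
) -> Dict[str, MotifSet]:
    out = {}
    for oid in sorted(promoter_sets):
        out[oid] = discover_motifs(
            promoter_sets[oid],
            widths=config.widths,
            s=config.motifs_per_operon,
            seed=config.seed,
            n_shuffles=config.n_shuffles,
        )
    return out


def run_pipeline(
    target_genome: Genome,
    ref_operons: Sequence[Operon],
    orthology: OrthologyMap,
    ref_promoters: Dict[str, str],
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """Run footprinting, motif discovery, graph construction and regulon
    clustering end to end (deterministic for a fixed config/seed)."""
    config = config or RunConfig()
    config.validate()
    timings: Dict[str, float] = {}

    t0 = time.perf_counter()
    promoter_sets, groups = collect_promoter_sets(
        target_genome,
        ref_operons,
        orthology,
        ref_promoters,
        max_len=config.promoter_length,
        identity=config.dedup_identity,
    )
    timings["footprint"] = time.perf_counter() - t0
    logger.info(
        "collected %d promoter sets (%.1fs)", len(promoter_sets), timings["footprint"]
    )

    t0 = time.perf_counter()
    motif_sets = discover_all_motifs(promoter_sets, config)
    timings["motifs"] = time.perf_counter() - t0
    logger.info(
        "discovered motifs for %d operons (%.1fs)", len(motif_sets), timings["motifs"]
    )

    t0 = time.perf_counter()
    graph = build_graph(
        motif_sets,
        omega_threshold=config.omega_threshold,
        min_overlap=config.min_overlap,
    )
    expand_labels(graph, z_threshold=config.z_threshold)
    timings["graph"] = time.perf_counter() - t0
    logger.info(
        "co-regulation graph: %d operons, %d edges (%.1fs)",
        len(graph.operon_ids),
        len(graph.edges),
        timings["graph"],
    )

    t0 = time.perf_counter()
    predictions, cliques = predict_regulons(
        graph,
        motif_sets,
        promoter_sets,
        alpha_pct=config.alpha_pct,
        beta=config.beta,
        max_cliques=config.max_cliques,
        p_cut=config.p_cut,
        blowup_weight=config.blowup_weight,
        combine=config.scan_combine,
    )
    timings["cluster"] = time.perf_counter() - t0
    logger.info(
        "%d predictions from %d cliques (%.1fs)",
        len(predictions),
        len(cliques),
        timings["cluster"],
    )
    return PipelineResult(
        config=config,
        promoter_sets=promoter_sets,
        groups=groups,
        motif_sets=motif_sets,
        graph=graph,
        predictions=predictions,
        primary_cliques=cliques,
        timings=timings,
    )


# ---------------------------------------------------------------------------
# Serialization


def predictions_to_json(result: PipelineResult) -> str:
    """Canonical JSON for the prediction output (byte-stable across runs
    with the same config and inputs)."""
    payload = {
        "manifest": {
            "config": asdict(result.config),
            "config_digest": result.config.digest(),
            "n_operons": len(result.promoter_sets),
        },
        "predictions": [
            {
                "rank": p.rank,
                "operons": sorted(p.operons),
                "motif": {
                    "id": p.representative_motif.motif_id,
                    "width": p.representative_motif.width,
                    "n_instances": p.representative_motif.n_instances,
                    "discovery_pvalue": p.representative_motif.discovery_pvalue,
                    "matrix": [
                        [round(float(x), 6) for x in row]
                        for row in p.representative_motif.matrix
                    ],
                },
                "member_pvalues": {
                    k: float(v) for k, v in sorted(p.member_pvalues.items())
                },
                "seed_clique": [[oid, idx] for oid, idx in p.seed_clique],
            }
            for p in result.predictions
        ],
        "primary_clusters": [
            sorted({oid for oid, _ in clique}) for clique in result.primary_cliques
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def atomic_write(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)
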