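"""Readers and writers for the external formats the pipeline touches.

Tables are tab-separated with a header line; operon gene lists are joined
with ";". Coordinates are 1-based inclusive in files and converted to
Python's 0-based half-open slices only at the point of sequence access.
FASTA goes through Biopython. PWMs are interchanged in the MEME minimal
text format; that parser is implemented here because the renormalization
contract (repair column sums off by <= 1e-3, reject anything worse) must be
applied to the raw file values.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    BASES,
    Operon,
    OrthologyMap,
    Pwm,
    RegulonBenchmark,
    ValidationError,
)

_DNA_OK = set("ACGTN")


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# Operon tables


OPERON_COLUMNS = ["operon_id", "genome_id", "gene_ids", "strand", "start", "end"]


def read_operon_table(path) -> List[Operon]:
    """Read a DOOR-like operon table (TSV with header).

    Columns: operon_id, genome_id, gene_ids (";"-joined), strand, start, end.
    Duplicate operon ids within a genome are rejected.
    """
    path = Path(path)
    operons: List[Operon] = []
    seen = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file")
        if [h.strip() for h in header] != OPERON_COLUMNS:
            raise ParseError(
                f"{path}: line 1: expected header {OPERON_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 fields, got {len(row)}")
            operon_id, genome_id, genes_s, strand, start_s, end_s = (
                f.strip() for f in row
            )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates")
            gene_ids = tuple(g for g in genes_s.split(";") if g)
            key = (genome_id, operon_id)
            if key in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate operon id {operon_id} in {genome_id}"
                )
            seen.add(key)
            try:
                operons.append(
                    Operon(operon_id, genome_id, gene_ids, strand, start, end)
                )
            except ValidationError as e:
                raise ValidationError(f"{path}: line {lineno}: {e}") from e
    return operons


def write_operon_table(operons: Iterable[Operon], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(OPERON_COLUMNS)
        for op in operons:
            w.writerow(
                [op.operon_id, op.genome_id, ";".join(op.gene_ids), op.strand, op.start, op.end]
            )


# ---------------------------------------------------------------------------
# FASTA


def _clean_dna(seq: str) -> str:
    """Uppercase; mask non-ACGT IUPAC symbols to N."""
    s = seq.upper()
    if set(s) - _DNA_OK:
        s = "".join(c if c in _DNA_OK else "N" for c in s)
    return s


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA as (header, sequence) pairs; sequences uppercased,
    non-ACGT symbols masked to N."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, _clean_dna(str(rec.seq))))
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 70) -> None:
    recs = []
    for header, seq in records:
        rid = header.split()[0]
        recs.append(
            SeqRecord(Seq(seq), id=rid, description=header[len(rid):].strip())
        )
    with Path(path).open("w") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# MEME minimal format


def read_meme_pwm(path) -> List[Pwm]:
    """Parse PWMs from a MEME minimal text file.

    Columns whose probabilities sum to within 1e-3 of 1 are renormalized;
    larger deviations are an error.
    """
    path = Path(path)
    text = path.read_text()
    if "MEME version" not in text:
        raise ParseError(f"{path}: not a MEME minimal file (missing 'MEME version')")
    pwms: List[Pwm] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1] if len(parts) > 1 else f"motif_{len(pwms) + 1}"
            # find the letter-probability header
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[j].strip().startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {motif_id} has no probability matrix")
                j += 1
            if j >= len(lines):
                raise ParseError(f"{path}: motif {motif_id} has no probability matrix")
            header = lines[j].strip()
            attrs: Dict[str, str] = {}
            fields = header.split(":", 1)[1].split() if ":" in header else []
            for k in range(0, len(fields) - 1, 2):
                attrs[fields[k].rstrip("=")] = fields[k + 1]
            rows = []
            j += 1
            while j < len(lines):
                s = lines[j].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                try:
                    vals = [float(x) for x in s.split()]
                except ValueError:
                    break
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}: line {j + 1}: expected 4 probabilities, got {len(vals)}"
                    )
                rows.append(vals)
                j += 1
            m = np.array(rows, dtype=float)
            if m.size == 0:
                raise ParseError(f"{path}: motif {motif_id} has an empty matrix")
            sums = m.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise ParseError(
                    f"{path}: motif {motif_id} column {bad} sums to {sums[bad]:.4f}"
                )
            m = m / sums[:, None]
            nsites = int(attrs.get("nsites", 0))
            pval = float(attrs.get("P", attrs.get("E", 1.0)))
            pval = min(max(pval, 0.0), 1.0)
            pwms.append(
                Pwm(matrix=m, n_instances=nsites, discovery_pvalue=pval, motif_id=motif_id)
            )
            i = j
        else:
            i += 1
    return pwms


def write_meme_pwm(pwms: Sequence[Pwm], path, background=None) -> None:
    """Write PWMs as a MEME minimal text file (discovery p-value stored in
    the ``P=`` attribute of the matrix header)."""
    bg = background if background is not None else [0.25] * 4
    buf = _io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write(
        "Background letter frequencies\n"
        + " ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg))
        + "\n\n"
    )
    for pwm in pwms:
        buf.write(f"MOTIF {pwm.motif_id or 'motif'}\n")
        buf.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {pwm.n_instances} P= {pwm.discovery_pvalue:.6g}\n"
        )
        for row in pwm.matrix:
            buf.write(" ".join(f"{x:.6f}" for x in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Benchmarks and orthology


def read_regulon_benchmark(path, known_operon_ids=None):
    """Read a TF -> operon benchmark table (columns tf_name, operon_id).

    Rows naming operons absent from ``known_operon_ids`` (when given) are
    excluded and returned in a rejects list.
    """
    path = Path(path)
    regulons: Dict[str, set] = {}
    rejects: List[Tuple[str, str]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file")
        if [h.strip() for h in header] != ["tf_name", "operon_id"]:
            raise ParseError(f"{path}: expected header ['tf_name', 'operon_id']")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            tf, operon = row[0].strip(), row[1].strip()
            if known_operon_ids is not None and operon not in known_operon_ids:
                rejects.append((tf, operon))
                continue
            regulons.setdefault(tf, set()).add(operon)
    return RegulonBenchmark(regulons=regulons), rejects


def write_regulon_benchmark(benchmark: RegulonBenchmark, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tf_name", "operon_id"])
        for tf in sorted(benchmark.regulons):
            for op in sorted(benchmark.regulons[tf]):
                w.writerow([tf, op])


def read_orthology(path) -> OrthologyMap:
    """Read gene orthology pairs (columns target_gene, ref_gene, ref_genome)."""
    path = Path(path)
    pairs = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file")
        if [h.strip() for h in header] != ["target_gene", "ref_gene", "ref_genome"]:
            raise ParseError(
                f"{path}: expected header ['target_gene', 'ref_gene', 'ref_genome']"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 fields")
            pairs.append(tuple(f.strip() for f in row))
    return OrthologyMap.from_pairs(pairs)


def write_orthology(orth: OrthologyMap, path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_gene", "ref_gene", "ref_genome"])
        for t, r, g in sorted(orth.pairs):
            w.writerow([t, r, g])
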