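"""Genomic primitives: intervals, peaks, gene models and their file formats.

Coordinates are 0-based half-open throughout, matching BED. A gene's
transcription start site (TSS) is its `start` on the + strand and `end - 1`
on the − strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class BedParseError(ValueError):
    """Raised for malformed BED/gene-table lines; carries the line number."""


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak (or any genomic interval) with optional name/score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand; the TSS is derived from the strand."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: require 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_bed(source: Union[str, Path, TextIO]) -> list[Peak]:
    """Read BED3+ into peaks, preserving input order.

    track/browser/comment lines are tolerated. Malformed coordinates raise
    :class:`BedParseError` with the offending line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_bed(fh)
    peaks: list[Peak] = []
    for lineno, line in enumerate(source, start=1):
        if _is_skippable(line):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise BedParseError(f"line {lineno}: expected >= 3 tab-separated fields")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
        if start >= end or start < 0:
            raise BedParseError(
                f"line {lineno}: invalid interval {chrom}:{start}-{end}"
            )
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            score = float(fields[4])
        peaks.append(Peak(chrom, start, end, name, score))
    return peaks


def write_bed(peaks: Iterable[Peak], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_bed(peaks, fh)
        return
    for p in peaks:
        cols = [p.chrom, str(p.start), str(p.end)]
        if p.name is not None or p.score is not None:
            cols.append(p.name if p.name is not None else ".")
        if p.score is not None:
            cols.append(repr(p.score) if p.score != int(p.score) else str(int(p.score)))
        dest.write("\t".join(cols) + "\n")


def read_gene_table(source: Union[str, Path, TextIO]) -> list[GeneModel]:
    """Read a gene table: TSV with chrom, start, end, gene id, (score), strand.

    The column layout doubles as BED6 (score column optional and ignored).
    A header line starting with 'chrom' is tolerated.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_gene_table(fh)
    genes: list[GeneModel] = []
    for lineno, line in enumerate(source, start=1):
        if _is_skippable(line) or line.lower().startswith("chrom\t"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 5:
            raise BedParseError(f"line {lineno}: expected >= 5 fields (BED6-like)")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
        gene_id = fields[3]
        strand = fields[5] if len(fields) > 5 else fields[4]
        if strand not in ("+", "-"):
            raise BedParseError(f"line {lineno}: bad strand {strand!r}")
        try:
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
        except ValueError as exc:
            raise BedParseError(f"line {lineno}: {exc}") from exc
    return genes


def write_gene_table(genes: Iterable[GeneModel], dest: Union[str, Path, TextIO]) -> None:
    """Write genes as BED6 (name = gene id, score placeholder 0)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_gene_table(genes, fh)
        return
    for g in genes:
        dest.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_fasta(source: Union[str, Path, TextIO]) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_fasta(fh)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def write_fasta(sequences: dict[str, str], dest: Union[str, Path, TextIO]) -> None:
    """Write sequences as FASTA with 60-column wrapping."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_fasta(sequences, fh)
        return
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, dest, "fasta")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
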