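"""Assign ChIP-seq peaks to their closest gene and derive dual-bound genes.

A peak is assigned to the single closest gene by edge-to-edge gap (0 when
the peak overlaps the gene body) and retained iff that gap is <= 5 kb, the
filter used to link peaks to genes before intersecting the two TFs' bound
gene lists. TSS proximity is summarized from the peak midpoint, strand-
oriented (negative offsets are upstream of the TSS).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

from .genome import GeneModel, Peak


@dataclass(frozen=True)
class PeakAssignment:
    peak: Peak
    gene_id: str
    distance: int   # edge-to-edge gap, 0 if overlapping
    tss_offset: int  # signed bp from TSS to peak midpoint; negative = upstream


def _gap(peak_start: int, peak_end: int, gene_start: int, gene_end: int) -> int:
    # half-open intervals: gap is 0 when they overlap
    return max(0, gene_start - peak_end, peak_start - gene_end)


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = 5000,
) -> list[PeakAssignment]:
    """Map each peak to its closest gene; keep assignments with gap <= max_distance.

    Ties between equidistant genes break by smaller gene start, then
    lexicographic gene id. Each peak yields at most one assignment.
    """
    if not genes:
        raise ValueError("assign_peaks: empty gene table")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: (g.start, g.gene_id))

    out: list[PeakAssignment] = []
    for p in peaks:
        candidates = by_chrom.get(p.chrom)
        if not candidates:
            continue
        best: tuple[int, int, str, GeneModel] | None = None
        for g in candidates:
            d = _gap(p.start, p.end, g.start, g.end)
            key = (d, g.start, g.gene_id)
            if best is None or key < best[:3]:
                best = (d, g.start, g.gene_id, g)
        assert best is not None
        d, _, _, g = best
        if d <= max_distance:
            offset = p.midpoint - g.tss if g.strand == "+" else g.tss - p.midpoint
            out.append(PeakAssignment(p, g.gene_id, d, offset))
    return out


def dual_bound_genes(
    assignments_tf1: Iterable[PeakAssignment],
    assignments_tf2: Iterable[PeakAssignment],
) -> list[str]:
    """Genes with >= 1 retained assignment from each TF, sorted for determinism."""
    s1 = {a.gene_id for a in assignments_tf1}
    s2 = {a.gene_id for a in assignments_tf2}
    return sorted(s1 & s2)


def tss_proximity_fraction(
    assignments: Sequence[PeakAssignment], window: int = 1000
) -> float:
    """Fraction of retained assignments whose midpoint is within +/- window of the TSS."""
    if not assignments:
        return float("nan")
    hits = sum(1 for a in assignments if abs(a.tss_offset) <= window)
    return hits / len(assignments)


def merge_beds(peak_lists: Sequence[Sequence[Peak]]) -> list[Peak]:
    """Concatenate peak tracks (e.g. per-cell-line files for one TF) and sort."""
    merged = [p for lst in peak_lists for p in lst]
    return sorted(merged, key=lambda p: (p.chrom, p.start, p.end))


def write_assignments(
    assignments: Sequence[PeakAssignment], dest: Union[str, Path, TextIO]
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_assignments(assignments, fh)
        return
    dest.write("chrom\tstart\tend\tgene_id\tdistance\ttss_offset\n")
    for a in assignments:
        dest.write(
            f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t"
            f"{a.gene_id}\t{a.distance}\t{a.tss_offset}\n"
        )
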