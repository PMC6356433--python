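"""Motif matrices and Total Binding Affinity (TBA) over promoter windows.

The TBA of a motif of length L on a promoter window is the sum, over both
strands and every start position with a full L-bp sub-window, of the
likelihood ratio

    prod_j  P(base at offset j | motif column j) / background(base)

so many weak (low-affinity) sites can contribute as much as a single strong
site. Windows containing an ambiguous base (N) contribute zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

from .genome import GeneModel, reverse_complement

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


class PfmParseError(ValueError):
    """Malformed JASPAR PFM record; the message names the motif."""


@dataclass
class MotifMatrix:
    """A position count matrix with its pseudocounted probability form.

    counts is 4 x L over A,C,G,T row order. Probabilities are
    (count + pseudocount) / (column_total + 4 * pseudocount).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise PfmParseError(f"motif {self.name}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise PfmParseError(f"motif {self.name}: empty matrix")
        if (self.counts < 0).any():
            raise PfmParseError(f"motif {self.name}: negative counts")
        if self.pseudocount < 0:
            raise ValueError(f"motif {self.name}: pseudocount must be >= 0")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        totals = self.counts.sum(axis=0)
        return (self.counts + self.pseudocount) / (totals + 4.0 * self.pseudocount)


@dataclass
class PromoterWindow:
    """A promoter sequence oriented 5'->3' relative to its gene.

    For a + strand gene the genomic interval is [TSS - upstream, TSS + downstream);
    for a − strand gene (TSS = end - 1) it is [TSS - downstream + 1, TSS + upstream + 1)
    reverse-complemented, so the TSS sits at relative offset `upstream` in both
    cases. `truncated` flags windows clipped at chromosome bounds.
    """

    gene_id: str
    upstream_offset: int
    downstream_offset: int
    sequence: str
    truncated: bool = False


@dataclass
class TbaScore:
    motif_name: str
    gene_id: str
    tba: float
    log_tba: float
    n_windows: int
    rank: int | None = None
    z_score: float | None = None


def _parse_count_row(text: str) -> list[float]:
    cleaned = text.replace("[", " ").replace("]", " ")
    # tolerate an optional leading base label (A/C/G/T)
    tokens = cleaned.split()
    if tokens and tokens[0].upper() in _BASE_INDEX:
        tokens = tokens[1:]
    return [float(t) for t in tokens]


def read_jaspar_pfm(
    source: Union[str, Path, TextIO], pseudocount: float = 1.0
) -> list[MotifMatrix]:
    """Parse JASPAR PFM text: `>ID name` headers, then four count rows.

    Rows may be labeled ("A [ 3 21 ... ]") or bare; brackets optional.
    Unequal row lengths or negative counts raise :class:`PfmParseError`
    naming the motif.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_jaspar_pfm(fh, pseudocount=pseudocount)
    motifs: list[MotifMatrix] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows
        if name is None:
            return
        if len(rows) != 4:
            raise PfmParseError(f"motif {name}: expected 4 count rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise PfmParseError(f"motif {name}: rows of unequal length {sorted(lengths)}")
        motifs.append(MotifMatrix(name, np.array(rows), pseudocount=pseudocount))
        rows = []

    for line in source:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].strip() or "unnamed"
        else:
            if name is None:
                name = "unnamed"
            try:
                rows.append(_parse_count_row(line))
            except ValueError as exc:
                raise PfmParseError(f"motif {name}: unparsable count row {line!r}") from exc
            if len(rows) == 4:
                flush()
                name = None  # next record brings its own header (or is bare)
    if rows or name is not None:
        flush()
    return motifs


def write_jaspar_pfm(motifs: Iterable[MotifMatrix], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_jaspar_pfm(motifs, fh)
        return
    for m in motifs:
        dest.write(f">{m.name}\n")
        for i, base in enumerate(ALPHABET):
            vals = " ".join(
                str(int(v)) if float(v).is_integer() else repr(v) for v in m.counts[i]
            )
            dest.write(f"{base} [ {vals} ]\n")


def extract_promoter_window(
    gene: GeneModel,
    genome: dict[str, str],
    upstream: int = 756,
    downstream: int = 235,
) -> PromoterWindow:
    """Extract the promoter window around the TSS, strand-oriented.

    The default −756/+235 window (991 bp) mirrors the experimentally mapped
    responsive region of the RhoU promoter. Windows are intersected with
    chromosome bounds and flagged as truncated when clipped.
    """
    if gene.chrom not in genome:
        raise KeyError(f"chromosome {gene.chrom!r} not present in genome")
    chrom_seq = genome[gene.chrom]
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream + 1, gene.tss + upstream + 1
    clipped_lo, clipped_hi = max(0, lo), min(len(chrom_seq), hi)
    seq = chrom_seq[clipped_lo:clipped_hi].upper()
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return PromoterWindow(
        gene_id=gene.gene_id,
        upstream_offset=upstream,
        downstream_offset=downstream,
        sequence=seq,
        truncated=(clipped_lo != lo or clipped_hi != hi),
    )


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> 4."""
    arr = np.full(len(seq), 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def compute_tba(
    window: Union[PromoterWindow, str],
    motif: MotifMatrix,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> TbaScore:
    """Total Binding Affinity of `motif` over `window`, both strands.

    Sub-windows containing N score zero and are excluded from n_windows.
    A motif longer than the window yields TBA 0 with a warning.
    """
    if isinstance(window, PromoterWindow):
        seq, gene_id = window.sequence, window.gene_id
    else:
        seq, gene_id = window, ""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background probabilities must sum to 1")

    L = motif.length
    W = len(seq)
    if L > W:
        warnings.warn(
            f"motif {motif.name} (L={L}) longer than window ({W} bp); TBA set to 0"
        )
        return TbaScore(motif.name, gene_id, 0.0, float("-inf"), 0)

    ratio = motif.probabilities / bg[:, None]           # 4 x L
    ratio_n = np.vstack([ratio, np.zeros((1, L))])      # N row -> product 0
    total = 0.0
    n_windows = 0
    for strand_seq in (seq, reverse_complement(seq)):
        enc = _encode(strand_seq)
        # affinity of each start: product over motif columns of ratio[base, j]
        n_starts = W - L + 1
        idx = np.arange(n_starts)[:, None] + np.arange(L)[None, :]
        vals = ratio_n[enc[idx], np.arange(L)[None, :]]
        aff = vals.prod(axis=1)
        valid = (enc[idx] != 4).all(axis=1)
        total += aff.sum()
        n_windows += int(valid.sum())
    log_tba = math.log(total) if total > 0 else float("-inf")
    return TbaScore(motif.name, gene_id, float(total), log_tba, n_windows)


def _mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def rank_tfs(
    window: PromoterWindow,
    motifs: Sequence[MotifMatrix],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    n_shuffles: int = 0,
    seed: int = 0,
) -> list[TbaScore]:
    """Rank motifs on a promoter by TBA (or shuffle-normalized z-score).

    With n_shuffles = 0 motifs are ranked by log TBA descending (the raw
    ranking used to nominate SP1 on the RhoU promoter). With n_shuffles > 0
    each motif's log TBA is converted to an empirical z-score against
    mononucleotide-preserving shuffles of the window, removing the
    length/information-content bias of raw TBA across motifs. Ties break by
    motif name.
    """
    if not motifs:
        raise ValueError("rank_tfs requires at least one motif")
    scores = [compute_tba(window, m, background) for m in motifs]
    if n_shuffles > 0:
        rng = np.random.default_rng(seed)
        shuffled = [
            _mononucleotide_shuffle(window.sequence, rng) for _ in range(n_shuffles)
        ]
        for sc, m in zip(scores, motifs):
            null = np.array(
                [compute_tba(s, m, background).log_tba for s in shuffled]
            )
            mu, sd = null.mean(), null.std(ddof=1) if n_shuffles > 1 else 0.0
            sc.z_score = (sc.log_tba - mu) / sd if sd > 0 else 0.0
        key = lambda s: (-s.z_score, s.motif_name)
    else:
        key = lambda s: (-s.log_tba, s.motif_name)
    ranked = sorted(scores, key=key)
    for i, sc in enumerate(ranked, start=1):
        sc.rank = i
    return ranked


def write_tba_report(scores: Sequence[TbaScore], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_tba_report(scores, fh)
        return
    dest.write("motif\ttba\tlog_tba\tz\trank\n")
    for s in scores:
        z = "" if s.z_score is None else f"{s.z_score:.6g}"
        dest.write(f"{s.motif_name}\t{s.tba:.10g}\t{s.log_tba:.10g}\t{z}\t{s.rank}\n")
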