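"""Gene sets, Fisher-exact enrichment of the dual-bound list, and the
combined binding signature.

Enrichment of a dual-bound gene list in a curated set is tested one-sided
(hypergeometric upper tail): with universe size N, set size m, dual list
size n and overlap k, p = P(X >= k) for X ~ Hypergeom(N, m, n). The
signature is the union of the dual list's intersections with the two
top-ranking significant sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
from scipy import stats


class GmtParseError(ValueError):
    """Malformed GMT line; the message carries the line number."""


def normalize_gene_id(gene_id: str) -> str:
    return gene_id.strip().upper()


@dataclass
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name}: empty member list")
        self.members = frozenset(normalize_gene_id(m) for m in self.members)


@dataclass
class EnrichmentResult:
    set_name: str
    k: int          # overlap
    m: int          # set size after universe restriction
    n_dual: int     # dual list size after universe restriction
    N: int          # universe size
    odds_ratio: float
    p_value: float
    overlap_percent: float
    significant: bool
    q_value: float | None = None


@dataclass
class Signature:
    name: str
    members: frozenset[str]
    provenance: tuple[str, str]


def read_gmt(source: Union[str, Path, TextIO]) -> list[GeneSet]:
    """Parse GMT (name, description, tab-separated members).

    Duplicate member ids are deduplicated with a warning; lines with fewer
    than 3 fields or no members raise :class:`GmtParseError`.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_gmt(fh)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(source, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GmtParseError(f"line {lineno}: expected >= 3 tab-separated fields")
        name, desc, raw = fields[0], fields[1], [f for f in fields[2:] if f.strip()]
        if not raw:
            raise GmtParseError(f"line {lineno}: gene set {name!r} has no members")
        members = [normalize_gene_id(g) for g in raw]
        if len(set(members)) < len(members):
            warnings.warn(f"gene set {name}: duplicate member ids deduplicated")
        sets.append(GeneSet(name, desc, frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], dest: Union[str, Path, TextIO]) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_gmt(sets, fh)
        return
    for s in sets:
        dest.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def fisher_enrichment(
    dual: Iterable[str],
    gene_set: GeneSet,
    universe: Iterable[str],
    alpha: float = 0.05,
    tail: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment of `dual` in `gene_set` over `universe`.

    Both the dual list and the set are restricted to the universe before
    testing. The default upper tail tests positive enrichment; tail
    "two-sided" is available.
    """
    uni = {normalize_gene_id(g) for g in universe}
    if not uni:
        raise ValueError("fisher_enrichment: empty universe")
    d = {normalize_gene_id(g) for g in dual} & uni
    s = gene_set.members & uni
    N, m, n = len(uni), len(s), len(d)
    k = len(d & s)
    assert 0 <= k <= min(m, n) <= N

    if tail == "greater":
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
    elif tail == "two-sided":
        table = [[k, m - k], [n - k, N - m - n + k]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p = min(p, 1.0)

    a, b, c, dd = k, m - k, n - k, N - m - n + k
    if a * dd == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * dd) / (b * c)
    overlap_percent = 100.0 * k / m if m > 0 else float("nan")
    return EnrichmentResult(
        set_name=gene_set.name, k=k, m=m, n_dual=n, N=N,
        odds_ratio=odds, p_value=p, overlap_percent=overlap_percent,
        significant=p < alpha,
    )


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q.tolist()


class SelectionError(RuntimeError):
    pass


def rank_and_select(
    results: Sequence[EnrichmentResult], k_top: int = 2, alpha: float = 0.05
) -> tuple[str, str] | tuple[str, ...]:
    """Pick the k_top most significant sets by raw p (ties: larger overlap
    percentage, then name). BH q-values are attached for transparency but do
    not drive selection. Raises :class:`SelectionError` when fewer than
    k_top sets reach p < alpha.
    """
    qs = bh_qvalues([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
    ranked = sorted(results, key=lambda r: (r.p_value, -r.overlap_percent, r.set_name))
    significant = [r for r in ranked if r.p_value < alpha]
    if len(significant) < k_top:
        raise SelectionError(
            f"only {len(significant)} gene sets reach p < {alpha}; "
            f"{k_top} required — review universe/alpha or input sets"
        )
    return tuple(r.set_name for r in significant[:k_top])


def build_signature(
    dual: Iterable[str],
    set_a: GeneSet,
    set_b: GeneSet,
    name: str = "SP1-S3",
) -> Signature:
    """Combined signature: (dual ∩ A) ∪ (dual ∩ B).

    With per-set intersections of sizes |dual∩A| and |dual∩B| sharing j
    genes, the signature has |dual∩A| + |dual∩B| − j members.
    """
    d = {normalize_gene_id(g) for g in dual}
    members = (d & set_a.members) | (d & set_b.members)
    return Signature(name=name, members=frozenset(members),
                     provenance=tuple(sorted((set_a.name, set_b.name))))


def write_enrichment_table(
    results: Sequence[EnrichmentResult], dest: Union[str, Path, TextIO]
) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            write_enrichment_table(results, fh)
        return
    dest.write("set\tk\tm\tn_dual\tN\todds_ratio\tp_value\tq_value\t"
               "overlap_percent\tsignificant\n")
    for r in results:
        q = "" if r.q_value is None else f"{r.q_value:.6g}"
        dest.write(
            f"{r.set_name}\t{r.k}\t{r.m}\t{r.n_dual}\t{r.N}\t{r.odds_ratio:.6g}\t"
            f"{r.p_value:.6g}\t{q}\t{r.overlap_percent:.4f}\t{int(r.significant)}\n"
        )
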