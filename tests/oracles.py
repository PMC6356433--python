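"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a statistic by direct enumeration, deliberately
sharing no code with the implementation it checks.
"""

from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def tba_bruteforce(seq: str, probabilities, background) -> float:
    """Materialize every sub-window on both strands and sum its likelihood
    ratio; windows containing N contribute zero."""
    L = probabilities.shape[1]
    total = 0.0
    for strand in (seq, revcomp(seq)):
        for i in range(len(strand) - L + 1):
            sub = strand[i : i + L]
            if "N" in sub:
                continue
            prod = 1.0
            for j, base in enumerate(sub):
                prod *= probabilities[_IDX[base], j] / background[_IDX[base]]
            total += prod
    return total


def hypergeom_upper_tail(k: int, N: int, m: int, n: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeom(N, m, n) via rational enumeration."""
    total = Fraction(0)
    denom = comb(N, n)
    for x in range(k, min(m, n) + 1):
        total += Fraction(comb(m, x) * comb(N - m, n - x), denom)
    return float(total)


def closest_gene_bruteforce(peak, genes):
    """All-pairs scan for the closest gene by edge-to-edge gap, with the
    tie-break (distance, gene start, gene id)."""
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        gap = max(0, g.start - peak.end, peak.start - g.end)
        key = (gap, g.start, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g)
    if best is None:
        return None, None
    return best[1], best[0][0]


def km_by_hand(times, events):
    """Product-limit estimate as a list of (event_time, S) via direct tabulation."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    out = []
    s = 1.0
    for et in event_times:
        n_at_risk = sum(1 for t, _ in pairs if t >= et)
        d = sum(1 for t, e in pairs if t == et and e == 1)
        s *= 1.0 - d / n_at_risk
        out.append((et, s))
    return out


def logrank_by_hand(times, events, in_group1):
    """Per-event-time tabulation of the two-sample log-rank chi-square."""
    data = list(zip(times, events, in_group1))
    event_times = sorted({t for t, e, _ in data if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = [(t, e, g1) for t, e, g1 in data if t >= et]
        n = len(at_risk)
        n1 = sum(1 for _, _, g1 in at_risk if g1)
        d = sum(1 for t, e, _ in data if t == et and e == 1)
        d1 = sum(1 for t, e, g1 in data if t == et and e == 1 and g1)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (o_minus_e**2) / var if var > 0 else 0.0
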