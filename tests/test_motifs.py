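"""Motif parsing, promoter-window extraction and Total Binding Affinity."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bindsig.genome import GeneModel, reverse_complement
from bindsig.motifs import (
    MotifMatrix,
    PfmParseError,
    compute_tba,
    extract_promoter_window,
    rank_tfs,
    read_jaspar_pfm,
    write_jaspar_pfm,
)

from oracles import revcomp, tba_bruteforce

UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


def _random_motif(rng, L, name="M"):
    counts = rng.integers(0, 20, size=(4, L)).astype(float)
    counts[rng.integers(4), :] += 1  # avoid all-zero columns
    return MotifMatrix(name, counts, pseudocount=1.0)


def _random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


class TestJasparParsing:
    def test_uniform_counts_give_uniform_probabilities(self):
        text = ">M1 TEST\nA [ 1 1 1 ]\nC [ 1 1 1 ]\nG [ 1 1 1 ]\nT [ 1 1 1 ]\n"
        (m,) = read_jaspar_pfm(io.StringIO(text), pseudocount=0.0)
        assert np.allclose(m.probabilities, 0.25)

    def test_pseudocount_normalization(self):
        # column (8,0,0,0) with pseudocount 1: P(A) = 9/12, P(C) = 1/12
        text = ">M1\n8\n0\n0\n0\n"
        (m,) = read_jaspar_pfm(io.StringIO(text), pseudocount=1.0)
        assert m.probabilities[0, 0] == pytest.approx(9 / 12)
        assert m.probabilities[1, 0] == pytest.approx(1 / 12)

    def test_bare_unlabeled_rows_and_multiple_records(self):
        text = ">A\n1 2\n3 4\n5 6\n7 8\n>B\nA [ 1 ]\nC [ 2 ]\nG [ 3 ]\nT [ 4 ]\n"
        motifs = read_jaspar_pfm(io.StringIO(text))
        assert [m.name for m in motifs] == ["A", "B"]
        assert motifs[0].counts[3, 1] == 8

    def test_unequal_row_lengths_rejected_with_name(self):
        text = ">BAD\n1 2 3\n1 2\n1 2 3\n1 2 3\n"
        with pytest.raises(PfmParseError, match="BAD"):
            read_jaspar_pfm(io.StringIO(text))

    def test_negative_counts_rejected(self):
        text = ">NEG\n1 -2\n1 1\n1 1\n1 1\n"
        with pytest.raises(PfmParseError, match="NEG"):
            read_jaspar_pfm(io.StringIO(text))

    def test_write_read_round_trip_preserves_counts(self, rng):
        motifs = [_random_motif(rng, L, name=f"M{L}") for L in (1, 4, 9)]
        buf = io.StringIO()
        write_jaspar_pfm(motifs, buf)
        back = read_jaspar_pfm(io.StringIO(buf.getvalue()))
        assert [m.name for m in back] == [m.name for m in motifs]
        for a, b in zip(motifs, back):
            np.testing.assert_array_equal(a.counts, b.counts)


class TestPromoterWindow:
    def _genome(self, rng, n=5000):
        return {"chr1": _random_seq(rng, n)}

    def test_default_window_length_is_991(self, rng):
        genome = self._genome(rng)
        gene = GeneModel("G1", "chr1", 2000, 3000, "+")
        w = extract_promoter_window(gene, genome, upstream=756, downstream=235)
        assert len(w.sequence) == 756 + 235 == 991
        assert not w.truncated

    def test_zero_upstream_one_downstream_is_tss_base(self, rng):
        genome = self._genome(rng)
        gene = GeneModel("G1", "chr1", 2000, 3000, "+")
        w = extract_promoter_window(gene, genome, upstream=0, downstream=1)
        assert w.sequence == genome["chr1"][2000]

    def test_minus_strand_is_reverse_complement_of_mirror(self, rng):
        # On a genome and its reverse complement, the window of a − strand
        # gene must equal the + strand extraction at mirrored coordinates.
        n = 4000
        seq = _random_seq(rng, n)
        genome_fwd = {"chr1": seq}
        genome_rev = {"chr1": reverse_complement(seq)}
        start, end = 1500, 2200
        gene_minus = GeneModel("G", "chr1", start, end, "-")
        mirrored = GeneModel("G", "chr1", n - end, n - start, "+")
        w_minus = extract_promoter_window(gene_minus, genome_fwd, 300, 100)
        w_plus = extract_promoter_window(mirrored, genome_rev, 300, 100)
        assert w_minus.sequence == w_plus.sequence

    def test_truncation_flagged_at_chromosome_edge(self, rng):
        genome = self._genome(rng, 500)
        gene = GeneModel("G1", "chr1", 100, 400, "+")
        w = extract_promoter_window(gene, genome, upstream=756, downstream=235)
        assert w.truncated
        assert len(w.sequence) < 991

    def test_unknown_chromosome_raises(self, rng):
        gene = GeneModel("G1", "chrX", 100, 400, "+")
        with pytest.raises(KeyError, match="chrX"):
            extract_promoter_window(gene, {"chr1": "ACGT" * 100})


class TestTba:
    def test_background_matching_motif_scores_window_count(self):
        # every window ratio is 1, so TBA = 2 * (|window| - L + 1)
        motif = MotifMatrix("FLAT", np.ones((4, 3)), pseudocount=0.0)
        seq = "ACGTACGTAC"
        score = compute_tba(seq, motif, UNIFORM_BG)
        assert score.tba == pytest.approx(2 * (len(seq) - 3 + 1))
        assert score.n_windows == 2 * (len(seq) - 3 + 1)

    def test_matches_bruteforce_on_acgtac(self, rng):
        motif = _random_motif(rng, 2)
        score = compute_tba("ACGTAC", motif, UNIFORM_BG)
        expected = tba_bruteforce("ACGTAC", motif.probabilities, UNIFORM_BG)
        assert score.tba == pytest.approx(expected, rel=1e-12)

    def test_strand_reversal_invariance(self, rng):
        for _ in range(20):
            seq = _random_seq(rng, rng.integers(10, 40))
            motif = _random_motif(rng, rng.integers(2, 7))
            a = compute_tba(seq, motif, UNIFORM_BG).tba
            b = compute_tba(revcomp(seq), motif, UNIFORM_BG).tba
            assert a == pytest.approx(b, rel=1e-12)

    def test_n_windows_skipped(self, rng):
        motif = _random_motif(rng, 3)
        score = compute_tba("ACNTACGT", motif, UNIFORM_BG)
        # windows covering the N (positions 0..2 on each strand) score 0
        clean = compute_tba("TACGT", motif, UNIFORM_BG)
        assert score.tba == pytest.approx(clean.tba, rel=1e-12)
        assert score.n_windows == clean.n_windows

    def test_additivity_over_split(self, rng):
        # TBA(whole) = TBA(left) + TBA(right) + straddling windows
        seq = _random_seq(rng, 30)
        motif = _random_motif(rng, 4)
        L = 4
        cut = 13
        whole = compute_tba(seq, motif, UNIFORM_BG).tba
        left = compute_tba(seq[:cut], motif, UNIFORM_BG).tba
        right = compute_tba(seq[cut:], motif, UNIFORM_BG).tba
        straddle = tba_bruteforce(seq[cut - L + 1 : cut + L - 1],
                                  motif.probabilities, np.array(UNIFORM_BG))
        assert whole == pytest.approx(left + right + straddle, rel=1e-10)

    def test_monotonicity_in_match_probability(self):
        # boosting the probability of the bases of a present match never
        # decreases TBA of a window containing that match
        base_counts = np.ones((4, 3))
        seq = "TTACGTT"  # contains ACG
        weak = MotifMatrix("W", base_counts.copy(), pseudocount=0.0)
        boosted = base_counts.copy()
        boosted[0, 0] += 50  # A at column 0
        boosted[1, 1] += 50  # C at column 1
        boosted[2, 2] += 50  # G at column 2
        strong = MotifMatrix("S", boosted, pseudocount=0.0)
        assert compute_tba(seq, strong, UNIFORM_BG).tba >= \
            compute_tba(seq, weak, UNIFORM_BG).tba

    def test_motif_longer_than_window_warns_and_zeroes(self, rng):
        motif = _random_motif(rng, 10)
        with pytest.warns(UserWarning, match="longer than window"):
            score = compute_tba("ACGT", motif, UNIFORM_BG)
        assert score.tba == 0.0
        assert score.n_windows == 0


class TestRankTfs:
    def _window(self, seq):
        from bindsig.motifs import PromoterWindow

        return PromoterWindow("G", 0, len(seq), seq)

    def test_single_motif_ranks_first(self, rng):
        w = self._window(_random_seq(rng, 50))
        (only,) = rank_tfs(w, [_random_motif(rng, 4)])
        assert only.rank == 1

    def test_planted_sites_outrank_unrelated_motif(self, rng):
        site = "ACGTGC"
        seq = ("TT" + site) * 10  # 10 perfect sites for A
        a_counts = np.full((4, 6), 0.0)
        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for j, b in enumerate(site):
            a_counts[idx[b], j] = 20
        motif_a = MotifMatrix("A", a_counts, pseudocount=0.5)
        # unrelated motif of the same length prefers a site absent from seq
        b_counts = np.full((4, 6), 0.0)
        for j, b in enumerate("CCCCCC"):
            b_counts[idx[b], j] = 20
        motif_b = MotifMatrix("B", b_counts, pseudocount=0.5)
        from bindsig.motifs import PromoterWindow

        w = PromoterWindow("G", 0, len(seq), seq)
        raw = rank_tfs(w, [motif_b, motif_a], n_shuffles=0)
        assert raw[0].motif_name == "A"
        normalized = rank_tfs(w, [motif_b, motif_a], n_shuffles=25, seed=7)
        assert normalized[0].motif_name == "A"

    def test_ranking_invariant_to_input_order(self, rng):
        w = self._window(_random_seq(rng, 60))
        motifs = [_random_motif(rng, L, name=f"M{i}") for i, L in enumerate((3, 4, 5, 6))]
        fwd = rank_tfs(w, motifs)
        rev = rank_tfs(w, motifs[::-1])
        assert [s.motif_name for s in fwd] == [s.motif_name for s in rev]

    def test_requires_a_motif(self, rng):
        with pytest.raises(ValueError):
            rank_tfs(self._window("ACGT"), [])
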