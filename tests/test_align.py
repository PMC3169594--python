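import itertools
import math
from dataclasses import replace

import numpy as np
import pytest

import oracles
from conftest import random_dna
from tm1kit.align import (GLOBAL_DEFAULT, SEED_SEARCH, TIR_DELINEATION,
                          GlobalScoringScheme, LocalScoringScheme,
                          alignment_score, global_align_free_end,
                          karlin_lambda, mask_low_complexity, percent_identity,
                          seeded_local_search, smith_waterman)
from tm1kit.seqio import reverse_complement


class TestScoringScheme:
    def test_printed_presets(self):
        assert (SEED_SEARCH.word_size, SEED_SEARCH.match, SEED_SEARCH.mismatch,
                SEED_SEARCH.gap_open, SEED_SEARCH.gap_extend,
                SEED_SEARCH.e_max) == (7, 1, -3, 4, 2, 10.0)
        assert (TIR_DELINEATION.word_size, TIR_DELINEATION.mismatch,
                TIR_DELINEATION.gap_open, TIR_DELINEATION.gapped_x_dropoff) \
            == (11, -2, 5, 50.0)

    def test_positive_expected_score_rejected(self):
        with pytest.raises(ValueError):
            LocalScoringScheme(match=5, mismatch=-1)

    def test_karlin_lambda_solves_identity(self):
        for m, mm in [(1, -3), (1, -2), (2, -3)]:
            lam = karlin_lambda(m, mm)
            val = (4 * math.exp(lam * m) + 12 * math.exp(lam * mm)) / 16
            assert val == pytest.approx(1.0, abs=1e-9)

    def test_evalue_strictly_decreasing_in_score(self):
        es = [SEED_SEARCH.evalue(s, 38, 10_000) for s in range(7, 40)]
        assert all(a > b for a, b in zip(es, es[1:]))


class TestMaskLowComplexity:
    def test_dinucleotide_repeat_fully_masked(self):
        seq = "AC" * 10
        mask = mask_low_complexity(seq)
        # hand check: every 16 bp window of ACAC... has triplet counts 7+7,
        # raw score 2*21 = 42, 42/13 = 3.23 > 2
        assert oracles.dust_window_score(seq[:16]) > 2.0
        assert mask.all()

    def test_random_sequence_mostly_unmasked(self, rng):
        masked = 0
        for _ in range(20):
            seq = random_dna(rng, 50)
            m = mask_low_complexity(seq)
            expected = any(oracles.dust_window_score(seq[i:i + 16]) > 2.0
                           for i in range(len(seq) - 15))
            assert m.any() == expected
            masked += m.mean()
        assert masked / 20 < 0.10

    def test_shorter_than_window_all_false(self):
        assert not mask_low_complexity("ACGTACGT", window=16).any()

    def test_window_below_eight_rejected(self):
        with pytest.raises(ValueError):
            mask_low_complexity("ACGTACGTACGT", window=4)


class TestSeededLocalSearch:
    def test_perfect_substring_single_hit(self, rng):
        subject = random_dna(rng, 2000)
        query = subject[700:738]
        hits = seeded_local_search(query, subject, SEED_SEARCH,
                                   search_space_n=100_000)
        assert len(hits) == 1
        h = hits[0]
        assert h.raw_score == 38          # length x match with match = 1
        assert h.identity_pct == 100.0
        assert (h.subject_interval.start, h.subject_interval.end) == (700, 738)
        assert h.strand == "+"

    def test_reverse_complement_hit_on_minus_strand(self, rng):
        subject = random_dna(rng, 1500)
        query = subject[400:438]
        planted = subject[:900] + reverse_complement(query) + subject[900:938]
        hits = seeded_local_search(query, planted, SEED_SEARCH,
                                   search_space_n=100_000)
        by_strand = {h.strand: h for h in hits}
        assert "-" in by_strand
        h = by_strand["-"]
        assert h.raw_score == 38
        assert (h.subject_interval.start, h.subject_interval.end) == (900, 938)

    def test_query_shorter_than_word_errors(self):
        with pytest.raises(ValueError):
            seeded_local_search("ACGT", "ACGTACGTACGT", SEED_SEARCH)

    def test_score_recomputable_from_aligned_strings(self, rng):
        subject = random_dna(rng, 800)
        query = subject[100:160]
        hits = seeded_local_search(query, subject, SEED_SEARCH)
        for h in hits:
            assert alignment_score(h.aligned_query, h.aligned_subject,
                                   SEED_SEARCH) == h.raw_score

    def test_best_score_matches_smith_waterman_oracle(self, rng):
        """Core oracle equivalence: on random pairs sharing an exact word,
        the best seeded hit equals the exhaustive Smith-Waterman optimum."""
        scheme = replace(SEED_SEARCH, mask_low_complexity=False)
        checked = 0
        trials = 0
        while checked < 200 and trials < 2000:
            trials += 1
            n = int(rng.integers(80, 201))
            a = random_dna(rng, n)
            b = random_dna(rng, n)
            # plant partial similarity in half the cases so scores vary
            if trials % 2:
                k = int(rng.integers(10, 40))
                p = int(rng.integers(0, n - k))
                q = int(rng.integers(0, n - k))
                b = b[:q] + a[p:p + k] + b[q + k:]
            words_a = {a[i:i + 7] for i in range(len(a) - 6)}
            words_b = {b[i:i + 7] for i in range(len(b) - 6)}
            if not (words_a & words_b):
                continue
            checked += 1
            hits = seeded_local_search(a, b, scheme, search_space_n=None)
            best = max((h.raw_score for h in hits if h.strand == "+"), default=0)
            oracle = oracles.sw_score(a, b, scheme.match, scheme.mismatch,
                                      scheme.gap_open, scheme.gap_extend)
            assert best == oracle, (a, b)
        assert checked == 200

    def test_strand_symmetry(self, rng):
        subject = random_dna(rng, 600)
        query = subject[200:260]
        fwd = seeded_local_search(query, subject, SEED_SEARCH)
        rev = seeded_local_search(query, reverse_complement(subject), SEED_SEARCH)
        n = len(subject)
        fwd_set = {(h.strand, h.subject_interval.start, h.subject_interval.end,
                    h.raw_score) for h in fwd}
        rev_set = {("+" if h.strand == "-" else "-",
                    n - h.subject_interval.end, n - h.subject_interval.start,
                    h.raw_score) for h in rev}
        assert fwd_set == rev_set


def _enumerate_free_end_alignments(a: str, b: str):
    """All global alignments of two tiny strings, scored with free end gaps
    (exhaustive recursion; oracle for the 'enumerate all alignments' case)."""
    best = [float("-inf")]
    p = GLOBAL_DEFAULT

    def score(cols):
        # substitution columns plus gap runs; a maximal gap run in one
        # sequence is cost-free iff it touches the alignment start or end
        total = 0.0
        n = len(cols)
        for x, y in cols:
            if x != "-" and y != "-":
                total += p.match if x == y else p.mismatch
        for which in (0, 1):
            k = 0
            while k < n:
                if cols[k][which] == "-":
                    start = k
                    while k < n and cols[k][which] == "-":
                        k += 1
                    if start != 0 and k != n:
                        total -= p.gap_open + (k - start) * p.gap_extend
                else:
                    k += 1
        return total

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score(cols))
            return
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])

    rec(0, 0, [])
    return best[0]


class TestGlobalAlignFreeEnd:
    def test_identical_strings(self):
        aln = global_align_free_end("ACGTACGTAC", "ACGTACGTAC")
        assert aln.identity_pct == 100.0
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_insertion_pair_matches_enumeration(self):
        aln = global_align_free_end("ACGT", "ACGGT")
        assert aln.score == _enumerate_free_end_alignments("ACGT", "ACGGT")

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            global_align_free_end("", "ACGT")

    def test_score_matches_plain_dp_oracle(self, rng):
        p = GLOBAL_DEFAULT
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 41)))
            b = random_dna(rng, int(rng.integers(1, 41)))
            got = global_align_free_end(a, b).score
            want = oracles.global_free_end_score(
                a, b, p.match, p.mismatch, p.gap_open, p.gap_extend)
            assert got == want, (a, b)

    def test_ungapping_recovers_inputs(self, rng):
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(5, 60)))
            b = random_dna(rng, int(rng.integers(5, 60)))
            aln = global_align_free_end(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_deterministic(self, rng):
        a, b = random_dna(rng, 50), random_dna(rng, 55)
        r1 = global_align_free_end(a, b)
        r2 = global_align_free_end(a, b)
        assert r1 == r2


class TestPercentIdentity:
    def test_identical(self):
        assert percent_identity(("ACGTACGTAC", "ACGTACGTAC")) == 100.0

    def test_nine_matches_one_mismatch(self):
        assert percent_identity(("ACGTACGTAC", "ACGTACGTAT")) == 90.0

    def test_end_gaps_excluded_by_default(self):
        assert percent_identity(("ACGT--", "ACGTGG")) == 100.0
        assert percent_identity(("ACGT--", "ACGTGG"),
                                exclude_end_gaps=False) == pytest.approx(400 / 6)

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(20):
            a = random_dna(rng, 40)
            b = random_dna(rng, 44)
            ab = global_align_free_end(a, b).identity_pct
            ba = global_align_free_end(b, a).identity_pct
            assert ab == pytest.approx(ba, abs=1e-9)

    def test_zero_columns_errors(self):
        with pytest.raises(ValueError):
            percent_identity(("AA--", "--TT"))


class TestSmithWaterman:
    def test_matches_plain_oracle_on_random_pairs(self, rng):
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(10, 80)))
            b = random_dna(rng, int(rng.integers(10, 80)))
            got = smith_waterman(a, b, SEED_SEARCH)[0]
            want = oracles.sw_score(a, b, SEED_SEARCH.match, SEED_SEARCH.mismatch,
                                    SEED_SEARCH.gap_open, SEED_SEARCH.gap_extend)
            assert got == want
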