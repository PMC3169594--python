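import numpy as np
import pytest

import oracles
from conftest import random_dna
from tm1kit.classify import (HAIRPIN_CONSENSUS, ClassifyThresholds,
                             CoverageMap, ElementFeatures, classify_element,
                             detect_internal_ir, detect_nested_insertions,
                             reference_similarity, scan_histone_hairpin,
                             scan_orfs)
from tm1kit.seqio import SequenceRecord, reverse_complement
from tm1kit.simulate import (MutationModel, Tm1Grammar, build_element,
                             build_reference, mutate)


class TestHairpinScan:
    def test_planted_perfect_stem_loop(self, rng):
        hp = "GGCTCT" + "TTTC" + "AGAGCC"   # 6 bp stem, 4 nt loop
        seq = random_dna(rng, 120) + hp + random_dna(rng, 120)
        hits = scan_histone_hairpin(seq)
        assert any(h.position == 120 and h.stem_mismatches == 0
                   and h.stem_length >= 6 for h in hits)
        # profile rescoring makes the planted hairpin the top hit even when
        # a chance stem-loop folds elsewhere
        prof = scan_histone_hairpin(seq, profile=HAIRPIN_CONSENSUS)
        assert prof and prof[0].position == 120

    def test_counts_match_brute_force_on_random(self, rng):
        for _ in range(5):
            seq = random_dna(rng, 300)
            got = {(h.position, h.stem_length, h.loop_length,
                    h.stem_mismatches) for h in
                   scan_histone_hairpin(seq, max_mismatch=1)}
            want = set(oracles.brute_force_hairpins(seq, 6, 10, 3, 6, 1))
            assert got == want

    def test_reverse_complement_mirrors_hit(self, rng):
        hp = "GGCTCT" + "TTTC" + "AGAGCC"
        seq = random_dna(rng, 80) + hp + random_dna(rng, 80)
        fwd = scan_histone_hairpin(seq)
        rev = scan_histone_hairpin(reverse_complement(seq))
        n = len(seq)
        fwd_pos = {(h.position, h.window_length) for h in fwd}
        rev_pos = {(n - h.position - h.window_length, h.window_length)
                   for h in rev}
        assert fwd_pos == rev_pos

    def test_profile_rescoring_rejects_unrelated_stem_loops(self, rng):
        # a random stem-loop folds but does not resemble the histone hairpin
        arm = random_dna(rng, 8)
        sl = arm + "TTTT" + reverse_complement(arm)
        seq = random_dna(rng, 100) + sl + random_dna(rng, 100)
        assert scan_histone_hairpin(seq)  # structural scan sees it
        if sum(a != b for a, b in zip(sl, HAIRPIN_CONSENSUS)) > 4:
            assert not scan_histone_hairpin(seq, profile=HAIRPIN_CONSENSUS)


class TestInternalIr:
    def test_planted_sixty_bp_arms(self, rng):
        x = random_dna(rng, 60)
        payload = x + random_dna(rng, 150) + reverse_complement(x)
        ir = detect_internal_ir(payload)
        assert ir is not None
        a, b = ir
        assert a.start <= 2 and a.end >= 55
        assert b.end >= len(payload) - 2

    def test_random_payload_none(self, rng):
        for _ in range(5):
            assert detect_internal_ir(random_dna(rng, 500)) is None

    def test_invariant_under_reverse_complement(self, rng):
        x = random_dna(rng, 60)
        payload = random_dna(rng, 40) + x + random_dna(rng, 150) \
            + reverse_complement(x) + random_dna(rng, 40)
        assert (detect_internal_ir(payload) is None) == \
            (detect_internal_ir(reverse_complement(payload)) is None)


class TestScanOrfs:
    def test_start_plus_thirty_codons(self, rng):
        codons = []
        r = np.random.default_rng(5)
        while len(codons) < 30:
            c = random_dna(r, 3)
            if c not in ("TAA", "TAG", "TGA", "ATG"):
                codons.append(c)
        seq = "CC" + "ATG" + "".join(codons) + "TGA" + "CC"
        orfs = [o for o in scan_orfs(seq, min_aa=10) if o.frame > 0]
        assert len(orfs) == 1
        assert orfs[0].length_aa == 31

    def test_no_start_no_orf(self):
        # stop-free frame without ATG yields nothing (start required)
        seq = "GGA" * 100
        assert scan_orfs(seq, min_aa=5) == []

    def test_counts_match_brute_force_on_random_kb(self, rng):
        seq = random_dna(rng, 1000)
        got = sorted((("+" if o.frame > 0 else "-"), abs(o.frame) - 1,
                      o.length_aa) for o in scan_orfs(seq, min_aa=20))
        want = sorted((s, f, aa) for s, f, _start, aa in
                      oracles.brute_force_orfs(seq, 20))
        assert got == want


class TestReferenceSimilarity:
    def test_identical_query_full_coverage(self, rng):
        ref, regions = build_reference(rng)
        cov = reference_similarity(ref.residues, ref, regions)
        assert cov.total_fraction > 0.99
        assert all(f > 0.99 for f in cov.region_fractions.values())

    def test_middle_third_deletion_leaves_gap(self, rng):
        ref, _ = build_reference(rng)
        n = len(ref)
        query = ref.residues[:n // 3] + ref.residues[2 * n // 3:]
        regions = {"first": (0, n // 3), "middle": (n // 3, 2 * n // 3),
                   "last": (2 * n // 3, n)}
        cov = reference_similarity(query, ref, regions)
        assert cov.total_fraction == pytest.approx(2 / 3, abs=0.03)
        assert cov.region_fractions["middle"] < 0.05
        assert cov.region_fractions["first"] > 0.95
        assert cov.region_fractions["last"] > 0.95

    def test_three_prime_fragment_leaves_mule_uncovered(self, rng):
        ref, regions = build_reference(rng)
        query = ref.residues[1600:2100]       # 3' of the MULE region
        cov = reference_similarity(query, ref, regions)
        # short chance word hits can dust the domain with a few percent of
        # nominal coverage; the classifier's absence threshold is 0.1
        assert cov.mule_fraction < 0.1
        assert cov.region_fractions["3prime"] > 0.5


def _features(internal_length=400, hairpins=(), ir=None, cov=None,
              d=False):
    return ElementFeatures(internal_length=internal_length,
                           hairpin_hits=list(hairpins), internal_ir=ir,
                           orfs=[], coverage=cov, motif_d_present=d)


class TestClassifyRules:
    def test_full_reference_interior_is_autonomous(self):
        cov = CoverageMap("ref", 0.95, {"MULE_domain": 0.9, "3prime": 1.0}, 0.9)
        assert classify_element(_features(cov=cov)).label == "Tm1-A"

    def test_patch_without_mule_is_deletion_derivative(self):
        cov = CoverageMap("ref", 0.15, {"MULE_domain": 0.0, "3prime": 0.5}, 0.0)
        assert classify_element(_features(cov=cov)).label == "Tm1-D"

    def test_hairpin_beats_internal_ir(self, rng):
        hits = scan_histone_hairpin(
            random_dna(rng, 50) + HAIRPIN_CONSENSUS + random_dna(rng, 50))
        from tm1kit.seqio import GenomicInterval
        ir = (GenomicInterval("i", 0, 60), GenomicInterval("i", 300, 360, "-"))
        lab = classify_element(_features(hairpins=hits, ir=ir))
        assert lab.label == "Tm1-HH"

    def test_short_interior_with_ir_is_mite_like(self):
        from tm1kit.seqio import GenomicInterval
        ir = (GenomicInterval("i", 0, 60), GenomicInterval("i", 240, 300, "-"))
        assert classify_element(_features(internal_length=300, ir=ir)).label \
            == "Tm1-ML"

    def test_long_interior_with_ir_is_other(self):
        from tm1kit.seqio import GenomicInterval
        ir = (GenomicInterval("i", 0, 60), GenomicInterval("i", 800, 860, "-"))
        assert classify_element(_features(internal_length=900, ir=ir)).label \
            == "other"

    def test_every_element_gets_exactly_one_label(self, rng):
        ref, regions = build_reference(rng)
        g = Tm1Grammar()
        for cls in ("Tm1-A", "Tm1-D", "Tm1-HH", "Tm1-ML", "other"):
            elem, _ = build_element(g, cls, rng, ref)
            lab = classify_element(_features())
            assert lab.label in {"Tm1-A", "Tm1-D", "Tm1-HH", "Tm1-ML", "other"}
            assert lab.evidence

    def test_classifier_accuracy_on_diverged_planted_features(self, rng):
        """>= 0.95 class accuracy over 200 planted elements at 5% divergence,
        classifying from each element's own annotated features."""
        from tm1kit.pipeline import classify_elements
        from tm1kit.tir import annotate_element_window
        from tm1kit.model import build_element_record

        g = Tm1Grammar()
        mm = MutationModel(substitution_rate=0.05)
        ref, regions = build_reference(rng)
        classes = ["Tm1-A", "Tm1-D", "Tm1-HH", "Tm1-ML", "other"]
        ok = total = 0
        k = 0
        while total < 200:
            cls = classes[k % len(classes)]
            k += 1
            elem, _ = build_element(g, cls, rng, ref)
            window = random_dna(rng, 120) + mutate(elem, mm, rng) \
                + random_dna(rng, 120)
            ann = annotate_element_window(window)
            if ann is None:
                continue
            rec = build_element_record("c", 0, ann)
            classify_elements([rec], ref, regions)
            total += 1
            ok += rec.class_label.label == cls
        assert ok / total >= 0.95


class TestNestedInsertions:
    def _exemplar_pair(self, rng, insert_len=900, tsd_len=7, with_tsd=True):
        exemplar = random_dna(rng, 1100)
        p = 500
        arm = random_dna(rng, 80)
        insert = arm + random_dna(rng, insert_len - 160) + reverse_complement(arm)
        # pin the insert's terminal bases so the duplication cannot extend
        # into a longer chance direct repeat
        bases = "ACGT"
        first = bases[(bases.index(exemplar[p + tsd_len]) + 1) % 4]
        last = bases[(bases.index(exemplar[p - 1]) + 1) % 4]
        insert = first + insert[1:-1] + last
        tsd = exemplar[p:p + tsd_len] if with_tsd else ""
        element = exemplar[:p + len(tsd)] + insert + exemplar[p:] if with_tsd \
            else exemplar[:p] + insert + exemplar[p:]
        return element, exemplar, insert

    def test_insertion_with_seven_bp_tsd(self, rng):
        element, exemplar, insert = self._exemplar_pair(rng)
        found = detect_nested_insertions(element, exemplar)
        assert len(found) == 1
        ins = found[0]
        assert abs(ins.interval.length - len(insert)) <= 10
        assert ins.own_tsd is not None
        assert ins.own_tsd.length == 7
        assert ins.has_internal_ir

    def test_unchanged_exemplar_no_insertions(self, rng):
        exemplar = random_dna(rng, 1000)
        assert detect_nested_insertions(exemplar, exemplar) == []

    def test_insertion_without_tsd_reported_with_none(self, rng):
        element, exemplar, insert = self._exemplar_pair(rng, with_tsd=False)
        found = detect_nested_insertions(element, exemplar)
        assert len(found) == 1
        assert found[0].own_tsd is None
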