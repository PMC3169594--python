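"""Element classification from internal-sequence features.

Classes follow the family's taxonomy: a putative autonomous element
(``Tm1-A``, transposase-coding interior), deletion derivatives of it
(``Tm1-D``, similarity patches 3' of the transposase's MULE domain with the
domain itself lost), histone-hairpin carriers (``Tm1-HH``), MITE-like
elements (``Tm1-ML``, short with an internal inverted repeat and no Motif D),
and ``other``.  Autonomy is called by coverage against a user-supplied
reference interior rather than de novo gene prediction, which keeps the call
deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .align import (SEED_SEARCH, GlobalScoringScheme, LocalScoringScheme,
                    global_align_free_end, seeded_local_search)
from .seqio import GenomicInterval, SequenceRecord, reverse_complement
from .tsd import TsdCall

#: Canonical metazoan histone stem-loop (6 bp stem, 4 nt loop) used as the
#: default rescoring profile; the structural scan alone is not specific
#: enough to drive classification on short payloads.
HAIRPIN_CONSENSUS = "GGCTCTTTTCAGAGCC"

#: Scheme for payload self-comparison (internal inverted repeats): word-7
#: seeding with +1/-2 scoring, a middle ground that keeps a diverged repeat
#: arm in one local alignment (a -3 penalty fragments it) without letting
#: the two arms of the repeat chain through the spacer into a single
#: self-spanning alignment (as a -1 penalty does); significance comes from
#: the raw-score floor, far above the random expectation for payload sizes.
INTERNAL_IR_SCHEME = LocalScoringScheme(
    match=1, mismatch=-2, gap_open=4, gap_extend=2, word_size=7,
    e_max=1e6, mask_low_complexity=False)
INTERNAL_IR_MIN_SCORE = 20

#: Coverage projection runs ungapped-only: gap placement is irrelevant to
#: which reference bases are covered, and it keeps long scans cheap.
REF_COVERAGE_SCHEME = replace(SEED_SEARCH, gapped=False)


@dataclass(frozen=True)
class HairpinHit:
    position: int
    stem_length: int
    loop_length: int
    stem_mismatches: int
    window_length: int
    sequence: str
    score: int


@dataclass(frozen=True)
class ClassLabel:
    label: str                      # Tm1-A | Tm1-D | Tm1-HH | Tm1-ML | other
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("class label requires evidence")


@dataclass(frozen=True)
class CoverageMap:
    reference_id: str
    total_fraction: float
    region_fractions: dict[str, float]
    mule_fraction: float


@dataclass(frozen=True)
class Orf:
    frame: int                      # +1..+3 / -1..-3
    interval: GenomicInterval       # on the forward strand of the input
    length_aa: int


@dataclass(frozen=True)
class NestedInsertion:
    interval: GenomicInterval       # element-local coordinates
    own_tsd: TsdCall | None
    has_internal_ir: bool


@dataclass(frozen=True)
class ClassifyThresholds:
    mule_cover: float = 0.5
    total_cover: float = 0.8
    patch_cover: float = 0.2
    mule_absent_below: float = 0.1
    ml_max_internal: int = 600
    nested_min_gap: int = 200


@dataclass
class ElementFeatures:
    internal_length: int
    hairpin_hits: list[HairpinHit]
    internal_ir: tuple[GenomicInterval, GenomicInterval] | None
    orfs: list[Orf]
    coverage: CoverageMap | None
    motif_d_present: bool


# ---------------------------------------------------------------------------
# feature scans
# ---------------------------------------------------------------------------

def scan_histone_hairpin(seq: str, min_stem: int = 6, max_stem: int = 10,
                         loop_range: tuple[int, int] = (3, 6),
                         max_mismatch: int = 2,
                         profile: str | None = None,
                         profile_max_mismatch: int = 2) -> list[HairpinHit]:
    """All stem-loop windows folding with the given stem/loop constraints.

    A window folds when its first ``stem`` bases are reverse-complementary
    to its last ``stem`` bases up to ``max_mismatch``.  When ``profile`` is
    supplied, hits are additionally rescored against it (Hamming distance
    over the profile length anchored at the hit start) and hits farther than
    ``profile_max_mismatch`` are discarded.  Deterministic ordering: score
    (stem length minus mismatches) descending, then position.
    """
    n = len(seq)
    hits: list[HairpinHit] = []
    lo_loop, hi_loop = loop_range
    for i in range(n):
        for stem in range(min_stem, max_stem + 1):
            for loop in range(lo_loop, hi_loop + 1):
                w = 2 * stem + loop
                if i + w > n:
                    continue
                arm1 = seq[i:i + stem]
                arm2 = seq[i + stem + loop:i + w]
                mm = sum(x != y for x, y in zip(arm1, reverse_complement(arm2)))
                if mm > max_mismatch:
                    continue
                if profile is not None:
                    window = seq[i:i + len(profile)]
                    if len(window) < len(profile):
                        continue
                    pmm = sum(x != y for x, y in zip(window, profile))
                    if pmm > profile_max_mismatch:
                        continue
                hits.append(HairpinHit(
                    position=i, stem_length=stem, loop_length=loop,
                    stem_mismatches=mm, window_length=w,
                    sequence=seq[i:i + w], score=stem - mm,
                ))
    hits.sort(key=lambda h: (-h.score, h.position, h.loop_length))
    return hits


def detect_internal_ir(internal_seq: str,
                       scheme: LocalScoringScheme = INTERNAL_IR_SCHEME,
                       min_score: int = INTERNAL_IR_MIN_SCORE
                       ) -> tuple[GenomicInterval, GenomicInterval] | None:
    """Best inverted-repeat pair within a payload, or None below the floor."""
    if len(internal_seq) < scheme.word_size:
        return None
    hits = seeded_local_search(internal_seq, internal_seq, scheme)
    best = None
    for h in hits:
        if h.strand != "-":
            continue
        qa, qb = h.query_interval.start, h.query_interval.end
        sa, sb = h.subject_interval.start, h.subject_interval.end
        if qa >= sa or qb > sa:       # mirror duplicate / overlapping arms
            continue
        if h.raw_score < min_score:
            continue
        if best is None or h.raw_score > best.raw_score:
            best = h
    if best is None:
        return None
    return (GenomicInterval("internal", best.query_interval.start,
                            best.query_interval.end, "+"),
            GenomicInterval("internal", best.subject_interval.start,
                            best.subject_interval.end, "-"))


_CODON_STOPS = {"TAA", "TAG", "TGA"}


def scan_orfs(seq: str, min_aa: int = 50) -> list[Orf]:
    """Six-frame ORFs (ATG..stop, standard code) of at least ``min_aa``.

    Lengths count the initiator Met but not the stop codon; ORFs are
    reported as forward-strand intervals covering start through stop codon.
    """
    out: list[Orf] = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for off in range(3):
            i = off
            while i + 3 <= n:
                if s[i:i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= n and s[j:j + 3] not in _CODON_STOPS:
                        j += 3
                    if j + 3 <= n:               # stop found
                        aa = (j - i) // 3
                        if aa >= min_aa:
                            frame = off + 1 if strand == "+" else -(off + 1)
                            if strand == "+":
                                iv = GenomicInterval("seq", i, j + 3, "+")
                            else:
                                iv = GenomicInterval("seq", n - (j + 3), n - i, "-")
                            out.append(Orf(frame, iv, aa))
                        i = j + 3
                    else:
                        break
                else:
                    i += 3
    out.sort(key=lambda o: (o.interval.start, o.frame))
    return out


def reference_similarity(internal_seq: str, reference: SequenceRecord,
                         regions: dict[str, tuple[int, int]],
                         scheme: LocalScoringScheme = REF_COVERAGE_SCHEME,
                         identity_floor: float = 60.0,
                         mule_region: str = "MULE_domain") -> CoverageMap:
    """Project local hits of the payload onto a reference interior.

    Returns the fraction of the reference (and of each named region) covered
    by hits at or above the identity floor.
    """
    covered = np.zeros(len(reference), dtype=bool)
    if len(internal_seq) >= scheme.word_size:
        for h in seeded_local_search(internal_seq, reference, scheme):
            if h.identity_pct >= identity_floor:
                covered[h.subject_interval.start:h.subject_interval.end] = True
    fractions = {
        name: float(covered[s:e].mean()) if e > s else 0.0
        for name, (s, e) in regions.items()
    }
    return CoverageMap(
        reference_id=reference.id,
        total_fraction=float(covered.mean()),
        region_fractions=fractions,
        mule_fraction=fractions.get(mule_region, 0.0),
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_element(features: ElementFeatures,
                     thresholds: ClassifyThresholds = ClassifyThresholds()) -> ClassLabel:
    """Assign exactly one class label; first matching rule wins.

    Rule order: (1) reference interior substantially covered including the
    MULE domain -> Tm1-A; (2) similarity patches with the MULE domain lost
    -> Tm1-D; (3) histone hairpin -> Tm1-HH; (4) internal inverted repeat in
    a short interior -> Tm1-ML; (5) other.
    """
    t = thresholds
    cov = features.coverage
    if cov is not None:
        if cov.mule_fraction >= t.mule_cover and cov.total_fraction >= t.total_cover:
            return ClassLabel("Tm1-A", (
                f"reference coverage {cov.total_fraction:.2f}",
                f"MULE region coverage {cov.mule_fraction:.2f}",
            ))
        patches = {n: f for n, f in cov.region_fractions.items()
                   if n != "MULE_domain" and f >= t.patch_cover}
        if patches and cov.mule_fraction < t.mule_absent_below:
            ev = tuple(f"patch {n} coverage {f:.2f}" for n, f in sorted(patches.items()))
            return ClassLabel("Tm1-D", ev + ("MULE region uncovered",))
    if features.hairpin_hits:
        h = features.hairpin_hits[0]
        return ClassLabel("Tm1-HH", (
            f"histone hairpin at {h.position} (stem {h.stem_length}, "
            f"loop {h.loop_length}, {h.stem_mismatches} mm)",
        ))
    if features.internal_ir is not None and features.internal_length <= t.ml_max_internal:
        a, b = features.internal_ir
        return ClassLabel("Tm1-ML", (
            f"internal inverted repeat {a.start}-{a.end}/{b.start}-{b.end}",
            f"interior {features.internal_length} bp",
        ))
    return ClassLabel("other", ("no class feature detected",))


#: Alignment costs for insertion detection: with the default extension cost
#: a kilobase internal gap is dearer than discarding the flanking match as a
#: free end gap, so long gaps must be near length-independent here.
NESTED_ALIGN_SCHEME = GlobalScoringScheme(match=5, mismatch=-4,
                                          gap_open=12, gap_extend=1)


def detect_nested_insertions(element_seq: str, exemplar_seq: str,
                             min_gap: int = 200,
                             tsd_flank: int = 15) -> list[NestedInsertion]:
    """Insertions revealed by free-end-gap alignment to a class exemplar.

    Runs of at least ``min_gap`` alignment columns gapped in the exemplar
    (extra sequence in the element) are flagged; each is re-analysed for an
    internal inverted repeat and for its own target-site duplication in the
    immediately flanking element sequence.
    """
    aln = global_align_free_end(element_seq, exemplar_seq, NESTED_ALIGN_SCHEME)
    (lead_a, trail_a), _ = aln.end_gap_spans
    cols = len(aln.aligned_a)
    out: list[NestedInsertion] = []
    pos_a = 0
    run_start = None
    for k in range(cols):
        ca, cb = aln.aligned_a[k], aln.aligned_b[k]
        internal = lead_a + 0 <= k < cols  # end gaps in a are lead/trail in a
        if cb == "-" and ca != "-":
            if run_start is None:
                run_start = pos_a
        else:
            if run_start is not None:
                _maybe_add(out, element_seq, run_start, pos_a, min_gap, tsd_flank)
                run_start = None
        if ca != "-":
            pos_a += 1
    if run_start is not None:
        _maybe_add(out, element_seq, run_start, pos_a, min_gap, tsd_flank)
    # drop runs that are merely terminal overhangs of the element
    out = [ins for ins in out
           if ins.interval.start > 0 and ins.interval.end < len(element_seq)]
    return out


def _maybe_add(out: list[NestedInsertion], element_seq: str, start: int,
               end: int, min_gap: int, tsd_flank: int) -> None:
    if end - start < min_gap:
        return
    # The alignment gap is ambiguous wherever the insertion's own TSD
    # duplicates flanking sequence: the gap spans insert + one TSD copy and
    # can start anywhere inside the duplication.  Slide the boundary within
    # that ambiguity looking for a direct repeat of length 7-12 whose left
    # copy ends at the insertion start and right copy begins at its end.
    span = end - start
    best: tuple[tuple[float, int, int], int, int, TsdCall] | None = None
    for L in range(7, 13):
        ins_len = span - L
        if ins_len < min_gap:
            continue
        for p in range(start, start + L + 1):
            if p - L < 0 or p + span > len(element_seq):
                continue
            left = element_seq[p - L:p]
            right = element_seq[p + ins_len:p + ins_len + L]
            mism = tuple(i for i, (x, y) in enumerate(zip(left, right))
                         if x != y)
            if len(mism) > 1:
                continue
            # a mismatch-free duplication is the parsimonious call; only
            # then prefer higher score and the canonical 9 bp
            key = (-len(mism), L - len(mism), -abs(L - 9), L)
            if best is None or key > best[0]:
                best = (key, p, p + ins_len,
                        TsdCall("found", L, left, right, mism))
    if best is not None:
        _, s, e, tsd = best
    else:
        s, e, tsd = start, end, None
    ir = detect_internal_ir(element_seq[s:e])
    out.append(NestedInsertion(
        interval=GenomicInterval("element", s, e, "+"),
        own_tsd=tsd,
        has_internal_ir=ir is not None,
    ))
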