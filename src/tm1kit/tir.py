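"""Terminal-inverted-repeat delineation and composite motif-grammar annotation.

A family element reads (left to right, target-site duplications excluded)::

    A1 . B . C^n . D . C . payload . rc(C . D) . rc(C^m) . rc(B) . A2

where A1/A2 are asymmetric 7 bp terminal motifs *outside* the inverted
repeat, B is a 3 bp spacer, C a ~14 bp tandem repeat of variable copy
number, and D a purine-rich 12 bp inner motif (absent from MITE-like
elements, which also drop the D-flanking C unit).  The TIR proper is the
inverted portion ``B C^n D C`` (and its reverse complement on the right).

Delineation compares the element window to its own reverse complement with
the word-11 local preset and keeps the best hit anchored near both termini;
the motif grammar is then annotated by dynamic-programming segmentation of
each TIR against the Motif C / Motif D consensus.
"""
from __future__ import annotations

from dataclasses import dataclass

from .align import TIR_DELINEATION, LocalScoringScheme, seeded_local_search
from .seqio import GenomicInterval, reverse_complement

#: 38 bp TIR seed query (one C unit, Motif D, one C unit).
SEED_QUERY = "GATTCAGTATACGGGGAAAAGGGGACGATTCAGTATAC"

#: Shared Motif D core used for detection (species variants differ from it
#: by at most 2 mismatches).
D_CORE = "GGGAAAAGGGGA"


@dataclass(frozen=True)
class MotifProfile:
    """Species-level consensus strings for the composite TIR grammar."""

    name: str
    a1: str = "CGGTTAA"
    a2: str = "CCTACCC"
    b: str = "GGA"
    c: str = "CGATTCAGTATCGC"
    d: str = "GGGAAAAGGGGA"


INCOGNITA = MotifProfile(name="incognita")
HAPLA = MotifProfile(name="hapla", a1="CGGATAA", c="CGTTTCAGTATCGC", d="GCCAAAAGGGGA")
PROFILES = {"incognita": INCOGNITA, "hapla": HAPLA}


@dataclass(frozen=True)
class MotifCall:
    status: str          # "present" | "absent"
    sequence: str = ""
    position: int = -1   # local coordinate of the motif start, -1 if absent
    mismatches: int = 0

    @property
    def present(self) -> bool:
        return self.status == "present"


ABSENT = MotifCall(status="absent")


@dataclass(frozen=True)
class MotifCUnit:
    """One tandem-repeat unit of Motif C within a TIR (TIR-local coords)."""

    interval: GenomicInterval
    sequence: str
    identity_to_consensus: float

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class Segment:
    kind: str            # "C" | "D" | "skip"
    start: int
    end: int
    cost: float


@dataclass(frozen=True)
class TirDelineation:
    left: tuple[int, int]
    right: tuple[int, int]
    identity_pct: float
    score: int


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (the motif-unit scoring primitive)."""
    la, lb = len(a), len(b)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (ca != b[j - 1]))
        prev = cur
    return prev[lb]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# TIR delineation
# ---------------------------------------------------------------------------

def _trim_to_repeat_region(arm_seq: str, profile: MotifProfile) -> tuple[int, int]:
    """(start, end) of the motif-bearing core of a self-comparison arm.

    For a MITE-like element the element is near-palindromic as a whole, so
    the terminal self-comparison can chain through the payload's own
    inverted repeat; and when both termini carry the same terminal motif the
    motifs themselves align.  Trimming each arm to its contiguous grammar
    run (first unit through the last unit before any unexplained stretch
    longer than a few residues) restores the conventional TIR / payload
    distinction.  Short skips bridge diverged residues between units; the
    leading Motif B (3 bp) stays inside the arm.
    """
    segs = decompose_repeats(arm_seq, profile)
    start = end = 0
    started = False
    for s in segs:
        if s.kind == "skip":
            if started and s.end - s.start > 4:
                break
            if not started and s.end - s.start > 4:
                start = s.end
            continue
        if not started:
            start = min(start, s.start)
            started = True
        end = s.end
    if not started:
        return (0, 0)
    return (start, end)


def delineate_tirs(seq: str, preset: LocalScoringScheme = TIR_DELINEATION,
                   left_anchor: tuple[int, int] | None = None,
                   right_anchor: tuple[int, int] | None = None,
                   min_tir_len: int = 15,
                   profile: MotifProfile | None = INCOGNITA) -> TirDelineation | None:
    """Find the TIR pair by aligning the window against its reverse complement.

    The best minus-strand self-hit whose left interval overlaps
    ``left_anchor`` and right interval overlaps ``right_anchor`` (terminal
    thirds of the window when no anchors are given) defines the TIR pair and
    its identity.  When a motif profile is given, each arm is trimmed to its
    motif-bearing region so that payload inverted repeats (MITE-like
    elements are near-palindromic end to end) are not absorbed into the
    TIRs.  Returns ``None`` when no anchored self-hit exists (TIRs
    unresolved).
    """
    n = len(seq)
    margin = 60   # seed clusters can sit a repeat-unit phase away from the arm
    if left_anchor is None:
        left_anchor = (0, n // 3)
    if right_anchor is None:
        right_anchor = (2 * n // 3, n)
    la = (max(0, left_anchor[0] - margin), min(n, left_anchor[1] + margin))
    ra = (max(0, right_anchor[0] - margin), min(n, right_anchor[1] + margin))
    hits = seeded_local_search(seq, seq, preset, cull=False)
    anchored = []
    for h in hits:
        if h.strand != "-":
            continue
        qa, qb = h.query_interval.start, h.query_interval.end
        sa, sb = h.subject_interval.start, h.subject_interval.end
        # self-comparison hits come in mirror pairs and culling keeps an
        # arbitrary one; orient so the left arm is the query side (a
        # near-palindromic element yields one hit with heavily overlapping
        # arms, which grammar trimming below resolves)
        if qa > sa:
            (qa, qb), (sa, sb) = (sa, sb), (qa, qb)
        if min(qb, la[1]) - max(qa, la[0]) <= 0:
            continue
        if min(sb, ra[1]) - max(sa, ra[0]) <= 0:
            continue
        if qb - qa < min_tir_len or sb - sa < min_tir_len:
            continue
        anchored.append(((-h.raw_score, -(qb - qa), qa), (qa, qb, sa, sb), h))
    for _, (qa, qb, sa, sb), h in sorted(anchored, key=lambda x: x[0]):
        if profile is not None:
            ls, le = _trim_to_repeat_region(seq[qa:qb], profile)
            rs, re_ = _trim_to_repeat_region(
                reverse_complement(seq[sa:sb]), profile)
            if le - ls >= min_tir_len:
                qa, qb = qa + ls, qa + le
            if re_ - rs >= min_tir_len:
                sa, sb = sb - re_, sb - rs
        if qb - qa < min_tir_len or sb - sa < min_tir_len:
            continue
        if qb > sa:             # arms still overlap: not a terminal pair
            continue
        return TirDelineation(
            left=(qa, qb),
            right=(sa, sb),
            identity_pct=h.identity_pct,
            score=h.raw_score,
        )
    return None


# ---------------------------------------------------------------------------
# Motif C / D segmentation
# ---------------------------------------------------------------------------

def decompose_repeats(tir_seq: str, profile: MotifProfile = INCOGNITA,
                      min_unit: int = 8, max_unit: int = 21,
                      include_d: bool = True, c_max_cost: int = 4,
                      d_max_cost: int = 2, skip_cost: float = 1.0) -> list[Segment]:
    """Optimal segmentation of a TIR into C units, D, and skipped residues.

    Dynamic programming minimises total cost, where a candidate unit of
    length ``L`` costs its edit distance to the consensus (rejected above
    ``c_max_cost`` / ``d_max_cost``) and an unexplained residue costs
    ``skip_cost``.  The segmentation is a partition: concatenating the
    segments reconstructs the TIR exactly.
    """
    n = len(tir_seq)
    INF = float("inf")
    best = [0.0] + [INF] * n
    back: list[tuple[str, int, float] | None] = [None] * (n + 1)
    d_lens = range(max(10, len(D_CORE) - 2), len(D_CORE) + 3)
    for i in range(1, n + 1):
        # prefer an explained unit over skips; prefer C over D on cost ties
        for L in range(min(max_unit, i), min_unit - 1, -1):
            chunk = tir_seq[i - L:i]
            cost = levenshtein(chunk, profile.c)
            if cost <= c_max_cost and best[i - L] + cost < best[i]:
                best[i] = best[i - L] + cost
                back[i] = ("C", L, cost)
        if include_d:
            for L in d_lens:
                if L > i:
                    continue
                chunk = tir_seq[i - L:i]
                cost = levenshtein(chunk, D_CORE)
                if cost <= d_max_cost and best[i - L] + cost < best[i]:
                    best[i] = best[i - L] + cost
                    back[i] = ("D", L, cost)
        if best[i - 1] + skip_cost < best[i]:
            best[i] = best[i - 1] + skip_cost
            back[i] = ("skip", 1, skip_cost)
    segments: list[Segment] = []
    i = n
    while i > 0:
        kind, L, cost = back[i]  # type: ignore[misc]
        segments.append(Segment(kind, i - L, i, cost))
        i -= L
    segments.reverse()
    # merge adjacent skip segments
    merged: list[Segment] = []
    for s in segments:
        if merged and s.kind == "skip" and merged[-1].kind == "skip":
            merged[-1] = Segment("skip", merged[-1].start, s.end,
                                 merged[-1].cost + s.cost)
        else:
            merged.append(s)
    return merged


def decompose_motif_c(tir_seq: str, profile: MotifProfile = INCOGNITA,
                      min_unit: int = 8, max_unit: int = 21,
                      include_d: bool = True) -> list[MotifCUnit]:
    """Motif C units of a TIR (ordered, non-overlapping, TIR-local coords)."""
    units = []
    for seg in decompose_repeats(tir_seq, profile, min_unit, max_unit, include_d):
        if seg.kind != "C":
            continue
        seq = tir_seq[seg.start:seg.end]
        denom = max(len(seq), len(profile.c))
        units.append(MotifCUnit(
            interval=GenomicInterval("tir", seg.start, seg.end),
            sequence=seq,
            identity_to_consensus=100.0 * (1 - seg.cost / denom),
        ))
    return units


def find_motif_d(tir_seq: str, max_mismatch: int = 2) -> MotifCall:
    """Scan a (left-oriented) TIR for the purine-rich inner Motif D core.

    Best window by mismatch count; ties resolved toward the element interior
    (the motif sits at the TIR's inner end, followed by one more C unit).
    """
    L = len(D_CORE)
    best: MotifCall | None = None
    for i in range(len(tir_seq) - L + 1):
        mm = hamming(tir_seq[i:i + L], D_CORE)
        if mm <= max_mismatch and (best is None or (mm, -i) < (best.mismatches, -best.position)):
            best = MotifCall("present", tir_seq[i:i + L], i, mm)
    return best if best is not None else ABSENT


def find_motif_b(seq: str, pos: int, profile: MotifProfile = INCOGNITA,
                 leftward: bool = True) -> MotifCall:
    """Motif B just outside a TIR edge at local position ``pos``.

    The 3-mer must match exactly (no mismatch budget at this length); a few
    bp of jitter around the expected position absorbs the base-level
    uncertainty of the self-comparison edge.  ``leftward`` seeks B ending at
    ``pos`` (left TIR); otherwise its reverse complement starting at ``pos``.
    """
    motif = profile.b if leftward else reverse_complement(profile.b)
    expected = pos - 3 if leftward else pos
    best: tuple[int, int, MotifCall] | None = None
    for s in range(max(0, expected - 3), min(len(seq) - 3, expected + 4) + 1):
        if seq[s:s + 3] == motif:
            d = abs(s - expected)
            if best is None or d < best[0]:
                best = (d, s, MotifCall("present", seq[s:s + 3], s, 0))
    return best[2] if best else ABSENT


# ---------------------------------------------------------------------------
# terminal motifs and element boundaries
# ---------------------------------------------------------------------------

def _extend_units_outward(seq: str, pos: int, consensus: str, leftward: bool,
                          max_cost: int = 2) -> int:
    """Greedy outward extension over additional whole repeat units.

    Terminal self-comparison truncates the outer end of the longer C array
    when the two TIRs carry different unit counts; walking outward one unit
    at a time (preferring the consensus length) recovers the full array.
    """
    lengths = sorted(range(max(8, len(consensus) - 4), len(consensus) + 5),
                     key=lambda L: (abs(L - len(consensus)), L))
    while True:
        step = 0
        for L in lengths:
            if leftward:
                if pos - L < 0:
                    continue
                chunk = seq[pos - L:pos]
            else:
                if pos + L > len(seq):
                    continue
                chunk = seq[pos:pos + L]
            if levenshtein(chunk, consensus) <= max_cost:
                step = L
                break
        if step == 0:
            return pos
        pos = pos - step if leftward else pos + step


def _scan_terminal(seq: str, pos: int, motif: str, leftward: bool,
                   max_mismatch: int, max_offset: int = 12) -> MotifCall:
    """Look for a 7 bp terminal motif within ``max_offset`` bp outside ``pos``.

    The expected offset is 3 (Motif B sits between the motif and the TIR);
    candidates are ranked by mismatches, then by distance from that offset.
    Slightly negative offsets are allowed because the self-comparison edge
    can overhang the true TIR boundary by a base or two.
    """
    L = len(motif)
    best: tuple[tuple[int, int, int], MotifCall] | None = None
    for d in range(-3, max_offset + 1):
        if leftward:
            s = pos - d - L
            if s < 0:
                break
            chunk = seq[s:s + L]
        else:
            s = pos + d
            if s < 0:
                continue
            if s + L > len(seq):
                break
            chunk = seq[s:s + L]
        mm = hamming(chunk, motif)
        if mm <= max_mismatch:
            key = (mm, abs(d - 3), d)
            if best is None or key < best[0]:
                best = (key, MotifCall("present", chunk, s, mm))
    return best[1] if best else ABSENT


@dataclass(frozen=True)
class ElementAnnotation:
    """Full grammar annotation of one element window (local coordinates).

    Coordinates refer to the *oriented* window: if ``flipped`` is true the
    window was reverse-complemented so that Motif A1 is on the left, and
    positions index the flipped sequence.
    """

    seq: str
    element_start: int
    element_end: int
    left_tir: tuple[int, int]
    right_tir: tuple[int, int]
    tir_identity_pct: float
    a1: MotifCall
    a2: MotifCall
    b_left: MotifCall
    b_right: MotifCall
    d_left: MotifCall
    d_right: MotifCall
    c_left: tuple[MotifCUnit, ...]
    c_right: tuple[MotifCUnit, ...]
    flipped: bool = False
    a2_both_ends: bool = False
    #: whichever 7 bp motif (A1, A2 or a reverse complement) was found at
    #: each terminus; used for TSD eligibility and element boundaries
    left_terminal: MotifCall = ABSENT
    right_terminal: MotifCall = ABSENT

    @property
    def element_seq(self) -> str:
        return self.seq[self.element_start:self.element_end]

    @property
    def internal_seq(self) -> str:
        """Sequence between the two TIRs (the payload)."""
        return self.seq[self.left_tir[1]:self.right_tir[0]]


def annotate_element_window(seq: str, profile: MotifProfile = INCOGNITA,
                            preset: LocalScoringScheme = TIR_DELINEATION,
                            left_anchor: tuple[int, int] | None = None,
                            right_anchor: tuple[int, int] | None = None,
                            max_mismatch: int = 1,
                            _allow_flip: bool = True) -> ElementAnnotation | None:
    """Delineate TIRs, fix orientation, and annotate the motif grammar.

    Orientation: each terminus is scanned for a forward terminal motif and
    for the reverse complement of the opposite motif; when the inverted
    reading is strictly better supported the whole window is
    reverse-complemented so A1 ends up on the left.  An element showing A2
    at both ends is reported as found, flagged, and not flipped.
    """
    delin = delineate_tirs(seq, preset, left_anchor, right_anchor,
                           profile=profile)
    if delin is None:
        return None
    (ls, le), (rs, re_) = delin.left, delin.right

    # recover full unit arrays truncated by the asymmetric self-comparison
    ls_full = _extend_units_outward(seq, ls, profile.c, leftward=True)
    re_full = _extend_units_outward(seq, re_, reverse_complement(profile.c),
                                    leftward=False)

    left_a1 = _scan_terminal(seq, ls_full, profile.a1, True, max_mismatch)
    left_rc_a2 = _scan_terminal(seq, ls_full, reverse_complement(profile.a2),
                                True, max_mismatch)
    right_a2 = _scan_terminal(seq, re_full, profile.a2, False, max_mismatch)
    right_rc_a1 = _scan_terminal(seq, re_full, reverse_complement(profile.a1),
                                 False, max_mismatch)

    canonical = left_a1.present + right_a2.present
    inverted = left_rc_a2.present + right_rc_a1.present
    if _allow_flip and inverted > canonical:
        flipped = annotate_element_window(
            reverse_complement(seq), profile, preset,
            left_anchor=(len(seq) - right_anchor[1], len(seq) - right_anchor[0])
            if right_anchor else None,
            right_anchor=(len(seq) - left_anchor[1], len(seq) - left_anchor[0])
            if left_anchor else None,
            max_mismatch=max_mismatch, _allow_flip=False)
        if flipped is not None:
            from dataclasses import replace as _replace
            return _replace(flipped, flipped=True)
        return None

    a2_both = left_rc_a2.present and right_a2.present and not left_a1.present

    a1 = left_a1
    a2 = right_a2

    # element boundaries: outermost base of the terminal motif when present,
    # else the Motif B edge, else the recovered TIR edge
    left_edge = ls_full
    b_left = find_motif_b(seq, ls_full, profile, leftward=True)
    if b_left.present:
        left_edge = b_left.position
    left_motif = a1 if a1.present else left_rc_a2
    if left_motif.present:
        left_edge = left_motif.position

    right_edge = re_full
    b_right = find_motif_b(seq, re_full, profile, leftward=False)
    if b_right.present:
        right_edge = b_right.position + 3
    right_motif = a2 if a2.present else right_rc_a1
    if right_motif.present:
        right_edge = right_motif.position + 7

    left_tir_seq = seq[ls_full:le]
    right_tir_seq = reverse_complement(seq[rs:re_full])
    include_d = True
    c_left = tuple(decompose_motif_c(left_tir_seq, profile, include_d=include_d))
    c_right = tuple(decompose_motif_c(right_tir_seq, profile, include_d=include_d))
    d_left = find_motif_d(left_tir_seq)
    d_right = find_motif_d(right_tir_seq)

    return ElementAnnotation(
        seq=seq,
        element_start=left_edge,
        element_end=right_edge,
        left_tir=(ls_full, le),
        right_tir=(rs, re_full),
        tir_identity_pct=delin.identity_pct,
        a1=a1,
        a2=a2,
        b_left=b_left,
        b_right=b_right,
        d_left=d_left,
        d_right=d_right,
        c_left=c_left,
        c_right=c_right,
        a2_both_ends=a2_both,
        left_terminal=left_motif if left_motif.present else ABSENT,
        right_terminal=right_motif if right_motif.present else ABSENT,
    )
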