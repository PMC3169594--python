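"""Alignment engines: seeded local search and free-end-gap global alignment.

Two engines drive the annotation pipeline:

* :func:`seeded_local_search` — a word-seeded local aligner in the BLASTN
  mould: exact word hits on both strands, ungapped X-drop extension, then an
  exact affine-gap local optimisation in a window around each surviving seed
  (a conservative variant of gapped X-drop extension whose result equals the
  full Smith-Waterman optimum whenever a seed word exists).  Significance is
  assessed with ungapped Karlin-Altschul statistics.
* :func:`global_align_free_end` — an affine-gap Needleman-Wunsch/Gotoh
  aligner with cost-free terminal gaps and a fixed, documented tie-breaking
  order so identity percentages are bit-reproducible.

A gap of length L costs ``gap_open + L * gap_extend`` throughout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .seqio import GenomicInterval, SequenceRecord, reverse_complement

NEG = -(10**9)

# Ungapped Karlin-Altschul parameters for the nucleotide schemes used by the
# pipeline presets (uniform base composition).  Other schemes get lambda by
# numerically solving sum p_i p_j exp(lambda*s_ij) = 1 and an approximate K.
_KA_TABLE = {
    (1, -3): (1.374, 0.711),
    (1, -2): (1.330, 0.621),
}


def karlin_lambda(match: int, mismatch: int) -> float:
    """Solve the ungapped Karlin-Altschul lambda for uniform base frequencies."""
    def f(lam: float) -> float:
        return (4 * math.exp(lam * match) + 12 * math.exp(lam * mismatch)) / 16 - 1.0
    return brentq(f, 1e-9, 10.0, xtol=1e-12)


@dataclass(frozen=True)
class LocalScoringScheme:
    """Parameters of the seeded local search."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = 4
    gap_extend: int = 2
    word_size: int = 7
    x_dropoff: float = 20.0
    gapped_x_dropoff: float = 50.0
    e_max: float = 10.0
    lambda_: float = 0.0
    k_const: float = 0.0
    mask_low_complexity: bool = True
    gap_trigger: int = 0
    #: when False, hits are ungapped X-drop extensions only (used by
    #: coverage-style scans where gap placement is irrelevant)
    gapped: bool = True

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("need match > 0 and mismatch < 0")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        # expected per-pair score must be negative for E-value validity
        if (4 * self.match + 12 * self.mismatch) / 16 >= 0:
            raise ValueError("expected background score is non-negative")
        if self.lambda_ <= 0 or self.k_const <= 0:
            key = (self.match, self.mismatch)
            lam, k = _KA_TABLE.get(key, (karlin_lambda(*key), 0.35))
            object.__setattr__(self, "lambda_", lam)
            object.__setattr__(self, "k_const", k)

    def evalue(self, score: int, m: int, n: int) -> float:
        return self.k_const * m * n * math.exp(-self.lambda_ * score)

    def score_floor(self, m: int, n: int) -> int:
        """Smallest integer raw score with E <= e_max for search space m*n."""
        s = math.log(self.k_const * m * n / self.e_max) / self.lambda_
        return max(self.word_size * self.match, math.ceil(s - 1e-9))


#: Genome-wide TIR seed search: word 7, match/mismatch +1/-3, gaps 4/2, E<=10.
SEED_SEARCH = LocalScoringScheme(
    match=1, mismatch=-3, gap_open=4, gap_extend=2, word_size=7,
    e_max=10.0, mask_low_complexity=True,
)

#: Terminal self-comparison used to delineate TIR extents: word 11, +1/-2,
#: gaps 5/2, gapped X-dropoff 50, E<=10.
TIR_DELINEATION = LocalScoringScheme(
    match=1, mismatch=-2, gap_open=5, gap_extend=2, word_size=11,
    gapped_x_dropoff=50.0, e_max=10.0, mask_low_complexity=True,
)

PRESETS = {"seed-search": SEED_SEARCH, "tir-delineation": TIR_DELINEATION}


@dataclass(frozen=True)
class GlobalScoringScheme:
    match: int = 5
    mismatch: int = -4
    gap_open: int = 12
    gap_extend: int = 3


#: Free-end-gap global alignment costs used for element-vs-element comparison.
GLOBAL_DEFAULT = GlobalScoringScheme()

#: Tandem-repeat (motif unit) alignment costs.
MOTIF_ALIGN = GlobalScoringScheme(match=5, mismatch=-4, gap_open=15, gap_extend=7)


@dataclass(frozen=True)
class LocalHit:
    query_interval: GenomicInterval
    subject_interval: GenomicInterval
    strand: str
    raw_score: int
    e_value: float
    identity_pct: float
    aligned_query: str
    aligned_subject: str


@dataclass(frozen=True)
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: int
    identity_pct: float
    #: ((leading, trailing) gap columns in a, (leading, trailing) in b)
    end_gap_spans: tuple[tuple[int, int], tuple[int, int]]


# ---------------------------------------------------------------------------
# low-complexity masking (DUST-style triplet statistic)
# ---------------------------------------------------------------------------

def mask_low_complexity(seq: str, window: int = 16, threshold: float = 2.0) -> np.ndarray:
    """Boolean mask of positions inside low-complexity windows.

    The per-window statistic is the DUST triplet score
    ``sum_t c_t (c_t - 1) / 2 / (T - 1)`` where ``c_t`` counts occurrences of
    each overlapping triplet and ``T = window - 2``.  Masking suppresses
    seeding only; extensions may run through masked sequence.
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    if n < window:
        return mask
    for i in range(n - window + 1):
        counts: dict[str, int] = {}
        for k in range(i, i + window - 2):
            t = seq[k:k + 3]
            counts[t] = counts.get(t, 0) + 1
        raw = sum(c * (c - 1) // 2 for c in counts.values())
        if raw / (window - 3) > threshold:
            mask[i:i + window] = True
    return mask


# ---------------------------------------------------------------------------
# affine-gap DP cores (row-vectorised Gotoh)
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _gotoh_matrices(a: str, b: str, match: int, mismatch: int,
                    go: int, ge: int, local: bool, free_ends: bool,
                    band: tuple[int, int] | None = None):
    """Fill H (best), F (vertical: gap in b), E (horizontal: gap in a).

    ``band`` restricts local alignments to diagonals ``j - i`` within the
    given inclusive range (used to keep a gapped re-optimisation anchored
    to its seed).
    """
    la, lb = len(a), len(b)
    ea, eb = _encode(a), _encode(b)
    H = np.full((la + 1, lb + 1), 0 if (local or free_ends) else NEG, dtype=np.int64)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    H[0, :] = 0 if (local or free_ends) else NEG
    H[:, 0] = 0 if (local or free_ends) else NEG
    H[0, 0] = 0
    j_idx = np.arange(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        srow = np.where(eb == ea[i - 1], match, mismatch).astype(np.int64)
        # N never matches anything, including another N
        if ea[i - 1] == ord("N"):
            srow[:] = mismatch
        srow[eb == ord("N")] = mismatch
        D = H[i - 1, :-1] + srow
        F[i, 1:] = np.maximum(H[i - 1, 1:] - go - ge, F[i - 1, 1:] - ge)
        Hp = np.maximum(D, F[i, 1:])
        if local:
            Hp = np.maximum(Hp, 0)
        Hp_full = np.empty(lb + 1, dtype=np.int64)
        Hp_full[0] = H[i, 0]
        Hp_full[1:] = Hp
        run = np.maximum.accumulate(Hp_full + j_idx * ge)
        E[i, 1:] = run[:-1] - go - j_idx[1:] * ge
        H[i, 1:] = np.maximum(Hp, E[i, 1:])
        if local:
            H[i, 1:] = np.maximum(H[i, 1:], 0)
        if band is not None:
            lo = max(1, i + band[0])
            hi = min(lb, i + band[1])
            if lo > 1:
                H[i, 1:lo] = 0 if local else NEG
                E[i, 1:lo] = NEG
                F[i, 1:lo] = NEG
            if hi < lb:
                H[i, hi + 1:] = 0 if local else NEG
                E[i, hi + 1:] = NEG
                F[i, hi + 1:] = NEG
    return H, F, E


def _traceback(a: str, b: str, H, F, E, i: int, j: int,
               match: int, mismatch: int, go: int, ge: int, local: bool,
               stop_at_zero: bool):
    """Walk back from (i, j); preference diagonal > gap-in-b > gap-in-a."""
    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if local and stop_at_zero and H[i, j] == 0:
                break
            if i == 0 or j == 0:
                if not local:
                    break  # free leading end gaps handled by caller
                break
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - matrices are consistent by construction
                raise AssertionError("inconsistent traceback")
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            if i > 1 and F[i, j] == F[i - 1, j] - ge:
                i -= 1
            else:
                i -= 1
                state = "H"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            if j > 1 and E[i, j] == E[i, j - 1] - ge:
                j -= 1
            else:
                j -= 1
                state = "H"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), i, j


def smith_waterman(a: str, b: str, scheme: LocalScoringScheme,
                   band: tuple[int, int] | None = None):
    """Exact affine-gap local alignment (score and aligned strings).

    Returns ``(score, (a_start, a_end), (b_start, b_end), aligned_a,
    aligned_b)``; score 0 means no positive-scoring local alignment.
    ``band`` restricts the alignment to diagonals ``j - i`` in the given
    inclusive range.
    """
    H, F, E = _gotoh_matrices(a, b, scheme.match, scheme.mismatch,
                              scheme.gap_open, scheme.gap_extend,
                              local=True, free_ends=False, band=band)
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    if score <= 0:
        return 0, (0, 0), (0, 0), "", ""
    aa, bb, i0, j0 = _traceback(a, b, H, F, E, i, j, scheme.match,
                                scheme.mismatch, scheme.gap_open,
                                scheme.gap_extend, local=True, stop_at_zero=True)
    return score, (i0, i), (j0, j), aa, bb


def global_align_free_end(a: str, b: str,
                          params: GlobalScoringScheme = GLOBAL_DEFAULT) -> GlobalAlignment:
    """Optimal global alignment with affine gaps and cost-free terminal gaps.

    Tie-breaking is fixed (prefer diagonal, then a gap in ``b``, then a gap
    in ``a``; among equal terminal cells the one nearest the corner on the
    last column is preferred) so output is deterministic.
    """
    if not a or not b:
        raise ValueError("global alignment requires non-empty sequences")
    H, F, E = _gotoh_matrices(a, b, params.match, params.mismatch,
                              params.gap_open, params.gap_extend,
                              local=False, free_ends=True)
    la, lb = len(a), len(b)
    best_i, best_j, best = la, lb, H[la, lb]
    for i in range(la, -1, -1):
        if H[i, lb] > best:
            best, best_i, best_j = H[i, lb], i, lb
    for j in range(lb, -1, -1):
        if H[la, j] > best:
            best, best_i, best_j = H[la, j], la, j
    aa, bb, i0, j0 = _traceback(a, b, H, F, E, best_i, best_j, params.match,
                                params.mismatch, params.gap_open,
                                params.gap_extend, local=False, stop_at_zero=False)
    # free terminal gaps: pad un-traversed prefixes/suffixes
    lead_a = a[:i0]
    lead_b = b[:j0]
    aa = lead_a + "-" * len(lead_b) + aa
    bb = "-" * len(lead_a) + lead_b + bb
    tail_a = a[best_i:]
    tail_b = b[best_j:]
    aa = aa + tail_a + "-" * len(tail_b)
    bb = bb + "-" * len(tail_a) + tail_b
    lead_gap_a = len(lead_b)   # gap columns in a at the start
    lead_gap_b = len(lead_a)
    trail_gap_a = len(tail_b)
    trail_gap_b = len(tail_a)
    aln = GlobalAlignment(
        aligned_a=aa, aligned_b=bb, score=int(best),
        identity_pct=0.0,
        end_gap_spans=((lead_gap_a, trail_gap_a), (lead_gap_b, trail_gap_b)),
    )
    try:
        return replace(aln, identity_pct=percent_identity(aln))
    except ValueError:
        # fully staggered alignment (all columns are end gaps)
        return aln


def percent_identity(alignment: GlobalAlignment | tuple[str, str],
                     exclude_end_gaps: bool = True) -> float:
    """Identical columns / counted columns * 100.

    End-gap columns (terminal gaps in either sequence) are excluded from the
    denominator when ``exclude_end_gaps`` is true; internal gap columns always
    count as non-identical.
    """
    if isinstance(alignment, GlobalAlignment):
        aa, bb = alignment.aligned_a, alignment.aligned_b
    else:
        aa, bb = alignment
    if len(aa) != len(bb):
        raise ValueError("aligned strings differ in length")
    start, end = 0, len(aa)
    if exclude_end_gaps:
        while start < end and (aa[start] == "-" or bb[start] == "-"):
            start += 1
        while end > start and (aa[end - 1] == "-" or bb[end - 1] == "-"):
            end -= 1
    total = end - start
    if total == 0:
        raise ValueError("no counted columns in alignment")
    ident = sum(1 for k in range(start, end) if aa[k] == bb[k] and aa[k] != "-")
    return 100.0 * ident / total


def alignment_score(aligned_a: str, aligned_b: str, scheme: LocalScoringScheme) -> int:
    """Recompute the raw score of a gapped alignment under a local scheme."""
    score = 0
    k = 0
    n = len(aligned_a)
    while k < n:
        if aligned_a[k] == "-" or aligned_b[k] == "-":
            which = 0 if aligned_a[k] == "-" else 1
            run = 0
            while k < n and (aligned_a[k] == "-" if which == 0 else aligned_b[k] == "-"):
                run += 1
                k += 1
            score -= scheme.gap_open + run * scheme.gap_extend
        else:
            score += scheme.match if aligned_a[k] == aligned_b[k] else scheme.mismatch
            k += 1
    return score


# ---------------------------------------------------------------------------
# seeded local search
# ---------------------------------------------------------------------------

def _ungapped_extend(q: str, s: str, qpos: int, spos: int, w: int,
                     match: int, mismatch: int, xdrop: float):
    """X-drop ungapped extension around an exact word seed."""
    score = w * match
    best = score
    qi, si = qpos + w, spos + w
    bq, bs = qi, si
    while qi < len(q) and si < len(s):
        score += match if (q[qi] == s[si] and q[qi] != "N") else mismatch
        qi += 1
        si += 1
        if score > best:
            best, bq, bs = score, qi, si
        elif best - score > xdrop:
            break
    score = best
    qi, si = qpos, spos
    aq, as_ = qi, si
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        score += match if (q[qi] == s[si] and q[qi] != "N") else mismatch
        if score > best:
            best, aq, as_ = score, qi, si
        elif best - score > xdrop:
            break
    return best, aq, bq, as_, bs


def _residue_identity(aa: str, bb: str) -> float:
    ident = sum(1 for x, y in zip(aa, bb) if x == y and x != "-")
    return 100.0 * ident / len(aa)


def seeded_local_search(query: str | SequenceRecord, subject: str | SequenceRecord,
                        scheme: LocalScoringScheme = SEED_SEARCH,
                        search_space_n: int | None = None,
                        cull: bool = True) -> list[LocalHit]:
    """Word-seeded local search of ``query`` against both strands of ``subject``.

    ``search_space_n`` overrides the subject length used for E-values (set it
    to the total genome length for genome-wide searches).  Hits with
    ``E > e_max`` are discarded; overlapping same-strand hits are culled
    keeping the best score unless ``cull`` is false (self-comparisons keep
    sub-optimal hits because a chained repeat alignment can shadow the hit
    a caller actually wants); output is sorted by subject start.
    """
    qid = query.id if isinstance(query, SequenceRecord) else "query"
    sid = subject.id if isinstance(subject, SequenceRecord) else "subject"
    q = query.residues if isinstance(query, SequenceRecord) else query
    s = subject.residues if isinstance(subject, SequenceRecord) else subject
    w = scheme.word_size
    if len(q) < w:
        raise ValueError(f"query length {len(q)} < word size {w}")
    m = len(q)
    n_eff = search_space_n if search_space_n is not None else len(s)

    qmask = mask_low_complexity(q) if scheme.mask_low_complexity else np.zeros(m, bool)

    raw_hits: list[tuple[int, int, int, int, int, str]] = []
    for strand in ("+", "-"):
        qq = q if strand == "+" else reverse_complement(q)
        mm = qmask if strand == "+" else qmask[::-1]
        index: dict[str, list[int]] = {}
        for i in range(len(qq) - w + 1):
            if mm[i:i + w].any():
                continue
            word = qq[i:i + w]
            if "N" in word:
                continue
            index.setdefault(word, []).append(i)
        if not index:
            continue
        covered: dict[int, int] = {}
        for j in range(len(s) - w + 1):
            word = s[j:j + w]
            starts = index.get(word)
            if not starts:
                continue
            for qpos in starts:
                diag = j - qpos
                if covered.get(diag, -1) >= j + w:
                    continue
                score, qa, qb, sa, sb = _ungapped_extend(
                    qq, s, qpos, j, w, scheme.match, scheme.mismatch, scheme.x_dropoff)
                covered[diag] = max(covered.get(diag, -1), sb)
                raw_hits.append((score, qa, qb, sa, sb, strand))

    # pre-cull before the gapped stage: phase-shifted seeds from tandem
    # repeats converge on the same alignment, so only the best ungapped hit
    # per overlapping subject region needs re-optimising
    raw_hits.sort(key=lambda t: (-t[0], t[3], t[1], t[5]))
    pre: list[tuple[int, int, int, int, int, str]] = []
    for h in (raw_hits if cull else []):
        _, _, _, sa, sb, strand = h
        drop = False
        for _, _, _, ka, kb, kstrand in pre:
            if kstrand != strand:
                continue
            ov = min(kb, sb) - max(ka, sa)
            if ov > 0 and ov >= 0.5 * min(kb - ka, sb - sa):
                drop = True
                break
        if not drop:
            pre.append(h)
    if cull:
        raw_hits = pre

    floor = scheme.score_floor(m, n_eff)
    pad = 250   # gapped re-optimisation window around each ungapped hit
    hits: list[LocalHit] = []
    for score, qa, qb, sa, sb, strand in raw_hits:
        qq = q if strand == "+" else reverse_complement(q)
        if scheme.gapped and score >= max(scheme.gap_trigger, floor - 4):
            qlo, qhi = max(0, qa - pad), min(m, qb + pad)
            ws, we = max(0, sa - pad), min(len(s), sb + pad)
            band = None
            if not cull:
                # keep the re-optimisation anchored to this seed's diagonal
                # so distinct seeds report distinct alignments instead of
                # all converging on the window's single best one
                diag0 = (sa - ws) - (qa - qlo)
                band = (diag0 - 64, diag0 + 64)
            gscore, (ga0, ga1), (gb0, gb1), aa, bb = smith_waterman(
                qq[qlo:qhi], s[ws:we], scheme, band=band)
            if gscore > score:
                score, qa, qb = gscore, qlo + ga0, qlo + ga1
                sa, sb = ws + gb0, ws + gb1
                aq, asub = aa, bb
            else:
                aq = qq[qa:qb]
                asub = s[sa:sb]
        else:
            aq = qq[qa:qb]
            asub = s[sa:sb]
        if scheme.evalue(score, m, n_eff) > scheme.e_max:
            continue
        if strand == "+":
            q_iv = GenomicInterval(qid, qa, qb, "+")
        else:
            q_iv = GenomicInterval(qid, m - qb, m - qa, "+")
        hit = LocalHit(
            query_interval=q_iv,
            subject_interval=GenomicInterval(sid, sa, sb, "+"),
            strand=strand,
            raw_score=int(score),
            e_value=scheme.evalue(score, m, n_eff),
            identity_pct=_residue_identity(aq, asub),
            aligned_query=aq,
            aligned_subject=asub,
        )
        hits.append(hit)

    if not cull:
        hits.sort(key=lambda x: (x.subject_interval.start,
                                 x.subject_interval.end, x.strand))
        return hits
    return _cull(hits)


def _cull(hits: list[LocalHit], min_frac: float = 0.5) -> list[LocalHit]:
    """Keep the best-scoring hit among same-strand hits overlapping >= min_frac."""
    kept: list[LocalHit] = []
    for h in sorted(hits, key=lambda x: (-x.raw_score, x.subject_interval.start,
                                         x.strand, x.query_interval.start)):
        redundant = False
        for k in kept:
            if k.strand != h.strand:
                continue
            ov = (min(k.subject_interval.end, h.subject_interval.end)
                  - max(k.subject_interval.start, h.subject_interval.start))
            if ov > 0 and ov >= min_frac * min(k.subject_interval.length,
                                               h.subject_interval.length):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    kept.sort(key=lambda x: (x.subject_interval.start, x.subject_interval.end,
                             x.strand))
    return kept
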