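"""Target-site duplications, empty-site reconstruction, and in-silico PCR.

Element integration duplicates its target sequence, leaving a short direct
repeat immediately flanking the element (8-10 bp in this family, most
commonly 9 bp).  The pre-insertion locus ("empty site") carries a single
copy of the target; reconstructing it and predicting primer products is the
computational counterpart of the empty-site PCR assay.
"""
from __future__ import annotations

from dataclasses import dataclass

from .seqio import GenomicInterval, SequenceRecord, reverse_complement

TSD_LEN_RANGE = (7, 12)     # searched; 8-10 canonical, 7 seen at nested inserts
TSD_MAX_MISMATCH = 1
TSD_FLANK = 15              # bp of flank inspected on each side
PREFERRED_TSD_LEN = 9


@dataclass(frozen=True)
class TsdCall:
    status: str                      # "found" | "n.f." | "n.a."
    length: int = 0
    left_seq: str = ""
    right_seq: str = ""
    mismatch_positions: tuple[int, ...] = ()
    left_interval: GenomicInterval | None = None
    right_interval: GenomicInterval | None = None

    @property
    def found(self) -> bool:
        return self.status == "found"


TSD_NA = TsdCall(status="n.a.")
TSD_NF = TsdCall(status="n.f.")


@dataclass(frozen=True)
class PcrProduct:
    template_id: str
    fwd_interval: GenomicInterval    # footprint of the forward primer
    rev_interval: GenomicInterval    # footprint of the reverse primer
    product_length: int              # 5' end to 5' end, inclusive

    @property
    def fwd_5prime(self) -> int:
        return self.fwd_interval.start

    @property
    def rev_5prime(self) -> int:
        return self.rev_interval.end - 1


#: Primer table (name -> 5'->3' sequence) pre-loaded for the family's assays.
PRIMERS = {
    "a5": "GAGCCGTCCATTTTAAACCA",
    "a6": "GGGTTAAGGTTGTTGTTGCC",
    "SG1": "CGAGAATTCTACACTGACAATG",
    "SG2": "ACTGAATCGTCCCCTTTTCC",
    "SG6": "GATTCAGTATACGGGGAAAAGG",
    "M8-1F": "TGGCTTTCTATATGTTTTTCATGC",
    "M8-3R": "GTAAGTTGCTGTCAGTGCAAGG",
    "M8-6R": "TCAGAATCTGCCAAAAGAAACC",
    "MjActin RT-F": "AAGCCGTTCTTTCTTTGTATGC",
    "MjActin RT-R": "AAGAATAACCACGTTCAGTGAGG",
    "Mj bActin-F": "TAGGTATGTTGCCATCCAAGC",
    "Mj bActin-R": "CAAAGCAGTAATTTCCTTCTGC",
    "17-F": "AGAGCTCGGGACTGAAACGTCC",
    "17-R": "TCTCCCTCGCCTCATCTCCACG",
}


def detect_tsd(left_flank: str, right_flank: str,
               len_range: tuple[int, int] = TSD_LEN_RANGE,
               max_mismatch: int = TSD_MAX_MISMATCH,
               motifs_present: bool = True) -> TsdCall:
    """Direct-repeat search in the flanks immediately outside the element.

    One copy must end immediately before the left terminal motif
    (``left_flank`` suffix) and one begin immediately after the right motif
    (``right_flank`` prefix).  Candidates are scored by length minus
    mismatches; ties break toward length 9, then longer.  Returns status
    ``n.a.`` when a terminal motif is missing (duplication boundaries are
    then undefined) and ``n.f.`` when no candidate meets the mismatch budget.
    """
    if not motifs_present:
        return TSD_NA
    lo, hi = len_range
    best: tuple[tuple[float, int, int], TsdCall] | None = None
    for L in range(lo, hi + 1):
        if L > len(left_flank) or L > len(right_flank):
            continue
        left = left_flank[-L:]
        right = right_flank[:L]
        mism = tuple(i for i, (x, y) in enumerate(zip(left, right)) if x != y)
        if len(mism) > max_mismatch:
            continue
        score = L - len(mism)
        key = (score, -abs(L - PREFERRED_TSD_LEN), L)
        call = TsdCall("found", L, left, right, mism)
        if best is None or key > best[0]:
            best = (key, call)
    return best[1] if best else TSD_NF


def reconstruct_empty_site(contig: SequenceRecord, element_span: GenomicInterval,
                           tsd: TsdCall) -> SequenceRecord:
    """Excise the element plus one duplication copy, modelling the
    pre-insertion locus.

    The element span excludes the duplications; the right copy is removed
    together with the element so a single target copy (the left one)
    remains.
    """
    if not tsd.found:
        raise ValueError(f"cannot reconstruct empty site: TSD status {tsd.status}")
    s, e = element_span.start, element_span.end
    residues = contig.residues[:s] + contig.residues[e + tsd.length:]
    return SequenceRecord(id=f"{contig.id}_empty", residues=residues,
                          description=f"empty site of element at {s + 1}-{e}")


def insert_element(empty: SequenceRecord, position: int, element_seq: str,
                   tsd_seq: str) -> SequenceRecord:
    """Inverse of :func:`reconstruct_empty_site` for round-trip checks.

    ``position`` is where the element starts in the reconstituted contig,
    i.e. the end of the single retained target copy.
    """
    res = empty.residues
    out = res[:position] + element_seq + tsd_seq + res[position:]
    return SequenceRecord(id=empty.id.removesuffix("_empty") or empty.id,
                          residues=out)


def _match_positions(template: str, primer: str, max_mismatch: int,
                     anchor: int, anchor_at_end: bool) -> list[tuple[int, int]]:
    """(start, mismatches) of primer occurrences; the 3'-anchor bases exact."""
    L = len(primer)
    out = []
    for i in range(len(template) - L + 1):
        window = template[i:i + L]
        if anchor_at_end:
            if window[L - anchor:] != primer[L - anchor:]:
                continue
        else:
            if window[:anchor] != primer[:anchor]:
                continue
        mm = sum(x != y for x, y in zip(window, primer))
        if mm <= max_mismatch:
            out.append((i, mm))
    return out


def in_silico_pcr(template: SequenceRecord | str, fwd_primer: str, rev_primer: str,
                  max_mismatch: int = 2, anchor_3prime: int = 3,
                  max_product: int = 20_000) -> list[PcrProduct]:
    """All convergent primer placements and their inclusive product lengths.

    Product length runs from the forward primer's 5' end to the reverse
    primer's 5' end inclusive (gel-size convention).  Each primer may carry
    at most ``max_mismatch`` mismatches but must match exactly over its
    3'-terminal ``anchor_3prime`` bases.
    """
    tid = template.id if isinstance(template, SequenceRecord) else "template"
    seq = template.residues if isinstance(template, SequenceRecord) else template
    for p in (fwd_primer, rev_primer):
        if len(p) < 15:
            raise ValueError("primers must be >= 15 nt")
    fwd_sites = _match_positions(seq, fwd_primer, max_mismatch, anchor_3prime, True)
    rev_rc = reverse_complement(rev_primer)
    # on the template, the reverse primer's 3' end corresponds to the START
    # of the reverse-complemented occurrence
    rev_sites = _match_positions(seq, rev_rc, max_mismatch, anchor_3prime, False)
    products = []
    for fi, _ in fwd_sites:
        for ri, _ in rev_sites:
            rev5 = ri + len(rev_primer) - 1
            length = rev5 - fi + 1
            if length < len(fwd_primer) + len(rev_primer):
                continue  # non-convergent or overlapping placements
            if length > max_product:
                continue
            products.append(PcrProduct(
                template_id=tid,
                fwd_interval=GenomicInterval(tid, fi, fi + len(fwd_primer), "+"),
                rev_interval=GenomicInterval(tid, ri, ri + len(rev_primer), "-"),
                product_length=length,
            ))
    products.sort(key=lambda p: (p.fwd_interval.start, p.rev_interval.start))
    return products
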