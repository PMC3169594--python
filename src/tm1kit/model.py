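"""Element records: the pipeline's central annotated-element container."""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .classify import ClassLabel, NestedInsertion
from .seqio import GenomicInterval
from .tir import ElementAnnotation, MotifCall, MotifCUnit
from .tsd import TsdCall


@dataclass(frozen=True)
class TirAnnotation:
    """Motif grammar annotation in contig coordinates."""

    left_tir: GenomicInterval
    right_tir: GenomicInterval
    motif_a1: MotifCall
    motif_a2: MotifCall
    motif_b_left: MotifCall
    motif_b_right: MotifCall
    motif_d_left: MotifCall
    motif_d_right: MotifCall
    c_units_left: tuple[MotifCUnit, ...]
    c_units_right: tuple[MotifCUnit, ...]
    tir_identity_pct: float
    a2_both_ends: bool = False


@dataclass
class ElementRecord:
    """A called and annotated element.

    ``span`` covers the element from the outermost base of the left terminal
    motif to the outermost base of the right one (target-site duplications
    excluded); ``strand`` is '-' when the element was flipped so that Motif
    A1 reads on the left.  ``sequence`` is the oriented element sequence.
    """

    contig_id: str
    span: GenomicInterval
    sequence: str
    tir: TirAnnotation | None = None
    tsd: TsdCall | None = None
    class_label: ClassLabel | None = None
    pairing_score: float = 0.0
    nested_in: int | None = None
    nested_insertions: list[NestedInsertion] = field(default_factory=list)
    annotation: ElementAnnotation | None = None

    @property
    def internal_seq(self) -> str:
        if self.annotation is None:
            return ""
        return self.annotation.internal_seq


def _map_interval(window_start: int, window_len: int, flipped: bool,
                  contig_id: str, s: int, e: int, strand: str = "+") -> GenomicInterval:
    """Map an interval in the (possibly flipped) window to contig coordinates."""
    if not flipped:
        return GenomicInterval(contig_id, window_start + s, window_start + e, strand)
    return GenomicInterval(
        contig_id,
        window_start + window_len - e,
        window_start + window_len - s,
        "-" if strand == "+" else "+",
    )


def build_element_record(contig_id: str, window_start: int,
                         ann: ElementAnnotation,
                         pairing_score: float = 0.0,
                         nested_in: int | None = None) -> ElementRecord:
    """Assemble a contig-coordinate :class:`ElementRecord` from a window
    annotation."""
    wl = len(ann.seq)
    f = ann.flipped

    def iv(pair: tuple[int, int], strand: str = "+") -> GenomicInterval:
        return _map_interval(window_start, wl, f, contig_id, pair[0], pair[1], strand)

    span = iv((ann.element_start, ann.element_end))
    span = replace(span, strand="-" if f else "+")

    def map_units(units: tuple[MotifCUnit, ...], tir_local: tuple[int, int],
                  rc_frame: bool) -> tuple[MotifCUnit, ...]:
        # units are in TIR-local coordinates; the right TIR was annotated on
        # the reverse complement, so its frame runs inward from the TIR end
        out = []
        ts, te = tir_local
        for u in units:
            if not rc_frame:
                s, e = ts + u.interval.start, ts + u.interval.end
            else:
                s, e = te - u.interval.end, te - u.interval.start
            out.append(replace(u, interval=iv((s, e), "-" if rc_frame else "+")))
        return tuple(out)

    tir = TirAnnotation(
        left_tir=iv(ann.left_tir),
        right_tir=iv(ann.right_tir),
        motif_a1=ann.a1,
        motif_a2=ann.a2,
        motif_b_left=ann.b_left,
        motif_b_right=ann.b_right,
        motif_d_left=ann.d_left,
        motif_d_right=ann.d_right,
        c_units_left=map_units(ann.c_left, ann.left_tir, rc_frame=False),
        c_units_right=map_units(ann.c_right, ann.right_tir, rc_frame=True),
        tir_identity_pct=ann.tir_identity_pct,
        a2_both_ends=ann.a2_both_ends,
    )
    return ElementRecord(
        contig_id=contig_id,
        span=span,
        sequence=ann.element_seq,
        tir=tir,
        pairing_score=pairing_score,
        nested_in=nested_in,
        annotation=ann,
    )
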