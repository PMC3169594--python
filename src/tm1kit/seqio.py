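"""Sequence and annotation I/O with fixed coordinate conventions.

Internally every interval is 0-based half-open on the forward strand of its
contig.  Everything written for human consumption (GFF3, per-element tables)
is converted to 1-based inclusive coordinates, which is also how element
locations are conventionally reported for draft nematode assemblies.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("tm1kit")

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class DuplicateIdError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A contig or single sequence record over the {A,C,G,T,N} alphabet."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_1based(self) -> tuple[int, int]:
        """Convert to 1-based inclusive (GFF3 columns 4 and 5)."""
        return self.start + 1, self.end

    @classmethod
    def from_1based(cls, contig_id: str, start1: int, end1: int, strand: str = "+") -> "GenomicInterval":
        return cls(contig_id, start1 - 1, end1, strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start <= other.start
            and other.end <= self.end
        )

    def shifted(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)


def normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase and degrade non-ACGTN IUPAC codes to N (draft assemblies pass)."""
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - ALPHABET
    if bad:
        logger.warning(
            "record %s: %d ambiguity characters (%s) mapped to N",
            record_id,
            sum(seq.count(c) for c in bad),
            "".join(sorted(bad)),
        )
        seq = "".join(c if c in ALPHABET else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Raises on an empty file and on duplicate record ids; lowercase residues
    are uppercased and ambiguity codes other than N are mapped to N with a
    logged warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=normalize_residues(str(rec.seq), rec.id),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N; errors on other characters."""
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# annotation writers
# ---------------------------------------------------------------------------

from . import __version__ as _VERSION  # noqa: E402  (simple constant import)


def parameter_hash(params: dict) -> str:
    text = ";".join(f"{k}={params[k]}" for k in sorted(params))
    return hashlib.sha1(text.encode()).hexdigest()[:12]


def _header_comment(params: dict | None) -> str:
    h = parameter_hash(params or {})
    return f"tm1kit v{_VERSION} parameter-hash={h}"


def _check_bounds(elements, contig_lengths: dict[str, int] | None) -> None:
    if contig_lengths is None:
        return
    for el in elements:
        clen = contig_lengths.get(el.span.contig_id)
        if clen is not None and el.span.end > clen:
            raise ValueError(
                f"element span {el.span} exceeds contig length {clen}"
            )


def write_gff3(elements: Sequence, path: str | Path, params: dict | None = None,
               contig_lengths: dict[str, int] | None = None) -> None:
    """Write elements plus their TIR / motif / TSD children as GFF3.

    ``elements`` are duck-typed element records carrying ``span``, and
    optionally ``tir``, ``tsd``, ``class_label`` attributes (see
    :mod:`tm1kit.model`).
    """
    _check_bounds(elements, contig_lengths)
    lines = ["##gff-version 3", f"# {_header_comment(params)}"]
    for k, el in enumerate(elements):
        eid = f"element{k:04d}"
        s1, e1 = el.span.to_1based()
        attrs = [f"ID={eid}"]
        label = getattr(el, "class_label", None)
        if label is not None:
            attrs.append(f"class={label.label}")
            attrs.append("evidence=" + ",".join(label.evidence))
        if getattr(el, "nested_in", None) is not None:
            attrs.append(f"nested_in={el.nested_in}")
        lines.append(
            "\t".join(
                [el.span.contig_id, "tm1kit", "transposable_element",
                 str(s1), str(e1), ".", el.span.strand, ".", ";".join(attrs)]
            )
        )
        tir = getattr(el, "tir", None)
        if tir is not None:
            for side, iv in (("left", tir.left_tir), ("right", tir.right_tir)):
                ts, te = iv.to_1based()
                lines.append(
                    "\t".join(
                        [iv.contig_id, "tm1kit", "terminal_inverted_repeat",
                         str(ts), str(te), ".", iv.strand, ".",
                         f"ID={eid}.tir_{side};Parent={eid}"]
                    )
                )
            for side, units in (("left", tir.c_units_left), ("right", tir.c_units_right)):
                for u, unit in enumerate(units):
                    us, ue = unit.interval.to_1based()
                    lines.append(
                        "\t".join(
                            [unit.interval.contig_id, "tm1kit", "repeat_unit",
                             str(us), str(ue), f"{unit.identity_to_consensus:.1f}",
                             unit.interval.strand, ".",
                             f"ID={eid}.motifC_{side}_{u};Parent={eid}.tir_{side}"]
                        )
                    )
        tsd = getattr(el, "tsd", None)
        if tsd is not None and tsd.status == "found":
            for side, iv in (("left", tsd.left_interval), ("right", tsd.right_interval)):
                if iv is None:
                    continue
                ds, de = iv.to_1based()
                lines.append(
                    "\t".join(
                        [iv.contig_id, "tm1kit", "target_site_duplication",
                         str(ds), str(de), ".", "+", ".",
                         f"ID={eid}.tsd_{side};Parent={eid}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(elements: Sequence, path: str | Path, params: dict | None = None,
              contig_lengths: dict[str, int] | None = None) -> None:
    """BED6, 0-based half-open, score column = pairing score if available."""
    _check_bounds(elements, contig_lengths)
    lines = [f"# {_header_comment(params)}"]
    for k, el in enumerate(elements):
        label = getattr(el, "class_label", None)
        name = label.label if label is not None else f"element{k:04d}"
        score = getattr(el, "pairing_score", 0.0) or 0.0
        lines.append(
            "\t".join(
                [el.span.contig_id, str(el.span.start), str(el.span.end),
                 name, f"{min(1000, int(score))}", el.span.strand]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


TSV_COLUMNS = [
    "contig", "start", "end", "strand", "length", "class",
    "left_tir_len", "right_tir_len", "tir_identity_pct",
    "c_units_left", "c_units_right",
    "motif_a1", "motif_a2", "motif_b_left", "motif_b_right",
    "motif_d_left", "motif_d_right",
    "tsd_status", "tsd_length", "tsd_left", "tsd_right",
    "nested_insertions",
]


def write_element_tsv(elements: Sequence, path: str | Path, params: dict | None = None,
                      contig_lengths: dict[str, int] | None = None) -> None:
    """Per-element table using the family's status vocabulary.

    ``n.a.`` (not analyzed) marks a TSD that was not sought because one or
    both terminal motifs is missing; ``n.f.`` (not found) marks a terminus or
    TSD that was sought but absent.
    """
    _check_bounds(elements, contig_lengths)
    lines = [f"# {_header_comment(params)}", "\t".join(TSV_COLUMNS)]
    for el in elements:
        s1, e1 = el.span.to_1based()
        tir = getattr(el, "tir", None)
        tsd = getattr(el, "tsd", None)
        label = getattr(el, "class_label", None)

        def motif(call) -> str:
            if call is None or call.status != "present":
                return "n.f."
            return call.sequence

        row = {
            "contig": el.span.contig_id,
            "start": s1,
            "end": e1,
            "strand": el.span.strand,
            "length": el.span.length,
            "class": label.label if label is not None else ".",
            "left_tir_len": tir.left_tir.length if tir else ".",
            "right_tir_len": tir.right_tir.length if tir else ".",
            "tir_identity_pct": f"{tir.tir_identity_pct:.2f}" if tir else ".",
            "c_units_left": len(tir.c_units_left) if tir else ".",
            "c_units_right": len(tir.c_units_right) if tir else ".",
            "motif_a1": motif(tir.motif_a1) if tir else "n.f.",
            "motif_a2": motif(tir.motif_a2) if tir else "n.f.",
            "motif_b_left": motif(tir.motif_b_left) if tir else "n.f.",
            "motif_b_right": motif(tir.motif_b_right) if tir else "n.f.",
            "motif_d_left": motif(tir.motif_d_left) if tir else "n.f.",
            "motif_d_right": motif(tir.motif_d_right) if tir else "n.f.",
            "tsd_status": tsd.status if tsd else "n.a.",
            "tsd_length": tsd.length if tsd and tsd.status == "found" else ".",
            "tsd_left": tsd.left_seq if tsd and tsd.status == "found" else ".",
            "tsd_right": tsd.right_seq if tsd and tsd.status == "found" else ".",
            "nested_insertions": len(getattr(el, "nested_insertions", []) or []),
        }
        lines.append("\t".join(str(row[c]) for c in TSV_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotations(elements: Sequence, path: str | Path, fmt: str = "gff3",
                      params: dict | None = None,
                      contig_lengths: dict[str, int] | None = None) -> None:
    fmt = fmt.lower()
    if fmt == "gff3":
        write_gff3(elements, path, params, contig_lengths)
    elif fmt == "bed":
        write_bed(elements, path, params, contig_lengths)
    elif fmt == "tsv":
        write_element_tsv(elements, path, params, contig_lengths)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
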