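"""Synthetic genomes with planted grammar-built elements and full truth.

The generator assembles elements from the composite-TIR grammar
(``A1 B C^n D C payload rc(C D C^m B) A2``, with Motif D and its flanking C
unit dropped for MITE-like elements), plants them at non-overlapping
positions in a uniform-composition background with 8-10 bp target-site
duplications (weighted toward 9 bp), applies tunable element-wise
divergence, and records complete ground truth for recovery scoring.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .classify import HAIRPIN_CONSENSUS
from .seqio import GenomicInterval, SequenceRecord, reverse_complement
from .tir import INCOGNITA, MotifProfile

_BASES = np.array(list("ACGT"))

#: Default class mix, proportioned after the family's composition in the
#: asexual root-knot nematode genome (1 autonomous : 8 hairpin : 30 MITE-like
#: of 39, with small D/other admixture for generality).
DEFAULT_CLASS_MIX = {
    "Tm1-A": 0.05,
    "Tm1-D": 0.10,
    "Tm1-HH": 0.20,
    "Tm1-ML": 0.55,
    "other": 0.10,
}

#: Mean of the (shifted) Poisson draw for Motif C units per TIR.  The family
#: averages ~4.3 units per TIR (334 units over 39 elements; 238 over 22), so
#: counts are drawn as 1 + Poisson(3.3) clipped to the observed 1-9 range.
C_UNIT_POISSON_MEAN = 3.3

TSD_LENGTHS = (8, 9, 10)
TSD_WEIGHTS = (0.2, 0.6, 0.2)

MULE_REGION = (900, 1500)
REFERENCE_LENGTH = 2300


@dataclass(frozen=True)
class MutationModel:
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    indel_mean_length: float = 2.0   # geometric mean length, capped at 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate <= 0.3):
            raise ValueError("substitution_rate must be in [0, 0.3]")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


@dataclass(frozen=True)
class Tm1Grammar:
    profile: MotifProfile = INCOGNITA
    c_units_min: int = 1
    c_units_max: int = 9
    hairpin: str = HAIRPIN_CONSENSUS
    ml_arm_length: int = 60
    ml_spacer_range: tuple[int, int] = (120, 250)
    hh_payload_range: tuple[int, int] = (650, 850)
    other_payload_range: tuple[int, int] = (500, 800)
    d_fragment_range: tuple[int, int] = (200, 600)


@dataclass
class ElementTruth:
    contig_id: str
    span: GenomicInterval
    strand: str
    class_label: str
    tsd_length: int
    tsd_seq: str
    c_units_left: int
    c_units_right: int
    element_seq: str
    nested: tuple[tuple[int, int], ...] = ()


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def build_reference(rng: np.random.Generator) -> tuple[SequenceRecord, dict[str, tuple[int, int]]]:
    """Synthetic transposase-interior reference with a designated MULE region.

    A stand-in constructed for classification tests; regions mimic the
    layout used for autonomy calling (5' part, MULE domain, 3' part).
    """
    seq = _random_seq(rng, REFERENCE_LENGTH)
    regions = {
        "5prime": (0, MULE_REGION[0]),
        "MULE_domain": MULE_REGION,
        "3prime": (MULE_REGION[1], REFERENCE_LENGTH),
    }
    return SequenceRecord(id="reference_interior", residues=seq,
                          description="synthetic transposase interior"), regions


def _draw_c_units(rng: np.random.Generator, grammar: Tm1Grammar) -> int:
    n = 1 + rng.poisson(C_UNIT_POISSON_MEAN)
    return int(min(max(n, grammar.c_units_min), grammar.c_units_max))


def build_element(grammar: Tm1Grammar, cls: str, rng: np.random.Generator,
                  reference: SequenceRecord | None = None) -> tuple[str, dict]:
    """Assemble one element (TSDs excluded) plus its grammar bookkeeping."""
    p = grammar.profile
    with_d = cls != "Tm1-ML"
    total_left = _draw_c_units(rng, grammar)
    total_right = _draw_c_units(rng, grammar)
    if with_d:
        total_left = max(total_left, 2)
        total_right = max(total_right, 2)

    if cls == "Tm1-A":
        if reference is None:
            raise ValueError("Tm1-A requires a reference interior")
        payload = reference.residues
    elif cls == "Tm1-D":
        if reference is None:
            raise ValueError("Tm1-D requires a reference interior")
        lo, hi = grammar.d_fragment_range
        length = int(rng.integers(lo, hi + 1))
        start_lo, start_hi = MULE_REGION[1], len(reference) - length
        start = int(rng.integers(start_lo, max(start_lo + 1, start_hi + 1)))
        payload = reference.residues[start:start + length]
    elif cls == "Tm1-HH":
        lo, hi = grammar.hh_payload_range
        length = int(rng.integers(lo, hi + 1))
        payload = _random_seq(rng, length)
        pos = length - int(rng.integers(100, 141))
        payload = payload[:pos] + grammar.hairpin + payload[pos + len(grammar.hairpin):]
    elif cls == "Tm1-ML":
        arm = _random_seq(rng, grammar.ml_arm_length)
        lo, hi = grammar.ml_spacer_range
        spacer = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        payload = arm + spacer + reverse_complement(arm)
    elif cls == "other":
        lo, hi = grammar.other_payload_range
        payload = _random_seq(rng, int(rng.integers(lo, hi + 1)))
    else:
        raise ValueError(f"unknown element class {cls!r}")

    if with_d:
        left_block = p.b + p.c * (total_left - 1) + p.d + p.c
        right_block_fwd = p.b + p.c * (total_right - 1) + p.d + p.c
    else:
        left_block = p.b + p.c * total_left
        right_block_fwd = p.b + p.c * total_right
    seq = p.a1 + left_block + payload + reverse_complement(right_block_fwd) + p.a2
    truth = {
        "class": cls,
        "c_units_left": total_left,
        "c_units_right": total_right,
        "payload_length": len(payload),
    }
    return seq, truth


def mutate(seq: str, model: MutationModel, rng: np.random.Generator) -> str:
    """Apply per-site substitutions and short indels."""
    if model.substitution_rate <= 0 and model.indel_rate <= 0:
        return seq
    out: list[str] = []
    bases = "ACGT"
    for ch in seq:
        if model.indel_rate > 0 and rng.random() < model.indel_rate:
            L = int(min(10, 1 + rng.geometric(1.0 / model.indel_mean_length)))
            if rng.random() < 0.5:
                continue                     # deletion of this base (length 1)
            out.append(_random_seq(rng, L))  # insertion before this base
        if model.substitution_rate > 0 and rng.random() < model.substitution_rate:
            alt = bases.replace(ch, "") if ch in bases else bases
            out.append(alt[rng.integers(0, len(alt))])
        else:
            out.append(ch)
    return "".join(out)


def plant_elements(genome_length: int, n_elements: int,
                   grammar: Tm1Grammar = Tm1Grammar(),
                   mutation: MutationModel = MutationModel(),
                   rng_seed: int = 0,
                   class_mix: dict[str, float] | None = None,
                   contig_id: str = "synth_contig",
                   nested_rate: float = 0.0,
                   ) -> tuple[SequenceRecord, list[ElementTruth],
                              SequenceRecord, dict[str, tuple[int, int]]]:
    """Plant ``n_elements`` grammar-built elements in a random background.

    Returns (genome, truth list, reference interior, reference regions).
    Background composition is i.i.d. uniform ACGT; insertion points are
    non-overlapping; each insertion duplicates its target site by the drawn
    TSD length; divergence is applied per element after assembly.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    mix = class_mix or DEFAULT_CLASS_MIX
    names = sorted(mix)
    weights = np.array([mix[n] for n in names], dtype=float)
    weights /= weights.sum()
    reference, regions = build_reference(rng)

    classes = [names[k] for k in rng.choice(len(names), size=n_elements, p=weights)]
    built = []
    for cls in classes:
        seq, info = build_element(grammar, cls, rng, reference)
        nested_spans: list[tuple[int, int]] = []
        if nested_rate > 0 and rng.random() < nested_rate:
            seq, nested_spans = _plant_nested(seq, rng)
        seq = mutate(seq, mutation, rng)
        built.append((cls, seq, info, tuple(nested_spans)))

    total_planted = sum(len(s) for _, s, _, _ in built)
    if total_planted >= genome_length / 2:
        raise ValueError(
            f"planted length {total_planted} exceeds half the genome "
            f"({genome_length})")

    background = _random_seq(rng, genome_length)
    margin = 50
    points: list[int] = []
    for _ in range(n_elements):
        for _attempt in range(1000):
            p = int(rng.integers(margin, genome_length - margin))
            if all(abs(p - q) >= 40 for q in points):
                points.append(p)
                break
        else:
            raise RuntimeError("could not place elements without overlap")
    order = np.argsort(points)

    pieces: list[str] = []
    truths: list[ElementTruth] = []
    prev = 0
    offset = 0
    for idx in order:
        cls, eseq, info, nested_spans = built[idx]
        p = points[idx]
        L = int(rng.choice(TSD_LENGTHS, p=TSD_WEIGHTS))
        tsd = background[p:p + L]
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = eseq if strand == "+" else reverse_complement(eseq)
        pieces.append(background[prev:p + L])
        start = p + L + offset
        pieces.append(inserted)
        truths.append(ElementTruth(
            contig_id=contig_id,
            span=GenomicInterval(contig_id, start, start + len(inserted), strand),
            strand=strand,
            class_label=cls,
            tsd_length=L,
            tsd_seq=tsd,
            c_units_left=info["c_units_left"],
            c_units_right=info["c_units_right"],
            element_seq=eseq,
            nested=nested_spans,
        ))
        offset += len(inserted) + L
        prev = p
    pieces.append(background[prev:])
    genome = SequenceRecord(id=contig_id, residues="".join(pieces),
                            description=f"synthetic genome, {n_elements} planted elements")
    truths.sort(key=lambda t: t.span.start)
    return genome, truths, reference, regions


def _plant_nested(element_seq: str, rng: np.random.Generator,
                  insert_len: int = 900, tsd_len: int = 7) -> tuple[str, list[tuple[int, int]]]:
    """Insert an unrelated inverted-repeat element (own TSD) into the payload."""
    arm = _random_seq(rng, 80)
    core = arm + _random_seq(rng, insert_len - 160) + reverse_complement(arm)
    lo = len(element_seq) // 3
    hi = 2 * len(element_seq) // 3
    p = int(rng.integers(lo, hi))
    tsd = element_seq[p:p + tsd_len]
    out = element_seq[:p + tsd_len] + core + element_seq[p:]
    return out, [(p + tsd_len, p + tsd_len + len(core))]


# ---------------------------------------------------------------------------
# truth serialisation and recovery scoring
# ---------------------------------------------------------------------------

def truth_to_gff3(truths: list[ElementTruth], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for k, t in enumerate(truths):
        s1, e1 = t.span.to_1based()
        attrs = (f"ID=truth{k:04d};class={t.class_label};tsd_length={t.tsd_length};"
                 f"tsd_seq={t.tsd_seq};c_units_left={t.c_units_left};"
                 f"c_units_right={t.c_units_right}")
        lines.append("\t".join([t.contig_id, "tm1kit-sim", "transposable_element",
                                str(s1), str(e1), ".", t.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


def truth_from_gff3(path: str | Path) -> list[ElementTruth]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
        span = GenomicInterval.from_1based(cols[0], int(cols[3]), int(cols[4]), cols[6])
        out.append(ElementTruth(
            contig_id=cols[0], span=span, strand=cols[6],
            class_label=attrs["class"], tsd_length=int(attrs["tsd_length"]),
            tsd_seq=attrs.get("tsd_seq", ""),
            c_units_left=int(attrs.get("c_units_left", 0)),
            c_units_right=int(attrs.get("c_units_right", 0)),
            element_seq="",
        ))
    return out


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    boundary_mae: float
    tsd_accuracy: float
    class_accuracy: float
    n_truth: int
    n_called: int
    n_matched: int

    def as_dict(self) -> dict:
        return asdict(self)


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.contig_id != b.contig_id:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def evaluate_recovery(truths: list[ElementTruth], called,
                      min_reciprocal_overlap: float = 0.8) -> RecoveryMetrics:
    """Match called elements to planted truth and score the recovery.

    A called element matches a truth element when their reciprocal overlap
    is at least ``min_reciprocal_overlap``; matching is greedy by overlap.
    Boundary MAE, TSD-length accuracy and class accuracy are computed over
    matched pairs.
    """
    pairs = []
    for ti, t in enumerate(truths):
        for ci, c in enumerate(called):
            ov = _reciprocal_overlap(t.span, c.span)
            if ov >= min_reciprocal_overlap:
                pairs.append((ov, ti, ci))
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_c: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, ti, ci in pairs:
        if ti in used_t or ci in used_c:
            continue
        used_t.add(ti)
        used_c.add(ci)
        matches.append((ti, ci))

    n_t, n_c, n_m = len(truths), len(called), len(matches)
    if n_m:
        mae = float(np.mean([
            (abs(truths[ti].span.start - called[ci].span.start)
             + abs(truths[ti].span.end - called[ci].span.end)) / 2.0
            for ti, ci in matches]))
        tsd_acc = float(np.mean([
            1.0 if (getattr(called[ci], "tsd", None) is not None
                    and called[ci].tsd.found
                    and called[ci].tsd.length == truths[ti].tsd_length) else 0.0
            for ti, ci in matches]))
        cls_acc = float(np.mean([
            1.0 if (getattr(called[ci], "class_label", None) is not None
                    and called[ci].class_label.label == truths[ti].class_label)
            else 0.0
            for ti, ci in matches]))
    else:
        mae, tsd_acc, cls_acc = float("nan"), 0.0, 0.0
    return RecoveryMetrics(
        precision=n_m / n_c if n_c else (1.0 if n_t == 0 else 0.0),
        recall=n_m / n_t if n_t else 1.0,
        boundary_mae=mae,
        tsd_accuracy=tsd_acc,
        class_accuracy=cls_acc,
        n_truth=n_t, n_called=n_c, n_matched=n_m,
    )
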