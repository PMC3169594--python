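"""End-to-end orchestration: discover -> delineate -> annotate -> TSD ->
classify -> summarize.

The programmatic entry point is :func:`run_analysis` (in-memory records in,
annotated elements and family summaries out); :func:`run_pipeline` wraps it
with config validation and file output for the command-line interface.  All
randomness (bootstrap resampling) flows from the single config seed, and a
rerun with an identical config writes byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .align import PRESETS, TIR_DELINEATION, LocalScoringScheme
from .classify import (ClassifyThresholds, ElementFeatures, HAIRPIN_CONSENSUS,
                       classify_element, detect_internal_ir, reference_similarity,
                       scan_histone_hairpin, scan_orfs)
from .discovery import (MAX_SPAN_DEFAULT, MERGE_WINDOW_DEFAULT, MIN_SPAN_DEFAULT,
                        CandidateElement, call_elements, cluster_hits,
                        find_tir_seeds)
from .model import ElementRecord, build_element_record
from .seqio import (GenomicInterval, SequenceRecord, read_fasta,
                    write_bed, write_element_tsv, write_gff3)
from .summary import (align_motif_instances, bootstrap_support, compute_logo,
                      group_identity, motif_c_length_histogram,
                      summarize_classes)
from .tir import PROFILES, SEED_QUERY, annotate_element_window
from .tsd import TSD_FLANK, detect_tsd

logger = logging.getLogger("tm1kit")

#: bp of genomic context taken on each side of a candidate span for TIR
#: delineation; seed clusters can start a full repeat array (9 units plus
#: the inner motif block and terminal motifs, ~170 bp) inside the element
#: edge, and the terminal motifs and TSD lie outside the seed hits
WINDOW_FLANK = 200


@dataclass
class PipelineConfig:
    genome: str = ""                      # FASTA path
    query: str = SEED_QUERY
    profile: str = "incognita"
    preset: str = "seed-search"
    merge_window: int = MERGE_WINDOW_DEFAULT
    min_span: int = MIN_SPAN_DEFAULT
    max_span: int = MAX_SPAN_DEFAULT
    flank: int = WINDOW_FLANK
    reference: str = ""                   # FASTA path of classification reference
    reference_regions: str = ""           # side-car table: name start end (1-based)
    hairpin_profile: str = HAIRPIN_CONSENSUS
    min_orf_aa: int = 100
    bootstrap_replicates: int = 100
    seed: int = 0
    out_prefix: str = "tm1kit_out"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    elements: list[ElementRecord]
    counts: dict[str, int]
    class_table: "object" = None          # pandas DataFrame
    motif_c_hist: dict[int, int] = field(default_factory=dict)
    logos: dict[str, "object"] = field(default_factory=dict)
    ml_tree_newick: str = ""
    ml_group_identity: float = float("nan")
    mean_tir_identity: float = float("nan")


def _read_regions(path: str) -> dict[str, tuple[int, int]]:
    regions = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, s, e = line.split()[:3]
        regions[name] = (int(s) - 1, int(e))
    return regions


def annotate_candidate(contig: SequenceRecord, cand: CandidateElement,
                       profile, flank: int = WINDOW_FLANK,
                       preset: LocalScoringScheme = TIR_DELINEATION,
                       nested_in: int | None = None) -> ElementRecord | None:
    """Window out one candidate, resolve TIRs and the motif grammar.

    Returns ``None`` when the terminal self-comparison cannot resolve a TIR
    pair (the candidate is dropped, mirroring manual curation of seed-hit
    pairs that are not actually inverted repeats of each other).
    """
    w0 = max(0, cand.outer_span.start - flank)
    w1 = min(len(contig), cand.outer_span.end + flank)
    window = contig.residues[w0:w1]
    left_anchor = (cand.left_cluster.span.start - w0, cand.left_cluster.span.end - w0)
    right_anchor = (cand.right_cluster.span.start - w0, cand.right_cluster.span.end - w0)
    ann = annotate_element_window(window, profile, preset,
                                  left_anchor=left_anchor,
                                  right_anchor=right_anchor)
    if ann is None:
        return None
    rec = build_element_record(contig.id, w0, ann,
                               pairing_score=cand.pairing_score,
                               nested_in=nested_in)
    return rec


def call_tsd(contig: SequenceRecord, rec: ElementRecord) -> None:
    """Attach the TSD call for an element (n.a. when a terminus is missing)."""
    ann = rec.annotation
    motifs_present = (ann is not None and ann.left_terminal.present
                      and ann.right_terminal.present)
    s, e = rec.span.start, rec.span.end
    left = contig.residues[max(0, s - TSD_FLANK):s]
    right = contig.residues[e:e + TSD_FLANK]
    tsd = detect_tsd(left, right, motifs_present=motifs_present)
    if tsd.found:
        tsd = dataclasses.replace(
            tsd,
            left_interval=GenomicInterval(contig.id, s - tsd.length, s, "+"),
            right_interval=GenomicInterval(contig.id, e, e + tsd.length, "+"),
        )
    rec.tsd = tsd


def classify_elements(elements: list[ElementRecord],
                      reference: SequenceRecord | None = None,
                      regions: dict[str, tuple[int, int]] | None = None,
                      thresholds: ClassifyThresholds = ClassifyThresholds(),
                      hairpin_profile: str | None = HAIRPIN_CONSENSUS,
                      min_orf_aa: int = 100) -> None:
    """Compute features and assign one class label per element (in place)."""
    if reference is None:
        logger.warning("no classification reference supplied: "
                       "Tm1-A / Tm1-D are unreachable")
    for rec in elements:
        internal = rec.internal_seq
        hairpins = scan_histone_hairpin(internal, profile=hairpin_profile) \
            if len(internal) >= 16 else []
        ir = detect_internal_ir(internal) if internal else None
        orfs = scan_orfs(internal, min_aa=min_orf_aa) if internal else []
        cov = None
        if reference is not None and regions:
            cov = reference_similarity(internal, reference, regions)
        ann = rec.annotation
        d_present = (ann is not None
                     and (ann.d_left.present or ann.d_right.present))
        features = ElementFeatures(
            internal_length=len(internal),
            hairpin_hits=hairpins,
            internal_ir=ir,
            orfs=orfs,
            coverage=cov,
            motif_d_present=d_present,
        )
        rec.class_label = classify_element(features, thresholds)


def summarize_family(elements: list[ElementRecord], profile,
                     bootstrap_replicates: int = 100, seed: int = 0) -> dict:
    """Family-level outputs: class table, unit-length histogram, logos,
    MITE-like group identity and NJ consensus tree."""
    out: dict = {}
    out["class_table"] = summarize_classes(elements)
    hist, mode = motif_c_length_histogram(elements)
    out["motif_c_hist"] = dict(sorted(hist.items()))
    out["motif_c_mode"] = mode
    out["motif_c_total"] = sum(hist.values())

    tirs = [e.tir for e in elements if e.tir is not None]
    if tirs:
        out["mean_tir_identity"] = float(np.mean([t.tir_identity_pct for t in tirs]))

    logos = {}
    c_instances = []
    for e in elements:
        if e.tir is None:
            continue
        for units in (e.tir.c_units_left, e.tir.c_units_right):
            c_instances.extend(u.sequence for u in units)
    if len(c_instances) >= 2:
        # cap the logo alignment at a fixed-size deterministic subset
        c_instances = sorted(c_instances)[:120]
        logos["motif_c"] = compute_logo(align_motif_instances(c_instances))
    a1 = sorted(e.tir.motif_a1.sequence for e in elements
                if e.tir and e.tir.motif_a1.present)
    if len(a1) >= 2:
        logos["motif_a1"] = compute_logo(list(a1))
    a2 = sorted(e.tir.motif_a2.sequence for e in elements
                if e.tir and e.tir.motif_a2.present)
    if len(a2) >= 2:
        logos["motif_a2"] = compute_logo(list(a2))
    d = sorted(m.sequence for e in elements if e.tir
               for m in (e.tir.motif_d_left, e.tir.motif_d_right) if m.present)
    if len(d) >= 2:
        logos["motif_d"] = compute_logo(list(d))
    out["logos"] = logos

    ml = [e for e in elements
          if e.class_label is not None and e.class_label.label == "Tm1-ML"]
    if len(ml) >= 2:
        out["ml_group_identity"] = group_identity([e.sequence for e in ml])
    if len(ml) >= 3:
        labels = [f"ML_{e.contig_id}_{e.span.start}" for e in ml]
        msa = align_motif_instances([e.sequence for e in ml])
        tree = bootstrap_support(msa, labels, replicates=bootstrap_replicates,
                                 seed=seed)
        out["ml_tree_newick"] = str(tree).strip()
    return out


def run_analysis(genome: list[SequenceRecord], query: str = SEED_QUERY,
                 profile_name: str = "incognita",
                 preset: LocalScoringScheme | str = "seed-search",
                 merge_window: int = MERGE_WINDOW_DEFAULT,
                 min_span: int = MIN_SPAN_DEFAULT,
                 max_span: int = MAX_SPAN_DEFAULT,
                 flank: int = WINDOW_FLANK,
                 reference: SequenceRecord | None = None,
                 regions: dict[str, tuple[int, int]] | None = None,
                 hairpin_profile: str | None = HAIRPIN_CONSENSUS,
                 min_orf_aa: int = 100,
                 bootstrap_replicates: int = 100,
                 seed: int = 0,
                 summarize: bool = True) -> PipelineResult:
    """Run the full annotation pipeline on in-memory records."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    profile = PROFILES[profile_name]
    contigs = {r.id: r for r in genome}

    hits_by_contig = find_tir_seeds(genome, query, preset)
    n_hits = sum(len(v) for v in hits_by_contig.values())
    candidates: list[CandidateElement] = []
    n_clusters = 0
    for contig_id in sorted(hits_by_contig):
        clusters = cluster_hits(hits_by_contig[contig_id], merge_window)
        n_clusters += len(clusters)
        candidates.extend(call_elements(clusters, min_span, max_span))

    elements: list[ElementRecord] = []
    unresolved = 0
    for k, cand in enumerate(candidates):
        rec = annotate_candidate(contigs[cand.contig_id], cand, profile, flank,
                                 nested_in=k if cand.nested else None)
        if rec is None:
            unresolved += 1
            continue
        call_tsd(contigs[cand.contig_id], rec)
        elements.append(rec)

    classify_elements(elements, reference, regions,
                      hairpin_profile=hairpin_profile, min_orf_aa=min_orf_aa)

    counts = {
        "seed_hits": n_hits,
        "clusters": n_clusters,
        "candidates": len(candidates),
        "tirs_unresolved": unresolved,
        "elements": len(elements),
        "tsd_found": sum(1 for e in elements if e.tsd and e.tsd.status == "found"),
        "tsd_nf": sum(1 for e in elements if e.tsd and e.tsd.status == "n.f."),
        "tsd_na": sum(1 for e in elements if e.tsd and e.tsd.status == "n.a."),
    }
    for e in elements:
        if e.class_label:
            key = f"class_{e.class_label.label}"
            counts[key] = counts.get(key, 0) + 1
    logger.info("pipeline counts: %s", counts)

    result = PipelineResult(elements=elements, counts=counts)
    if summarize and elements:
        s = summarize_family(elements, profile, bootstrap_replicates, seed)
        result.class_table = s.get("class_table")
        result.motif_c_hist = s.get("motif_c_hist", {})
        result.logos = s.get("logos", {})
        result.ml_tree_newick = s.get("ml_tree_newick", "")
        result.ml_group_identity = s.get("ml_group_identity", float("nan"))
        result.mean_tir_identity = s.get("mean_tir_identity", float("nan"))
    return result


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based pipeline run; writes GFF3/BED/TSV, summary tables,
    logo matrices, a Newick tree and a JSON run log under ``out_prefix``."""
    if not config.genome:
        raise ValueError("config error: no genome path supplied")
    genome_path = Path(config.genome)
    if not genome_path.exists():
        raise ValueError(f"config error: genome {genome_path} does not exist")
    if config.profile not in PROFILES:
        raise ValueError(f"config error: unknown motif profile {config.profile!r}")
    if config.preset not in PRESETS:
        raise ValueError(f"config error: unknown preset {config.preset!r}")
    genome = read_fasta(genome_path)
    reference = None
    regions = None
    if config.reference:
        reference = read_fasta(config.reference)[0]
        if config.reference_regions:
            regions = _read_regions(config.reference_regions)
        else:
            regions = {"full": (0, len(reference))}

    result = run_analysis(
        genome, query=config.query, profile_name=config.profile,
        preset=config.preset, merge_window=config.merge_window,
        min_span=config.min_span, max_span=config.max_span,
        flank=config.flank, reference=reference, regions=regions,
        hairpin_profile=config.hairpin_profile or None,
        min_orf_aa=config.min_orf_aa,
        bootstrap_replicates=config.bootstrap_replicates, seed=config.seed,
    )

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    params = config.as_dict()
    # the header hash covers analysis parameters only, so reruns into a
    # different output location stay byte-identical
    params.pop("out_prefix", None)
    contig_lengths = {r.id: len(r) for r in genome}
    write_gff3(result.elements, f"{prefix}.gff3", params, contig_lengths)
    write_bed(result.elements, f"{prefix}.bed", params, contig_lengths)
    write_element_tsv(result.elements, f"{prefix}.tsv", params, contig_lengths)
    if result.class_table is not None:
        result.class_table.to_csv(f"{prefix}.classes.tsv", sep="\t", index=False)
    with open(f"{prefix}.motif_c_hist.tsv", "w") as fh:
        fh.write("unit_length\tcount\n")
        for L, c in sorted(result.motif_c_hist.items()):
            fh.write(f"{L}\t{c}\n")
    for name, logo in result.logos.items():
        logo.to_frame().to_csv(f"{prefix}.logo_{name}.tsv", sep="\t")
    if result.ml_tree_newick:
        Path(f"{prefix}.ml_tree.nwk").write_text(result.ml_tree_newick + "\n")
    log = {"version": __version__, "config": params, "counts": result.counts}
    Path(f"{prefix}.run.json").write_text(json.dumps(log, indent=2) + "\n")
    return result
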