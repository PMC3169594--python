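"""Candidate element discovery from TIR seed hits.

The core detection rule: two or more seed hits on the same contig in opposite
orientation delimit a candidate element.  Because each composite TIR is a
tandem array of ~14 bp repeat units, one TIR often spawns several seed hits;
same-strand hits are therefore merged into clusters first, and clusters of
opposite orientation are paired into candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import SEED_SEARCH, LocalHit, LocalScoringScheme, seeded_local_search
from .seqio import GenomicInterval, SequenceRecord

logger = logging.getLogger("tm1kit")

MERGE_WINDOW_DEFAULT = 200     # bp; merges within-TIR multi-hits
MIN_SPAN_DEFAULT = 100         # bp; family elements run ~0.17-2.5 kb
MAX_SPAN_DEFAULT = 10_000      # headroom for nested insertions
SPAN_PENALTY_PER_KB = 1.0


@dataclass(frozen=True)
class HitCluster:
    contig_id: str
    strand: str
    span: GenomicInterval
    member_hits: tuple[LocalHit, ...]
    best_score: int


@dataclass(frozen=True)
class CandidateElement:
    contig_id: str
    outer_span: GenomicInterval
    left_cluster: HitCluster
    right_cluster: HitCluster
    pairing_score: float
    ambiguous: bool = False
    nested: bool = False


def find_tir_seeds(genome: list[SequenceRecord], tir_query: str | SequenceRecord,
                   scheme: LocalScoringScheme = SEED_SEARCH) -> dict[str, list[LocalHit]]:
    """Search every contig for the TIR seed query; hits grouped per contig.

    E-values use the total genome length as the subject search space, so hit
    significance matches a genome-wide search.
    """
    if not genome:
        raise ValueError("empty genome")
    total_n = sum(len(r) for r in genome)
    out: dict[str, list[LocalHit]] = {}
    n_hits = 0
    for rec in genome:
        hits = seeded_local_search(tir_query, rec, scheme, search_space_n=total_n)
        if hits:
            out[rec.id] = hits
            n_hits += len(hits)
    logger.info("seed search: %d hits on %d/%d contigs", n_hits, len(out), len(genome))
    return out


def cluster_hits(hits: list[LocalHit], merge_window: int = MERGE_WINDOW_DEFAULT) -> list[HitCluster]:
    """Single-linkage merge of same-strand hits within ``merge_window`` bp.

    The inter-hit distance is the gap between subject intervals (0 when they
    touch or overlap).  Hits must come from one contig.
    """
    clusters: list[HitCluster] = []
    for strand in ("+", "-"):
        sh = sorted((h for h in hits if h.strand == strand),
                    key=lambda h: (h.subject_interval.start, h.subject_interval.end))
        group: list[LocalHit] = []
        for h in sh:
            if group and h.subject_interval.start - max(
                    g.subject_interval.end for g in group) > merge_window:
                clusters.append(_make_cluster(group, strand))
                group = []
            group.append(h)
        if group:
            clusters.append(_make_cluster(group, strand))
    clusters.sort(key=lambda c: (c.span.start, c.span.end, c.strand))
    return clusters


def _make_cluster(group: list[LocalHit], strand: str) -> HitCluster:
    contig = group[0].subject_interval.contig_id
    start = min(h.subject_interval.start for h in group)
    end = max(h.subject_interval.end for h in group)
    return HitCluster(
        contig_id=contig,
        strand=strand,
        span=GenomicInterval(contig, start, end, strand),
        member_hits=tuple(group),
        best_score=max(h.raw_score for h in group),
    )


def call_elements(clusters: list[HitCluster],
                  min_span: int = MIN_SPAN_DEFAULT,
                  max_span: int = MAX_SPAN_DEFAULT) -> list[CandidateElement]:
    """Pair opposite-orientation clusters into candidate elements.

    Because the tandem units of a composite TIR have fixed polarity, the
    seed query matches the left TIR of an element on the plus strand and
    the right TIR on the minus strand regardless of element orientation
    (the element is structurally near-palindromic).  Plus clusters
    therefore open elements and minus clusters close them, and the correct
    pairing structure is laminar — nested or disjoint, never crossing —
    the structure of balanced parentheses.  The emitted set is the
    maximum-total-score laminar matching (interval dynamic programming
    within blocks of clusters separated by more than ``max_span``).  The
    laminar constraint is what keeps the facing TIRs of adjacent elements
    from pairing into a chimera, and score maximisation is what stops a
    weak spurious hit inside a long element from stealing its left TIR
    (which a plain last-in-first-out scan is vulnerable to).
    """
    if not clusters:
        return []
    contig = clusters[0].contig_id
    ordered = sorted(clusters, key=lambda c: (c.span.start, c.span.end,
                                              c.strand))

    def pair_score(a: HitCluster, b: HitCluster) -> float | None:
        if a.strand != "+" or b.strand != "-":
            return None
        if a.span.start >= b.span.start:
            return None
        span_len = b.span.end - a.span.start
        if not (min_span <= span_len <= max_span):
            return None
        s = (a.best_score + b.best_score
             - SPAN_PENALTY_PER_KB * span_len / 1000.0)
        return s if s > 0 else None

    # independent blocks: clusters further apart than max_span never pair
    blocks: list[list[HitCluster]] = []
    for c in ordered:
        if blocks and c.span.start - blocks[-1][-1].span.end <= max_span:
            blocks[-1].append(c)
        else:
            blocks.append([c])

    selected: list[CandidateElement] = []
    for block in blocks:
        m = len(block)
        F = [[0.0] * (m + 1) for _ in range(m + 1)]   # F[i][j], j exclusive
        choice: dict[tuple[int, int], int] = {}
        for length in range(2, m + 1):
            for i in range(0, m - length + 1):
                j = i + length
                best = F[i + 1][j]
                pick = -1
                for k in range(i + 1, j):
                    # starts are sorted: once out of pairing range, stay out
                    if block[k].span.start - block[i].span.start > max_span:
                        break
                    s = pair_score(block[i], block[k])
                    if s is None:
                        continue
                    total = s + F[i + 1][k] + F[k + 1][j]
                    if total > best + 1e-9:
                        best = total
                        pick = k
                F[i][j] = best
                if pick >= 0:
                    choice[(i, j)] = pick

        def emit(i: int, j: int) -> None:
            while i < j:
                k = choice.get((i, j), -1)
                if k < 0:
                    i += 1
                    continue
                a, b = block[i], block[k]
                selected.append(CandidateElement(
                    contig_id=contig,
                    outer_span=GenomicInterval(contig, a.span.start,
                                               b.span.end),
                    left_cluster=a, right_cluster=b,
                    pairing_score=float(pair_score(a, b)),
                ))
                emit(i + 1, k)
                i = k + 1

        emit(0, m)
    selected.sort(key=lambda c: (-c.pairing_score,
                                 c.outer_span.start, c.outer_span.end))

    # containment -> nested flag; partial overlap -> keep the better score
    final: list[CandidateElement] = []
    for cand in selected:
        nested = False
        conflict = False
        for kept in final:
            if kept.outer_span.contains(cand.outer_span):
                nested = True
            elif cand.outer_span.overlaps(kept.outer_span):
                conflict = True
                break
        if conflict:
            continue
        final.append(CandidateElement(
            contig_id=cand.contig_id, outer_span=cand.outer_span,
            left_cluster=cand.left_cluster, right_cluster=cand.right_cluster,
            pairing_score=cand.pairing_score, nested=nested,
        ))
    final.sort(key=lambda c: (c.outer_span.start, c.outer_span.end))
    return final


def discover(genome: list[SequenceRecord], tir_query: str | SequenceRecord,
             scheme: LocalScoringScheme = SEED_SEARCH,
             merge_window: int = MERGE_WINDOW_DEFAULT,
             min_span: int = MIN_SPAN_DEFAULT,
             max_span: int = MAX_SPAN_DEFAULT) -> list[CandidateElement]:
    """find_tir_seeds + cluster_hits + call_elements over a whole genome."""
    by_contig = find_tir_seeds(genome, tir_query, scheme)
    candidates: list[CandidateElement] = []
    for contig_id in sorted(by_contig):
        clusters = cluster_hits(by_contig[contig_id], merge_window)
        candidates.extend(call_elements(clusters, min_span, max_span))
    logger.info("called %d candidate elements", len(candidates))
    return candidates
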