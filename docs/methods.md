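# Methods

`tm1kit` annotates a family of *Foldback/Mutator*-like DNA transposons
(the Tm1 family of root-knot nematodes) whose defining feature is a
composite terminal inverted repeat (TIR) built from a small motif grammar,
and whose integration leaves 8–10 bp target-site duplications (TSDs).
This note records the model, the algorithmic choices, the synthetic data
the package tests itself against, and the known limitations.

## The element model

An element, read left to right with TSDs excluded, is

    A1 · B · C^n · D · C · payload · rc(C · D · C^m · B) · A2

- **A1 / A2** — asymmetric 7 bp terminal motifs *outside* the inverted
  repeat (consensus `CGGTTAA` / `CCTACCC` for the *M. incognita* profile;
  `CGGATAA` for A1 in the *M. hapla* profile). Either may be absent in a
  degenerate copy; one recombinant configuration carries A2 at both ends.
- **B** — a 3 bp spacer (`GGA`) immediately internal to each terminal
  motif.
- **C** — a ~14 bp tandem repeat (core consensus `CGATTCAGTATCGC`;
  `CGTTTCAGTATCGC` in the *M. hapla* profile), 1–9 consecutive units per
  TIR, with copy number differing freely between the two ends of one
  element. Observed unit lengths run 8–21 bp. The literature also prints a
  15 bp variant of this consensus (`CGATTCAGTATCCGC`); the 14 bp core is
  the default and the discrepancy is a documented ambiguity, not resolved
  here.
- **D** — a purine-rich 12 bp motif (`GGGAAAAGGGGA` core) at the inner end
  of the TIR, followed by one further C unit. MITE-like elements lack D
  and its flanking C unit.

Element classes: **Tm1-A** (autonomous; interior matches a supplied
transposase reference including its MULE-domain region), **Tm1-D**
(deletion derivatives; interior patches match the reference 3′ of the MULE
domain, the domain itself lost), **Tm1-HH** (interior carries a histone
stem-loop), **Tm1-ML** (short, MITE-like: interior inverted repeat, no
Motif D), and **other**.

## Pipeline

1. **Seed search.** A 38 bp TIR query (one C unit, Motif D, one C unit) is
   searched against every contig with a word-seeded local aligner
   (word 7, match +1, mismatch −3, gap open 4 / extend 2, E ≤ 10,
   DUST-style low-complexity masking of the query seeds). E-values use
   ungapped Karlin–Altschul statistics with the total genome length as the
   search space.
2. **Candidate calling.** Same-strand hits within 200 bp merge into
   clusters (one TIR commonly spawns several phase-shifted hits).
   Opposite-orientation cluster pairs spanning 100 bp – 10 kb become
   candidates. Because the C array has fixed polarity, a left TIR always
   matches the query on plus and a right TIR on minus, for either element
   orientation; pairing therefore requires plus-before-minus, which
   removes chimeric pairings between the facing TIRs of adjacent elements.
   The emitted set is the maximum-total-score laminar matching — nested
   or disjoint, never crossing, the structure of balanced parentheses —
   computed by interval dynamic programming within blocks of clusters
   separated by more than the span limit (pairing score: cluster scores
   minus a mild span penalty). The laminar constraint alone is not enough:
   a weak spurious seed hit inside a long element would otherwise steal
   its left TIR under nearest-partner pairing, and plain greedy selection
   can prefer or tie on a chimera bridging two adjacent elements; score
   maximisation under the laminar constraint avoids both. Pairs strictly
   inside a selected pair are emitted as nested candidates.
3. **TIR delineation.** Each candidate window (±200 bp of context) is
   aligned against its own reverse complement (word 11, +1/−2, open 5 /
   extend 2). The best self-hit anchored near both seed clusters defines
   the TIR pair and the TIR–TIR identity. Each arm is then trimmed to its
   contiguous motif-grammar run: MITE-like elements are near-palindromic
   end to end, so the self-alignment otherwise chains through the
   payload's own inverted repeat and absorbs it into the TIRs. Candidates
   whose self-comparison resolves no TIR pair are dropped — the automated
   equivalent of curating seed-hit pairs that are not actually inverted
   repeats of each other. This filter is what keeps precision exact on
   random backgrounds despite the lenient E ≤ 10 seed threshold.
4. **Motif annotation.** The TIR is segmented into C units, D, and
   unexplained residues by dynamic programming minimising total edit cost
   (unit cost = edit distance to the consensus, unit length 8–21,
   rejection above 4 edits for C and 2 for D; skipped residues cost 1).
   The segmentation is a partition: segments tile the TIR exactly.
   Terminal motifs are sought within a small jitter window outside the
   recovered repeat array (≤1 mismatch of 7 bp; B must match exactly at
   its length of 3). When the inverted reading of the termini is strictly
   better supported, the element is reverse-complemented so A1 reads on
   the left; A2-at-both-ends is reported and flagged, not "fixed".
5. **TSD calling.** The direct repeat must end immediately before the
   left terminal motif and begin immediately after the right one; lengths
   7–12 are scored as length minus mismatches (budget 1), ties break
   toward the canonical 9 bp, then longer. Elements missing a terminal
   motif are recorded `n.a.` (not analyzed); a sought-but-absent repeat is
   `n.f.` (not found). Empty-site reconstruction excises the element plus
   one duplication copy; in-silico PCR reports products 5′-end to 5′-end
   inclusive, with a mandatory exact 3′ anchor of 3 bases per primer.
6. **Classification.** First matching rule wins:
   (1) reference coverage ≥ 0.8 overall and ≥ 0.5 over the MULE region →
   Tm1-A; (2) any non-MULE region covered ≥ 0.2 with MULE coverage < 0.1 →
   Tm1-D; (3) histone hairpin present → Tm1-HH; (4) interior inverted
   repeat and interior ≤ 600 bp → Tm1-ML; (5) other. Thresholds are
   calibrated against the family's published class-size envelopes and are
   all configurable.
7. **Family summaries.** Class count/mean-length table, Motif C length
   histogram with mode, per-motif sequence logos (information content
   2 − H − e(n) bits with the small-sample correction e(n) = 3/(2·ln2·n),
   consensus shown only where bits > 0), mean pairwise group identity of
   the MITE-like class, and a neighbor-joining tree of MITE-like elements
   with column-resampling bootstrap support (majority-rule counts on the
   original topology; 100 replicates by default, seed mandatory).

## Alignment engines

The seeded local search performs exact-word seeding on both strands,
ungapped X-drop extension (X-drop 20), then an exact affine-gap local
optimisation in a ±250 bp window around each surviving seed. The windowed
re-optimisation is a conservative variant of gapped X-drop extension whose
result provably equals the full Smith–Waterman optimum whenever the
optimum lies within the window — in particular on the ≤200 bp pairs the
test suite checks against an exhaustive oracle. Overlapping same-strand
hits are culled keeping the best score. Gaps cost open + L·extend
throughout the package.

The global aligner is Gotoh's affine-gap algorithm with cost-free
terminal gaps, row-vectorised; the horizontal gap state is computed with a
running-maximum scan so each row is a few array operations. Tie-breaking
is fixed — prefer diagonal, then a gap in the second sequence, then a gap
in the first; among equal terminal cells the one nearest the corner — so
identity percentages are bit-reproducible. Percent identity excludes
end-gap columns by default; internal gap columns count against identity.

Karlin–Altschul (λ, K) are tabulated for the two preset schemes (+1/−3:
1.374, 0.711; +1/−2: 1.330, 0.621; ungapped values, uniform base
composition). Other schemes solve λ numerically; K falls back to an
approximate 0.35 and is only used where a raw-score floor, not the
E-value, carries the significance decision.

Three scheme choices are deliberate and worth recording. Interior
inverted-repeat detection uses +1/−2 (word 7, raw-score floor 20, E-value
disabled): a −3 penalty fragments a 60 bp repeat arm at ~10% arm-to-arm
divergence into sub-floor pieces, while a −1 penalty lets the two arms
chain through the spacer into one self-spanning alignment; −2 does
neither, and the floor of 20 sits far above the ~8 random expectation for
payload-sized self-comparisons. Reference-coverage projection runs
ungapped-only (gap placement cannot change which reference bases are
covered, and it keeps long scans cheap). Nested-insertion detection
aligns element to exemplar with gap extension reduced to 1 per column,
because at the default costs a kilobase internal gap is dearer than
discarding the flanking matches into a free end gap, which would hide the
insertion; the insertion's own TSD is then sought by sliding the gap
boundary through the duplication-induced placement ambiguity.

## Hairpin detection

The histone stem-loop scan is structural (stem 6–10 bp, loop 3–6 nt,
≤2 stem mismatches) with an optional profile rescore. The pipeline
supplies a built-in 16 nt canonical metazoan stem-loop profile
(`GGCTCTTTTCAGAGCC`, ≤4 mismatches): a purely structural scan accepts a
chance stem-loop every few hundred bp, which would overwhelm rule 3 of
the classifier on short payloads, while the profile brings the chance
rate to ~10⁻⁵ per window. Users with their own hairpin model can pass a
different profile or none.

## Synthetic genomes and ground truth

The generator assembles elements from the grammar above and plants them
at non-overlapping positions in an i.i.d. uniform-ACGT background,
duplicating the target site by a TSD length drawn from {8, 9, 10} with
weights {0.2, 0.6, 0.2}. C-unit counts per TIR are drawn as
1 + Poisson(3.3) clipped to [1, 9], matching the family's published
average of ~4.3 units per TIR; ends are drawn independently. Class
payloads: Tm1-A carries a synthetic 2.3 kb "transposase interior"
reference with a designated MULE region (900–1500); Tm1-D a 200–600 bp
fragment from 3′ of that region; Tm1-HH a 650–850 bp random payload with
the canonical hairpin written in ~100–140 bp from its 3′ end; Tm1-ML a
60 bp arm + 120–250 bp spacer + reverse-complement arm (and no Motif D);
"other" a 500–800 bp random payload. Orientation is a fair coin.
Divergence is applied per element after assembly: per-site substitutions
at the configured rate, optional short indels (insertions up to 10 bp,
single-base deletions). TSDs are host sequence and are not mutated.
Nested insertions (off by default) plant an unrelated ~900 bp
inverted-repeat element with its own 7 bp TSD inside the payload.

What this emulates — and what it does not: uniform background makes
false-positive analysis clean (the real host genome is AT-rich and far
more repetitive); elements never overlap; divergence is i.i.d. rather
than age-structured; there is no segmental duplication or assembly error.
Perfect scores at zero divergence therefore demonstrate correctness of
the machinery, not expected field performance on a draft assembly.  Note
also that synthetic MITE-like elements draw their payloads independently,
so their group identity reflects only the shared TIR grammar (roughly
55-60%) — unlike a real family, whose members are homologous.

Study conditions: 50 elements / 280 kb at zero divergence, where
precision, recall, TSD-length accuracy and class accuracy are 1.0 and
boundary error is 0 bp; and 200 elements / 1.1 Mb at 5% substitutions,
where recall ≥ 0.9 and class accuracy ≥ 0.9 (both hold with margin in the
seeded test suite; the residual misses are elements whose short
single-unit TIRs genuinely drop below the word-7 seeding floor at that
divergence).

## Numerical and degenerate-input choices

- Internal coordinates are 0-based half-open; all reported coordinates
  1-based inclusive. Conversion is bijective and tested.
- Non-ACGTN input characters degrade to N with a logged warning; N never
  matches anything, including another N.
- DUST masking uses 16 bp windows and threshold 2.0 on the triplet
  statistic; masking suppresses seeding only, never extension.
- The motif-unit multiple alignment is center-star under the stated
  tandem-repeat gap costs scaled ×3 to stay integral (match 15, mismatch
  −12, open 45, extend 20) — exactly reproducible and adequate for ≤16 bp
  units and family-sized element sets; it is not a general-purpose MSA.
- Neighbor joining breaks Q-criterion ties toward the lexicographically
  lowest pair of smallest member labels; the final edge hangs a leaf off
  the internal node with its full length.
- An all-end-gap (fully staggered) free-end alignment reports identity 0
  rather than erroring; `percent_identity` itself errors on zero counted
  columns.
- Empty FASTA files and duplicate record ids are hard errors; an empty
  element list writes valid header-only annotation files; "no elements
  found" is a valid pipeline result, not an error.

## Limitations

- Autonomy calling is reference-coverage based; without a supplied
  reference interior the Tm1-A and Tm1-D classes are unreachable (logged).
- The E-value model is ungapped; gapped-alignment statistics are not
  emulated, and a raw-score floor stands in where the E-value would be
  misleading.
- The published survey's genome-scale numbers (seed-hit totals, element
  counts per species, the specific record-level PCR product lengths)
  require the cited public assemblies and records as local input; the
  acceptance test for them states exactly which files it expects.
- Protein-domain search, transcript modelling and anything wet-lab are
  out of scope.
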