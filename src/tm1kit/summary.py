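"""Family-level statistics: motif alignments, logos, class tables, trees.

Multiple alignment uses a deterministic center-star built on the
free-end-gap pairwise engine; sequence logos report per-column information
content in bits with an optional small-sample correction; distance trees use
a hand-rolled neighbor-joining with fixed tie-breaking, serialised through
scikit-bio's tree container.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .align import GlobalScoringScheme, global_align_free_end, percent_identity

#: Tandem-repeat (motif instance) alignment costs.  The classic progressive
#: aligner costs (gap open 15, extend 6.66 against its default DNA matrix)
#: are scaled by 3 to stay integral: match 15, mismatch -12, open 45,
#: extend 20.
MOTIF_MSA_SCHEME = GlobalScoringScheme(match=15, mismatch=-12, gap_open=45, gap_extend=20)


# ---------------------------------------------------------------------------
# center-star multiple alignment
# ---------------------------------------------------------------------------

def align_motif_instances(instances: list[str],
                          scheme: GlobalScoringScheme = MOTIF_MSA_SCHEME) -> list[str]:
    """Center-star progressive multiple alignment (deterministic).

    The center is the instance minimising its summed pairwise distance
    (100 - identity); all others are aligned to it pairwise and merged under
    "once a gap, always a gap".  Adequate and exactly reproducible for short
    motif units and family-sized element sets.
    """
    if not instances:
        return []
    if len(instances) == 1:
        return list(instances)
    n = len(instances)
    dist_sum = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align_free_end(instances[i], instances[j], scheme)
            d = 100.0 - aln.identity_pct
            dist_sum[i] += d
            dist_sum[j] += d
    center = min(range(n), key=lambda k: (dist_sum[k], k))

    master = list(instances[center])          # center row, with merged gaps
    rows: list[list[str]] = [None] * n        # type: ignore[list-item]
    rows[center] = master

    aligned_others: list[tuple[int, list[str], list[str]]] = []
    for i in range(n):
        if i == center:
            continue
        aln = global_align_free_end(instances[center], instances[i], scheme)
        aligned_others.append((i, list(aln.aligned_a), list(aln.aligned_b)))

    # merge: maintain master gap pattern; insert new gaps into all rows
    for idx, c_aln, s_aln in aligned_others:
        merged_row: list[str] = []
        mi = 0   # index into master
        ai = 0   # index into c_aln/s_aln
        new_master: list[str] = []
        existing_rows = [r for r in rows if r is not None]
        inserts: list[int] = []  # master positions where a gap must be inserted
        while mi < len(master) or ai < len(c_aln):
            mc = master[mi] if mi < len(master) else None
            ac = c_aln[ai] if ai < len(c_aln) else None
            if mc == "-" and (ac is None or ac != "-"):
                # master has a gap the pairwise alignment lacks
                merged_row.append("-")
                new_master.append("-")
                mi += 1
            elif ac == "-" and (mc is None or mc != "-"):
                # pairwise alignment inserts a gap into the center
                inserts.append(len(new_master))
                new_master.append("-")
                merged_row.append(s_aln[ai])
                ai += 1
            else:
                new_master.append(mc if mc is not None else "-")
                merged_row.append(s_aln[ai] if ac is not None else "-")
                mi += 1
                ai += 1
        for r in existing_rows:
            for pos in inserts:
                r.insert(pos, "-")
        master = new_master
        rows[idx] = merged_row
        # pad any short rows (defensive; lengths should already agree)
        for r in rows:
            if r is not None:
                while len(r) < len(master):
                    r.append("-")
    return ["".join(r) for r in rows]  # type: ignore[arg-type]


def sp_score(msa: list[str], scheme: GlobalScoringScheme = MOTIF_MSA_SCHEME) -> int:
    """Sum-of-pairs score of an MSA (terminal gaps free, per pairwise row)."""
    from .align import alignment_score, LocalScoringScheme

    total = 0
    n = len(msa)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = _strip_common_gaps(msa[i], msa[j])
            a, b = _strip_end_gap_cols(a, b)
            if not a:
                continue
            total += _pair_score(a, b, scheme)
    return total


def _strip_common_gaps(a: str, b: str) -> tuple[str, str]:
    keep = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
    return "".join(x for x, _ in keep), "".join(y for _, y in keep)


def _strip_end_gap_cols(a: str, b: str) -> tuple[str, str]:
    s, e = 0, len(a)
    while s < e and (a[s] == "-" or b[s] == "-"):
        s += 1
    while e > s and (a[e - 1] == "-" or b[e - 1] == "-"):
        e -= 1
    return a[s:e], b[s:e]


def _pair_score(a: str, b: str, scheme: GlobalScoringScheme) -> int:
    score = 0
    k = 0
    while k < len(a):
        if a[k] == "-" or b[k] == "-":
            which = a if a[k] == "-" else b
            run = 0
            while k < len(a) and which[k] == "-":
                run += 1
                k += 1
            score -= scheme.gap_open + run * scheme.gap_extend
        else:
            score += scheme.match if a[k] == b[k] else scheme.mismatch
            k += 1
    return score


# ---------------------------------------------------------------------------
# sequence logos
# ---------------------------------------------------------------------------

_BASES = "ACGT"


@dataclass(frozen=True)
class LogoMatrix:
    counts: np.ndarray            # shape (4, width), base order ACGT
    bits: np.ndarray              # shape (width,)
    consensus: str                # '-' where bits == 0
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts.T, columns=list(_BASES))
        df["bits"] = self.bits
        df["consensus"] = list(self.consensus)
        df.index.name = "column"
        return df


def compute_logo(msa: list[str], correction: bool = True) -> LogoMatrix:
    """Per-column information content, 2 - (H + e(n)) bits, floored at 0.

    The small-sample correction is e(n) = 3 / (2 ln2 n) with n the number of
    non-gap residues in the column; consensus letters are emitted only where
    the corrected information is positive.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(r) != width for r in msa):
        raise ValueError("ragged alignment")
    counts = np.zeros((4, width), dtype=int)
    for row in msa:
        for j, c in enumerate(row):
            k = _BASES.find(c)
            if k >= 0:
                counts[k, j] += 1
    bits = np.zeros(width)
    consensus = []
    for j in range(width):
        n = counts[:, j].sum()
        if n == 0:
            consensus.append("-")
            continue
        p = counts[:, j] / n
        h = -sum(pi * math.log2(pi) for pi in p if pi > 0)
        e = 3.0 / (2.0 * math.log(2) * n) if correction else 0.0
        b = max(0.0, 2.0 - h - e)
        bits[j] = b
        consensus.append(_BASES[int(np.argmax(counts[:, j]))] if b > 0 else "-")
    return LogoMatrix(counts=counts, bits=bits, consensus="".join(consensus),
                      n_sequences=len(msa))


# ---------------------------------------------------------------------------
# family tables
# ---------------------------------------------------------------------------

def motif_c_length_histogram(elements) -> tuple[Counter, int | None]:
    """Counts of Motif C unit lengths over all TIRs; returns (counts, mode)."""
    counts: Counter = Counter()
    for el in elements:
        tir = getattr(el, "tir", None)
        if tir is None:
            continue
        for units in (tir.c_units_left, tir.c_units_right):
            for u in units:
                counts[u.length] += 1
    mode = counts.most_common(1)[0][0] if counts else None
    return counts, mode


def summarize_classes(elements) -> pd.DataFrame:
    """Class count and mean element length table (totals row included)."""
    rows = []
    for el in elements:
        label = el.class_label.label if getattr(el, "class_label", None) else "unclassified"
        rows.append((label, el.span.length))
    df = pd.DataFrame(rows, columns=["class", "length"])
    if df.empty:
        return pd.DataFrame(columns=["class", "count", "mean_length"])
    out = (df.groupby("class")
             .agg(count=("length", "size"), mean_length=("length", "mean"))
             .reset_index())
    out["mean_length"] = out["mean_length"].round().astype(int)
    total = pd.DataFrame([{"class": "Total", "count": int(out["count"].sum()),
                           "mean_length": int(round(df["length"].mean()))}])
    return pd.concat([out, total], ignore_index=True)


def group_identity(seqs: list[str]) -> float:
    """Mean pairwise free-end-gap identity over all unordered pairs."""
    if len(seqs) < 2:
        raise ValueError("group identity needs >= 2 sequences")
    vals = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            vals.append(global_align_free_end(seqs[i], seqs[j]).identity_pct)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# neighbor joining and bootstrap
# ---------------------------------------------------------------------------

def nj_tree(distances: np.ndarray, labels: list[str]) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimising the Q-criterion is joined; ties are
    resolved toward the pair whose (sorted) smallest member labels are
    lexicographically lowest.  Returns an unrooted tree (trifurcating root)
    with branch lengths.
    """
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix/label mismatch")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    if d.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes = [TreeNode(name=lab) for lab in labels]
    mins = [lab for lab in labels]           # smallest leaf label per cluster
    d = d.copy()
    active = list(range(len(labels)))
    while len(active) > 2:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        m = len(active)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                lab = tuple(sorted((mins[i], mins[j])))
                key = (q, lab)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length = float(li)
        cj.length = float(lj)
        parent.extend([ci, cj])
        # new distances
        new_row = {}
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes.append(parent)
        mins.append(min(mins[i], mins[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k, v in new_row.items():
            d[u, k] = d[k, u] = v
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    ci, cj = nodes[i], nodes[j]
    dij = float(d[i, j])
    # the final edge is a single branch of the unrooted tree: hang a leaf
    # off the internal node with the full length; split only when both
    # remaining nodes are internal (placement of the root is arbitrary)
    if not ci.children and cj.children:
        ci.length = dij
        cj.append(ci)
        return cj
    if not cj.children and ci.children:
        cj.length = dij
        ci.append(cj)
        return ci
    root = TreeNode()
    ci.length = dij / 2.0
    cj.length = dij / 2.0
    root.extend([ci, cj])
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    all_leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            parts.add(min(side, all_leaves - side, key=lambda s: sorted(s)))
    return parts


def msa_distance_matrix(msa: list[str]) -> np.ndarray:
    """p-distance on alignment columns (gap-vs-residue counts as different)."""
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cols = [(x, y) for x, y in zip(msa[i], msa[j])
                    if not (x == "-" and y == "-")]
            if not cols:
                d[i, j] = d[j, i] = 0.0
                continue
            diff = sum(1 for x, y in cols if x != y)
            d[i, j] = d[j, i] = diff / len(cols)
    return d


def bootstrap_support(msa: list[str], labels: list[str], replicates: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ tree from an MSA with majority-rule bootstrap support on branches.

    Columns are resampled with replacement; each replicate is re-joined and
    the original topology's internal branches receive the percentage of
    replicates containing the same bipartition (stored as internal node
    names).
    """
    rng = np.random.default_rng(seed)
    base = nj_tree(msa_distance_matrix(msa), labels)
    base_parts = {}
    for node in base.non_tips(include_self=False):
        all_leaves = frozenset(t.name for t in base.tips())
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            key = min(side, all_leaves - side, key=lambda s: sorted(s))
            base_parts[id(node)] = key
    counts = {k: 0 for k in base_parts.values()}
    width = len(msa[0])
    for _ in range(replicates):
        cols = rng.integers(0, width, size=width)
        rep = ["".join(row[c] for c in cols) for row in msa]
        try:
            t = nj_tree(msa_distance_matrix(rep), labels)
        except ValueError:
            continue
        for part in _bipartitions(t):
            if part in counts:
                counts[part] += 1
    for node in base.non_tips(include_self=False):
        key = base_parts.get(id(node))
        if key is not None:
            node.name = str(round(100.0 * counts[key] / replicates))
    return base
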