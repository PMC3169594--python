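"""Independent brute-force oracles used only by the test suite.

Every oracle here is written as plainly as possible (nested loops, explicit
recurrences, exhaustive enumeration) and shares no code with the package
implementation it checks.
"""
from __future__ import annotations

import itertools

NEG = float("-inf")

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def sw_score(a: str, b: str, match: int, mismatch: int, gap_open: int,
             gap_extend: int) -> int:
    """Plain quadratic-space affine-gap Smith-Waterman score (no tricks).

    Gap of length L costs gap_open + L * gap_extend.
    """
    la, lb = len(a), len(b)
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]   # gap in a (horizontal)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]   # gap in b (vertical)
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def global_free_end_score(a: str, b: str, match: int, mismatch: int,
                          gap_open: int, gap_extend: int) -> int:
    """Plain affine-gap global alignment score with cost-free end gaps."""
    la, lb = len(a), len(b)
    H = [[NEG] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        H[i][0] = 0.0
    for j in range(lb + 1):
        H[0][j] = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend,
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend,
                          F[i - 1][j] - gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    best = max(max(H[i][lb] for i in range(la + 1)),
               max(H[la][j] for j in range(lb + 1)))
    return int(best)


def dust_window_score(window: str) -> float:
    """DUST triplet statistic of one window, computed by hand."""
    triplets = [window[k:k + 3] for k in range(len(window) - 2)]
    counts: dict[str, int] = {}
    for t in triplets:
        counts[t] = counts.get(t, 0) + 1
    raw = sum(c * (c - 1) / 2 for c in counts.values())
    return raw / (len(triplets) - 1)


def edit_distance(a: str, b: str) -> int:
    la, lb = len(a), len(b)
    D = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        D[i][0] = i
    for j in range(lb + 1):
        D[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1,
                          D[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
    return D[la][lb]


def best_partition_cost(seq: str, c_consensus: str, d_consensus: str,
                        min_unit: int = 8, max_unit: int = 21,
                        c_max_cost: int = 4, d_max_cost: int = 2,
                        skip_cost: float = 1.0,
                        include_d: bool = True) -> float:
    """Exhaustive minimum segmentation cost by recursion over all partitions."""
    n = len(seq)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int) -> float:
        if i == 0:
            return 0.0
        best = rec(i - 1) + skip_cost
        for L in range(min_unit, max_unit + 1):
            if L > i:
                break
            cost = edit_distance(seq[i - L:i], c_consensus)
            if cost <= c_max_cost:
                best = min(best, rec(i - L) + cost)
        if include_d:
            for L in range(max(10, len(d_consensus) - 2), len(d_consensus) + 3):
                if L > i:
                    continue
                cost = edit_distance(seq[i - L:i], d_consensus)
                if cost <= d_max_cost:
                    best = min(best, rec(i - L) + cost)
        return best

    return rec(n)


def single_linkage_clusters(intervals: list[tuple[int, int]],
                            threshold: int) -> list[list[int]]:
    """Brute-force single-linkage clustering by interval-gap distance."""
    n = len(intervals)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            (s1, e1), (s2, e2) = intervals[i], intervals[j]
            gap = max(s1, s2) - min(e1, e2)
            if gap <= threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values())


def brute_force_tsd(left_flank: str, right_flank: str, lo: int, hi: int,
                    max_mismatch: int):
    """All (length, mismatches) of adjacent direct-repeat candidates."""
    out = []
    for L in range(lo, hi + 1):
        if L > len(left_flank) or L > len(right_flank):
            continue
        a = left_flank[-L:]
        b = right_flank[:L]
        mm = sum(x != y for x, y in zip(a, b))
        if mm <= max_mismatch:
            out.append((L, mm))
    return out


def brute_force_hairpins(seq: str, min_stem: int, max_stem: int,
                         loop_lo: int, loop_hi: int, max_mismatch: int):
    """All stem-loop windows by direct enumeration."""
    found = []
    for i in range(len(seq)):
        for stem in range(min_stem, max_stem + 1):
            for loop in range(loop_lo, loop_hi + 1):
                end = i + 2 * stem + loop
                if end > len(seq):
                    continue
                arm1 = seq[i:i + stem]
                arm2 = seq[end - stem:end]
                mm = sum(x != y for x, y in zip(arm1, revcomp(arm2)))
                if mm <= max_mismatch:
                    found.append((i, stem, loop, mm))
    return found


def brute_force_orfs(seq: str, min_aa: int):
    """Six-frame ORF enumeration by scanning codon positions directly."""
    stops = {"TAA", "TAG", "TGA"}
    results = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for start in range(len(s) - 2):
            if s[start:start + 3] != "ATG":
                continue
            # only count ORFs whose ATG is the first start after the previous
            # stop in this frame (leftmost ATG per stop-bounded segment)
            prev = start - 3
            is_first = True
            while prev >= 0:
                cod = s[prev:prev + 3]
                if cod in stops:
                    break
                if cod == "ATG":
                    is_first = False
                    break
                prev -= 3
            if not is_first:
                continue
            j = start + 3
            while j + 3 <= len(s) and s[j:j + 3] not in stops:
                j += 3
            if j + 3 <= len(s):
                aa = (j - start) // 3
                if aa >= min_aa:
                    results.append((strand, start % 3, start, aa))
    return sorted(results)
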