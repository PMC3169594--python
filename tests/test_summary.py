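import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from conftest import random_dna
from tm1kit.summary import (align_motif_instances, bootstrap_support,
                            compute_logo, group_identity,
                            motif_c_length_histogram, msa_distance_matrix,
                            nj_tree, sp_score, summarize_classes)


def _bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            parts.add(min(side, leaves - side, key=lambda s: sorted(s)))
    return parts


class TestCenterStarMsa:
    def test_identical_instances_gapless(self):
        msa = align_motif_instances(["CGATTCAGTATCGC"] * 5)
        assert all(r == "CGATTCAGTATCGC" for r in msa)

    def test_single_deletion_instance(self):
        a = "CGATTCAGTATCGC"
        b = a[:6] + a[7:]            # one base deleted
        msa = align_motif_instances([a, a, b])
        assert len(set(len(r) for r in msa)) == 1
        assert len(msa[0]) == 14
        assert msa[2].count("-") == 1

    def test_rows_ungap_to_inputs(self, rng):
        instances = [random_dna(rng, int(rng.integers(10, 17)))
                     for _ in range(6)]
        msa = align_motif_instances(instances)
        assert [r.replace("-", "") for r in msa] == instances

    def test_sp_score_not_far_below_pairwise_upper_bound(self, rng):
        # the sum of independent optimal pairwise scores bounds any MSA's
        # SP score from above; related motif units must come close
        from tm1kit.align import global_align_free_end
        from tm1kit.summary import MOTIF_MSA_SCHEME

        base = "CGATTCAGTATCGC"
        instances = [base]
        for _ in range(4):
            s = list(base)
            k = int(rng.integers(0, len(s)))
            s[k] = "ACGT"[int(rng.integers(0, 4))]
            instances.append("".join(s))
        msa = align_motif_instances(instances)
        got = sp_score(msa)
        bound = 0
        for i in range(len(instances)):
            for j in range(i + 1, len(instances)):
                bound += global_align_free_end(instances[i], instances[j],
                                               MOTIF_MSA_SCHEME).score
        assert got <= bound
        assert got >= 0.9 * bound

    def test_deterministic(self, rng):
        instances = [random_dna(rng, 14) for _ in range(5)]
        assert align_motif_instances(instances) == \
            align_motif_instances(instances)


class TestLogo:
    def test_conserved_column_two_bits(self):
        logo = compute_logo(["C" * 4] * 50, correction=False)
        assert np.allclose(logo.bits, 2.0)
        assert logo.consensus == "CCCC"

    def test_uniform_column_zero_bits(self):
        logo = compute_logo(["A", "C", "G", "T"], correction=False)
        assert logo.bits[0] == 0.0
        assert logo.consensus == "-"

    def test_hand_entropy_half_bit(self):
        # column {A, A, C, G}: H = 1.5, info = 2 - 1.5 = 0.5
        logo = compute_logo(["A", "A", "C", "G"], correction=False)
        assert logo.bits[0] == pytest.approx(0.5)

    def test_correction_never_increases_bits(self, rng):
        rows = [random_dna(rng, 12) for _ in range(8)]
        raw = compute_logo(rows, correction=False)
        corr = compute_logo(rows, correction=True)
        assert (corr.bits <= raw.bits + 1e-12).all()

    def test_bits_bounded(self, rng):
        rows = [random_dna(rng, 20) for _ in range(5)]
        logo = compute_logo(rows)
        assert (logo.bits >= 0).all() and (logo.bits <= 2).all()

    def test_counts_sum_to_sequence_count(self, rng):
        rows = [random_dna(rng, 9) for _ in range(7)]
        logo = compute_logo(rows)
        assert (logo.counts.sum(axis=0) == 7).all()


class TestTables:
    def test_class_means(self):
        class El:
            def __init__(self, length, label):
                from tm1kit.seqio import GenomicInterval
                from tm1kit.classify import ClassLabel
                self.span = GenomicInterval("c", 0, length)
                self.class_label = ClassLabel(label, ("x",))
                self.tir = None

        els = [El(420, "Tm1-ML"), El(430, "Tm1-ML"), El(444, "Tm1-ML"),
               El(900, "Tm1-HH")]
        df = summarize_classes(els)
        ml = df[df["class"] == "Tm1-ML"].iloc[0]
        assert (ml["count"], ml["mean_length"]) == (3, 431)
        total = df[df["class"] == "Total"].iloc[0]
        assert total["count"] == 4

    def test_histogram_counts_conserved(self, zero_divergence_result):
        elements = zero_divergence_result.elements
        counts, mode = motif_c_length_histogram(elements)
        assert sum(counts.values()) == sum(
            len(e.tir.c_units_left) + len(e.tir.c_units_right)
            for e in elements if e.tir)
        assert mode == 14

    def test_group_identity_identical_pair(self):
        assert group_identity(["ACGTACGTAC", "ACGTACGTAC"]) == 100.0

    def test_group_identity_symmetric_and_matches_direct_mean(self, rng):
        from tm1kit.align import global_align_free_end

        seqs = [random_dna(rng, 200) for _ in range(6)]
        got = group_identity(seqs)
        direct = np.mean([global_align_free_end(seqs[i], seqs[j]).identity_pct
                          for i in range(6) for j in range(i + 1, 6)])
        assert got == pytest.approx(direct)
        assert group_identity(seqs[::-1]) == pytest.approx(got)

    def test_group_identity_needs_two(self):
        with pytest.raises(ValueError):
            group_identity(["ACGT"])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 2, 4], [2, 0, 6], [4, 6, 0]])
        tree = nj_tree(d, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(0.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    def test_additive_five_taxon_topology_recovered(self):
        # distances generated from the tree ((A:1,B:2):1,(C:1,D:1):2,E:3)
        labels = ["A", "B", "C", "D", "E"]
        paths = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 5, ("A", "E"): 5,
                 ("B", "C"): 6, ("B", "D"): 6, ("B", "E"): 6,
                 ("C", "D"): 2, ("C", "E"): 6, ("D", "E"): 6}
        d = np.zeros((5, 5))
        for (x, y), v in paths.items():
            i, j = labels.index(x), labels.index(y)
            d[i, j] = d[j, i] = v
        tree = nj_tree(d, labels)
        leaves = frozenset(labels)

        def canon(side):
            side = frozenset(side)
            return min(side, leaves - side, key=lambda s: sorted(s))

        parts = _bipartitions(tree)
        assert canon({"A", "B"}) in parts
        assert canon({"C", "D"}) in parts

    def test_recovers_random_additive_topologies(self, rng):
        """NJ consistency on additive matrices over 4-12 taxa."""
        for trial in range(10):
            k = int(rng.integers(4, 13))
            labels = [f"t{i}" for i in range(k)]
            # random binary tree via sequential attachment; path distances
            parent = {}
            nodes = ["i0"]
            edges = {}
            for i, lab in enumerate(labels):
                if i < 3:
                    parent[lab] = "i0"
                    edges[lab] = float(rng.integers(1, 20))
                else:
                    host = labels[int(rng.integers(0, i))]
                    mid = f"i{i}"
                    parent[mid] = parent[host]
                    edges[mid] = float(rng.integers(1, 20))
                    parent[host] = mid
                    edges[host] = float(rng.integers(1, 20))
                    parent[lab] = mid
                    edges[lab] = float(rng.integers(1, 20))

            def path_to_root(x):
                out = []
                while x != "i0":
                    out.append(x)
                    x = parent[x]
                return out

            d = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    pi = path_to_root(labels[i])
                    pj = path_to_root(labels[j])
                    common = set(pi) & set(pj)
                    dist = sum(edges[x] for x in pi if x not in common) + \
                        sum(edges[x] for x in pj if x not in common)
                    d[i, j] = d[j, i] = dist
            got = nj_tree(d, labels)
            want = skbio_nj(DistanceMatrix(d, labels))
            assert _bipartitions(got) == _bipartitions(want)

    def test_matches_skbio_on_noisy_matrix(self, rng):
        k = 8
        labels = [f"s{i}" for i in range(k)]
        m = rng.random((k, k)) * 10
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        got = nj_tree(d, labels)
        want = skbio_nj(DistanceMatrix(d, labels))
        assert _bipartitions(got) == _bipartitions(want)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, np.inf], [np.inf, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_newick_round_trip(self):
        from skbio import TreeNode
        import io

        d = np.array([[0.0, 2, 4, 5], [2, 0, 6, 7],
                      [4, 6, 0, 3], [5, 7, 3, 0.0]])
        tree = nj_tree(d, ["A", "B", "C", "D"])
        nwk = str(tree)
        back = TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in back.tips()} == {"A", "B", "C", "D"}


class TestBootstrap:
    def test_two_identical_clades_full_support(self, rng):
        a = random_dna(rng, 120)
        b = random_dna(rng, 120)
        msa = [a, a, b, b]
        labels = ["a1", "a2", "b1", "b2"]
        tree = bootstrap_support(msa, labels, replicates=100, seed=3)
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None]
        assert supports and all(s == 100 for s in supports)

    def test_deterministic_given_seed(self, rng):
        msa = [random_dna(rng, 60) for _ in range(5)]
        labels = [f"x{i}" for i in range(5)]
        t1 = str(bootstrap_support(msa, labels, replicates=20, seed=9))
        t2 = str(bootstrap_support(msa, labels, replicates=20, seed=9))
        assert t1 == t2

    def test_distance_matrix_properties(self, rng):
        msa = [random_dna(rng, 40) for _ in range(4)]
        d = msa_distance_matrix(msa)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()
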