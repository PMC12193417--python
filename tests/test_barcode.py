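import math

import numpy as np
import pytest
import skbio

from conftest import random_additive_tree
from echinodiv.barcode import (
    DistanceMatrix,
    barcode_cluster,
    bootstrap_support,
    concatenate_barcodes,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    site_counts,
    variable_sites,
)
from echinodiv.errors import SaturationError, ValidationError
from echinodiv.io import LocusAlignment


def _aln(seqs: dict[str, str], locus="L", reference_id=None) -> LocusAlignment:
    ids = [s for s in seqs if s != reference_id]
    return LocusAlignment(locus, ids, seqs, reference_id)


class TestVariableSites:
    def test_invariant_alignment(self):
        aln = _aln({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        prof = variable_sites(aln)
        assert prof.positions == [] and prof.n_haplotypes == 1

    def test_single_variable_site(self):
        prof = variable_sites(_aln({"a": "AAA", "b": "AAA", "c": "AAC"}))
        assert prof.positions == [3]
        assert prof.n_haplotypes == 2

    def test_gap_and_n_excluded(self):
        # column 2 has only one unambiguous base among samples -> not variable
        prof = variable_sites(_aln({"a": "A-G", "b": "ANG", "c": "AAG"}))
        assert prof.positions == []

    def test_reference_coordinates(self):
        # reference has a gap at column 2; variable column 3 maps to ref pos 2
        seqs = {"REF": "A-CG", "a": "AACG", "b": "AATG"}
        prof = variable_sites(_aln(seqs, reference_id="REF"))
        assert prof.positions == [2]

    def test_planted_haplotypes_recovered(self, study):
        aln = study.alignments["ITS"]
        prof = variable_sites(aln)
        assert prof.positions == study.truth.snp_positions["ITS"]
        assert prof.n_haplotypes == 5

    def test_every_sequence_unique(self):
        seqs = {f"s{i}": b * 4 for i, b in enumerate("ACGT")}
        assert barcode_cluster(_aln(seqs)).n_clusters == 4


class TestHaplotypeClustering:
    def test_matches_truth_exactly(self, study):
        for locus, k in (("ITS", 5), ("psbA", 2), ("matK", 2), ("trnL-F", 1)):
            assert barcode_cluster(study.alignments[locus]).n_clusters == k
        its = barcode_cluster(study.alignments["ITS"])
        truth = study.truth.groups
        assert its.as_partition() == frozenset(
            frozenset(truth.index[truth == g]) for g in range(1, 6)
        )

    def test_labels_first_appearance(self):
        seqs = {"a": "AC", "b": "AT", "c": "AC"}
        out = barcode_cluster(_aln(seqs))
        assert out.labels.tolist() == [1, 2, 1]


class TestConcatenate:
    def test_combined_length(self, study):
        its, psba = study.alignments["ITS"], study.alignments["psbA"]
        combined = concatenate_barcodes([its, psba])
        assert combined.length == 588 + 337 == 925
        assert combined.boundaries["psbA"] == (589, 925)

    def test_single_locus_identity(self, study):
        its = study.alignments["ITS"]
        combined = concatenate_barcodes([its])
        assert combined.sequences == its.sequences

    def test_crossed_haplotypes_give_seven_groups(self):
        # 5 ITS haplotypes crossed with 2 psbA haplotypes so 7 combos occur
        its_haps = ["AAAAA", "CAAAA", "ACAAA", "AACAA", "AAACA"]
        psba_haps = ["GGG", "GGT"]
        combos = [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0), (0, 1), (2, 1)]
        its = {f"s{i}": its_haps[a] for i, (a, _) in enumerate(combos)}
        psba = {f"s{i}": psba_haps[b] for i, (_, b) in enumerate(combos)}
        combined = concatenate_barcodes([_aln(its, "ITS"), _aln(psba, "psbA")])
        assert barcode_cluster(combined).n_clusters == 7

    def test_partition_refines_each_locus(self, study):
        its, psba = study.alignments["ITS"], study.alignments["psbA"]
        combined = concatenate_barcodes([its, psba])
        comb = barcode_cluster(combined)
        for single in (barcode_cluster(its), barcode_cluster(psba)):
            for block in comb.as_partition():
                assert any(
                    block <= parent for parent in single.as_partition()
                )

    def test_mismatched_samples_rejected(self):
        a = _aln({"x": "AC", "y": "AC"})
        b = _aln({"x": "GG", "z": "GG"})
        with pytest.raises(ValidationError, match="differ"):
            concatenate_barcodes([a, b])


class TestK2P:
    def test_identical_sequences(self):
        d, c = k2p_distance("ACGTACGT", "ACGTACGT")
        assert d == 0.0 and c.P == 0.0 and c.Q == 0.0

    def test_one_transition_in_100(self):
        a, b = "A" * 100, "G" + "A" * 99
        d, c = k2p_distance(a, b)
        assert c.sites == 100 and c.P == 0.01 and c.Q == 0.0
        assert d == pytest.approx(-0.5 * math.log(0.98), rel=1e-12)

    def test_saturated_pair_flagged(self):
        with pytest.raises(SaturationError):
            k2p_distance("AT", "TA")  # P=0, Q=1

    def test_pairwise_deletion(self):
        # gaps/N removed pairwise: only 2 comparable sites remain
        d, c = k2p_distance("A-GN", "AAGC")
        assert c.sites == 2 and d == 0.0

    def test_reduces_to_transition_formula_when_q_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 200
            p = rng.integers(1, 30)
            a = "A" * n
            b = "G" * p + "A" * (n - p)  # transitions only
            d, c = k2p_distance(a, b)
            assert c.Q == 0
            assert d == pytest.approx(-0.5 * math.log(1 - 2 * p / n), rel=1e-12)
            assert d >= p / n  # K2P >= p-distance

    def test_matches_brute_force_counting(self):
        # independent oracle: classify each site explicitly, then closed form
        purines = {"A", "G"}
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        for _ in range(25):
            a = "".join(rng.choice(bases, 200))
            # mutate a few sites to keep distances defined
            b = list(a)
            for pos in rng.choice(200, size=12, replace=False):
                b[pos] = rng.choice([x for x in "ACGT" if x != b[pos]])
            b = "".join(b)
            ts = sum(
                1 for x, y in zip(a, b)
                if x != y and (x in purines) == (y in purines)
            )
            tv = sum(
                1 for x, y in zip(a, b)
                if x != y and (x in purines) != (y in purines)
            )
            P, Q = ts / 200, tv / 200
            expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
            d, _ = k2p_distance(a, b)
            assert d == pytest.approx(expected, rel=1e-12)

    def test_matrix_symmetric_zero_diagonal(self, study):
        dmat = k2p_matrix(study.alignments["ITS"])
        assert np.allclose(dmat.matrix, dmat.matrix.T)
        assert np.all(np.diag(dmat.matrix) == 0)
        assert not dmat.undefined

    def test_invariant_locus_all_zero(self, study):
        dmat = k2p_matrix(study.alignments["trnL-F"])
        assert np.all(dmat.matrix == 0.0)


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = nj_tree(d)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_hand_drawn_four_taxon_tree(self):
        # ((A:1,B:2):1,(C:3,D:4)) -> additive matrix by hand
        m = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), m))
        paths = tree.path_lengths()
        for i, a in enumerate("ABCD"):
            for j in range(i + 1, 4):
                b = "ABCD"[j]
                assert paths[(a, b)] == pytest.approx(m[i, j], abs=1e-9)
        assert frozenset({"C", "D"}) in tree.bipartitions()

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_recovers_random_additive_trees(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        for _ in range(40):
            names, m, true_splits = random_additive_tree(n_leaves, rng)
            tree = nj_tree(DistanceMatrix(names, m))
            assert set(tree.bipartitions()) == true_splits
            paths = tree.path_lengths()
            for i, a in enumerate(names):
                for j in range(i + 1, len(names)):
                    key = (a, names[j])
                    assert paths[key] == pytest.approx(m[i, j], abs=1e-9)

    def test_matches_skbio_topology(self):
        rng = np.random.default_rng(77)
        names, m, _ = random_additive_tree(6, rng)
        mine = nj_tree(DistanceMatrix(names, m))
        ref = skbio.tree.nj(skbio.DistanceMatrix(m, ids=names))
        ref_splits = set()
        all_leaves = frozenset(names)
        anchor = min(names)
        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = all_leaves - side
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                ref_splits.add(side)
        assert set(mine.bipartitions()) == ref_splits

    def test_tie_case_deterministic(self):
        m = np.ones((4, 4)) - np.eye(4)
        d = DistanceMatrix(list("ABCD"), m)
        assert nj_tree(d).to_newick() == nj_tree(d).to_newick()

    def test_undefined_distances_rejected(self):
        m = np.zeros((3, 3))
        d = DistanceMatrix(list("ABC"), m, undefined=[("A", "B")])
        with pytest.raises(ValidationError, match="undefined"):
            nj_tree(d)

    def test_negative_branch_clamped(self):
        # matrix engineered to produce a negative NJ branch estimate
        m = np.array(
            [
                [0.0, 0.1, 0.6, 0.6],
                [0.1, 0.0, 0.55, 0.65],
                [0.6, 0.55, 0.0, 0.1],
                [0.6, 0.65, 0.1, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(list("ABCD"), m))
        for node in tree.root.walk():
            assert node.length >= 0


class TestBootstrap:
    def _two_clade_alignment(self):
        # two clearly distinct clades with 20 diagnostic sites each
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 200))
        clade2 = list(base)
        for pos in range(0, 40, 2):  # 20 diagnostic substitutions
            clade2[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[clade2[pos]]
        clade2 = "".join(clade2)

        def noisy(seq, k, rng):
            s = list(seq)
            for pos in rng.choice(len(s), size=k, replace=False):
                s[pos] = rng.choice([x for x in "ACGT" if x != s[pos]])
            return "".join(s)

        seqs = {
            "a1": base,
            "a2": noisy(base, 2, rng),
            "b1": clade2,
            "b2": noisy(clade2, 2, rng),
        }
        return _aln(seqs)

    def test_planted_clade_strongly_supported(self):
        tree = bootstrap_support(self._two_clade_alignment(), 100, seed=9)
        splits = tree.bipartitions()
        assert len(splits) == 1
        (node,) = splits.values()
        assert node.support >= 95

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_support(self._two_clade_alignment(), 1, seed=2)
        supports = [
            n.support for n in tree.root.walk() if n.support is not None
        ]
        assert supports and all(s in (0, 100) for s in supports)

    def test_same_seed_reproducible(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, 50, seed=4)
        t2 = bootstrap_support(aln, 50, seed=4)
        assert t1.to_newick() == t2.to_newick()

    def test_small_alignment_returns_tree_without_supports(self):
        aln = _aln({"a": "AAAAAAAA", "b": "AAAAAAAG", "c": "AAAAAAGG"})
        tree = bootstrap_support(aln, 10, seed=1)
        assert all(n.support is None for n in tree.root.walk())
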