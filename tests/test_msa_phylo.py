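"""Alignment, distance and neighbor-joining correctness."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from mipscan.msa_phylo import (
    Alignment,
    AlignmentError,
    distance_matrix,
    global_align,
    is_unrooted_cluster,
    neighbor_joining,
    progressive_msa,
    read_newick,
    simple_matrix,
    tree_path_distances,
    write_newick,
)
from mipscan.seqio import ProteinRecord

from conftest import random_additive_tree


def rec(name, seq):
    return ProteinRecord(id=name, sequence=seq)


def brute_force_best_score(a, b, match=1.0, mismatch=-1.0, gap=-1.0):
    """Exhaustive enumeration over all global alignments (linear gaps)."""
    best = [-np.inf]

    def go(i, j, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            go(i + 1, j + 1, score + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            go(i + 1, j, score + gap)
        if j < len(b):
            go(i, j + 1, score + gap)

    go(0, 0, 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identical_sequences_no_gaps(self):
        seq = "MKVLIFSAGHWPTRENDQYCIVLMKVLIFSAGHWPTRENDQYCIVLMKVL"
        aln, _ = global_align(rec("a", seq), rec("b", seq))
        (_, ra), (_, rb) = aln.rows
        assert ra == rb == seq

    def test_score_symmetry(self):
        a, b = rec("a", "NPAWRK"), rec("b", "NPGWK")
        _, s1 = global_align(a, b)
        _, s2 = global_align(b, a)
        assert s1 == pytest.approx(s2)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        """DP optimum equals brute-force maximum for short sequences."""
        rng = np.random.default_rng(seed)
        alphabet = list("NPAWRKG")
        a = "".join(rng.choice(alphabet, rng.integers(1, 7)))
        b = "".join(rng.choice(alphabet, rng.integers(1, 7)))
        _, score = global_align(
            rec("a", a), rec("b", b), matrix=simple_matrix(), gap_open=1, gap_extend=1
        )
        assert score == pytest.approx(brute_force_best_score(a, b))

    def test_npa_vs_na_example(self):
        _, score = global_align(
            rec("a", "NPA"), rec("b", "NA"), matrix=simple_matrix(),
            gap_open=1, gap_extend=1,
        )
        assert score == pytest.approx(brute_force_best_score("NPA", "NA"))

    def test_degap_reproduces_inputs(self):
        a, b = rec("a", "MKVNPAWWR"), rec("b", "MKNPAR")
        aln, _ = global_align(a, b)
        assert aln.degapped("a") == a.sequence
        assert aln.degapped("b") == b.sequence


class TestProgressiveMsa:
    def test_two_identical_sequences_no_gaps(self):
        aln = progressive_msa([rec("a", "NPAWRK"), rec("b", "NPAWRK")])
        assert aln.n_columns == 6
        assert all("-" not in s for _, s in aln.rows)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(AlignmentError):
            progressive_msa([rec("a", "NPA")])

    def test_degap_invariant_on_family(self, family, family_msa):
        rows = dict(family_msa.rows)
        for p in family.proteins:
            assert rows[p.id].replace("-", "") == p.sequence

    def test_npa_columns_align_across_family(self, family, family_msa):
        """Planted loop-B/loop-E boxes occupy single alignment columns."""
        from mipscan.synthetic_data import archetype_spec

        rows = dict(family_msa.rows)

        def column_of(gapped, pos0):
            seen = -1
            for col, c in enumerate(gapped):
                if c != "-":
                    seen += 1
                    if seen == pos0:
                        return col

        cols_b, cols_e = set(), set()
        for p in family.proteins:
            spec = archetype_spec(p.id)
            cols_b.add(column_of(rows[p.id], spec.region_start0("loopB") + 10))
            cols_e.add(column_of(rows[p.id], spec.region_start0("loopE") + 8))
        assert len(cols_b) == 1 and len(cols_e) == 1


class TestDistances:
    def test_identical_rows_zero(self):
        aln = Alignment(rows=(("a", "NPAWRK"), ("b", "NPAWRK")))
        assert distance_matrix(aln)["a", "b"] == 0.0

    def test_p_distance_arithmetic(self):
        aln = Alignment(rows=(("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC")))
        assert distance_matrix(aln)["a", "b"] == pytest.approx(0.1)

    def test_poisson_closed_form(self):
        aln = Alignment(rows=(("a", "AAAAAAAAAA"), ("b", "AAAAAAAAAC")))
        d = distance_matrix(aln, model="poisson")["a", "b"]
        assert d == pytest.approx(-np.log(0.9), abs=1e-5)
        assert d == pytest.approx(0.10536, abs=1e-4)

    def test_pairwise_deletion(self):
        aln = Alignment(rows=(("a", "AA--AAAAAA"), ("b", "AAAA--AAAC")))
        assert distance_matrix(aln)["a", "b"] == pytest.approx(1 / 6)

    def test_no_comparable_columns_rejected(self):
        aln = Alignment(rows=(("a", "AA--"), ("b", "--AA")))
        with pytest.raises(AlignmentError):
            distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ids=list("abc")
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_fewer_than_three_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=list("ab"))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    @pytest.mark.parametrize("seed,n", [(0, 4), (1, 5), (2, 6), (3, 8), (4, 10)])
    def test_additive_matrix_recovered_exactly(self, seed, n):
        """NJ reproduces the generating tree's path distances to 1e-9."""
        rng = np.random.default_rng(seed)
        d = random_additive_tree(rng, n)
        ids = [str(i) for i in range(n)]
        tree = neighbor_joining(DistanceMatrix(d, ids=ids))
        recovered = tree_path_distances(tree).filter(ids).data
        assert np.abs(recovered - d).max() < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_skbio_reference(self, seed):
        """Independent cross-check against scikit-bio's NJ on noisy matrices."""
        rng = np.random.default_rng(seed)
        d = random_additive_tree(rng, 7)
        d += rng.uniform(0, 0.02, d.shape)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        ids = [str(i) for i in range(7)]
        dm = DistanceMatrix(d, ids=ids)
        ours = tree_path_distances(neighbor_joining(dm)).filter(ids).data
        theirs_tree = skbio_nj(dm)
        theirs = theirs_tree.tip_tip_distances().filter(ids).data
        assert np.abs(ours - theirs).max() < 1e-6

    def test_family_recovers_five_subfamily_clades(self, family, family_truth,
                                                   family_tree):
        for sub in ("PIP", "TIP", "NIP", "SIP", "XIP"):
            leaves = [p.id for p in family.proteins
                      if family_truth.loc[p.id, "subfamily"] == sub]
            assert is_unrooted_cluster(family_tree, leaves), sub


class TestNewick:
    def test_simple_roundtrip(self):
        tree = read_newick("(a:1,b:1,c:1);")
        text = write_newick(tree)
        again = read_newick(text)
        d1 = tree.tip_tip_distances().filter(list("abc")).data
        d2 = again.tip_tip_distances().filter(list("abc")).data
        assert np.abs(d1 - d2).max() < 1e-9

    def test_nj_output_roundtrip(self, tmp_path):
        rng = np.random.default_rng(7)
        d = random_additive_tree(rng, 4)
        ids = list("abcd")
        tree = neighbor_joining(DistanceMatrix(d, ids=ids))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        rec = back.tip_tip_distances().filter(ids).data
        assert np.abs(rec - d).max() < 1e-9

    def test_malformed_string_rejected(self):
        with pytest.raises(Exception):
            read_newick("((a:1,b:1;")
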