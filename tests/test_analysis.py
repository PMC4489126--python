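"""Difference matrices, score-to-distance transforms, UPGMA and classical MDS."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average as scipy_average, cophenet
from scipy.spatial.distance import squareform

import oracles
from famsubmat import (
    DistanceMatrix,
    SubstitutionMatrix,
    classical_mds,
    difference_matrix,
    score_to_distance,
    upgma,
)


def symmetric_matrix(rng, low=-4, high=12):
    s = rng.integers(low, high, size=(20, 20)).astype(float)
    s = np.triu(s) + np.triu(s, 1).T
    return SubstitutionMatrix.from_int_scores(s)


class TestDifferenceMatrix:
    def test_self_difference_zero(self, diag_matrix):
        d = difference_matrix(diag_matrix, diag_matrix)
        assert not d.values.any()

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = symmetric_matrix(rng), symmetric_matrix(rng)
        dab = difference_matrix(a, b).values
        dba = difference_matrix(b, a).values
        assert not (dab + dba).any()

    def test_hand_subtraction(self):
        sa = np.zeros((20, 20)); sb = np.zeros((20, 20))
        sa[0, 0] = 1; sa[0, 4] = sa[4, 0] = 3   # A-A=1, A-C=3
        sb[0, 0] = 2; sb[0, 4] = sb[4, 0] = 1
        d = difference_matrix(
            SubstitutionMatrix.from_int_scores(sa),
            SubstitutionMatrix.from_int_scores(sb),
        )
        assert d.values[0, 0] == -1
        assert d.values[0, 4] == 2

    def test_alphabet_mismatch_rejected(self, diag_matrix):
        other = SubstitutionMatrix.from_int_scores(
            np.zeros((4, 4)), alphabet="ACDE"
        )
        with pytest.raises(ValueError, match="alphabet"):
            difference_matrix(diag_matrix, other)


class TestScoreToDistance:
    def test_identity_like_matrix(self, diag_matrix):
        d = score_to_distance(diag_matrix, "diagonal_deficit")
        off = d.values[~np.eye(20, dtype=bool)]
        assert np.all(off == 8.0)  # 2c with c = 4
        assert np.all(np.diag(d.values) == 0)

    @pytest.mark.parametrize("method", ["diagonal_deficit", "correlation"])
    def test_zero_diagonal(self, method):
        rng = np.random.default_rng(1)
        m = symmetric_matrix(rng)
        d = score_to_distance(m, method)
        assert np.allclose(np.diag(d.values), 0)
        assert np.allclose(d.values, d.values.T)

    def test_diagonal_deficit_hand_values(self):
        # 3-residue restriction: S_AA=1, S_AC=3, S_LL=2, S_CC=floor
        s = np.zeros((20, 20))
        i, j, k = 0, 4, 10  # A, C, L in NCBI order
        s[i, i] = 1; s[k, k] = 2; s[i, j] = s[j, i] = 3
        m = SubstitutionMatrix.from_int_scores(s)
        d = score_to_distance(m).values
        assert d[i, j] == max(1 + 0 - 6, 0)  # floored at 0
        assert d[i, k] == 1 + 2 - 0

    def test_constant_row_correlation_error(self):
        m = SubstitutionMatrix.from_int_scores(np.zeros((20, 20)))
        with pytest.raises(ValueError, match="constant"):
            score_to_distance(m, "correlation")


class TestUPGMA:
    def test_hand_worked_three_leaves(self):
        d = DistanceMatrix(
            np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float), ["A", "B", "C"]
        )
        tree = upgma(d)
        assert tree.merge_heights == [1.0, 3.0]
        # first merge is (A,B); C joins at the root
        assert sorted(tree.root.children[0].leaves()) in (["A", "B"], ["C"])
        coph = tree.cophenetic()
        assert coph.values[0, 1] == 2.0
        assert coph.values[0, 2] == 6.0

    def test_all_equal_distances_tie_break(self):
        n = 5
        labels = list("EDCBA")
        d = DistanceMatrix(np.ones((n, n)) - np.eye(n), labels)
        tree = upgma(d)
        assert tree.merge_heights == [0.5] * (n - 1)
        # lexicographic tie-break merges A with B first
        first = tree.root
        while not first.children[0].is_leaf or not first.children[1].is_leaf:
            first = first.children[0] if not first.children[0].is_leaf else first.children[1]
            if first.is_leaf:
                break
        # find the depth-first first merged pair
        def deepest_pair(node):
            if node.is_leaf:
                return None
            for child in node.children:
                got = deepest_pair(child)
                if got:
                    return got
            return sorted(node.leaves())
        assert deepest_pair(tree.root) == ["A", "B"]

    def test_cophenetic_ultrametric_and_bounded(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            raw = rng.random((8, 8)) * 10
            dm = (raw + raw.T) / 2
            np.fill_diagonal(dm, 0)
            labels = [f"L{i}" for i in range(8)]
            tree = upgma(DistanceMatrix(dm, labels))
            coph = tree.cophenetic()
            assert oracles.is_ultrametric(coph.values, coph.labels)
            assert coph.values.max() <= dm.max() + 1e-9

    def test_matches_scipy_average_linkage(self):
        """Merge heights agree with scipy's UPGMA on tie-free random input."""
        rng = np.random.default_rng(6)
        raw = rng.random((12, 12)) * 7
        dm = (raw + raw.T) / 2
        np.fill_diagonal(dm, 0)
        labels = [f"L{i:02d}" for i in range(12)]
        tree = upgma(DistanceMatrix(dm, labels))
        Z = scipy_average(squareform(dm))
        assert np.allclose(sorted(tree.merge_heights), sorted(Z[:, 2] / 2), atol=1e-9)
        # cophenetic distances agree too
        ours = tree.cophenetic()
        order = [ours.labels.index(l) for l in labels]
        theirs = squareform(cophenet(Z))
        assert np.allclose(
            ours.values[np.ix_(order, order)], theirs, atol=1e-9
        )

    def test_leaf_set_is_input_labels(self):
        rng = np.random.default_rng(7)
        raw = rng.random((20, 20)) * 3
        dm = (raw + raw.T) / 2
        np.fill_diagonal(dm, 0)
        labels = list("ARNDCQEGHILKMFPSTWYV")
        tree = upgma(DistanceMatrix(dm, labels))
        assert sorted(tree.leaves()) == sorted(labels)

    def test_newick_parses_with_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        d = DistanceMatrix(
            np.array([[0, 2, 6], [2, 0, 6], [6, 6, 0]], float), ["A", "B", "C"]
        )
        nwk = upgma(d).to_newick()
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]

    def test_nan_distance_rejected(self):
        dm = np.zeros((3, 3))
        dm[0, 1] = dm[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            DistanceMatrix(dm, ["A", "B", "C"])


class TestClassicalMDS:
    def test_two_points(self):
        d = DistanceMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        proj = classical_mds(d, k=1)
        coords = sorted(proj.coordinates[:, 0])
        assert coords == pytest.approx([-2.0, 2.0], abs=1e-9)

    def test_recovers_planted_configuration(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(20, 2)) * 3
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"P{i}" for i in range(20)]
        proj = classical_mds(DistanceMatrix(dm, labels), k=2)
        # pairwise distances reproduced
        rec = proj.coordinates
        dm2 = np.sqrt(((rec[:, None, :] - rec[None, :, :]) ** 2).sum(-1))
        assert np.allclose(dm2, dm, atol=1e-8)
        # Procrustes residual below 1e-8 after optimal rotation
        from scipy.linalg import orthogonal_procrustes

        x = pts - pts.mean(0)
        y = rec - rec.mean(0)
        R, _ = orthogonal_procrustes(y, x)
        assert np.abs(y @ R - x).max() < 1e-8

    def test_eigenvalues_non_increasing_and_centred(self):
        rng = np.random.default_rng(12)
        raw = rng.random((10, 10)) * 5
        dm = (raw + raw.T) / 2
        np.fill_diagonal(dm, 0)
        proj = classical_mds(DistanceMatrix(dm, [f"L{i}" for i in range(10)]), k=2)
        assert np.all(np.diff(proj.eigenvalues) <= 1e-9)
        assert np.allclose(proj.coordinates.mean(0), 0, atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(6, 2))
        dm = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        d = DistanceMatrix(dm, list("ABCDEF"))
        p1 = classical_mds(d, k=2)
        p2 = classical_mds(d, k=2)
        assert np.array_equal(p1.coordinates, p2.coordinates)
        for axis in range(2):
            j = np.argmax(np.abs(p1.coordinates[:, axis]))
            assert p1.coordinates[j, axis] > 0

    def test_truncation_flagged(self):
        # 3 collinear points span only 1 dimension
        dm = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        proj = classical_mds(DistanceMatrix(dm, ["A", "B", "C"]), k=2)
        assert proj.truncated
        assert proj.coordinates.shape[1] == 1
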