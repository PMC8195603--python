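"""Z→distance conversion and UPGMA construction, with independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from contextscan.trees import TreeNode, ZMatrix, upgma, zscore_tree, zscores_to_distance


def random_distance_matrix(n, rng):
    d = rng.uniform(0.5, 10.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def brute_force_upgma_cophenetic(d, labels):
    """Naive UPGMA oracle: clusters as leaf sets; inter-cluster distance
    recomputed each round as the arithmetic mean over all original leaf
    pairs.  Returns pairwise cophenetic distances."""
    n = len(labels)
    clusters = [frozenset([i]) for i in range(n)]
    coph = {}
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            mean_d = np.mean([d[i, j] for i in a for j in b])
            if best is None or mean_d < best[0]:
                best = (mean_d, a, b)
        mean_d, a, b = best
        for i in a:
            for j in b:
                coph[frozenset((labels[i], labels[j]))] = mean_d
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return coph


class TestZMatrix:
    def test_asymmetry_rejected(self):
        z = np.array([[10.0, 3.0], [4.0, 10.0]])
        with pytest.raises(ValueError):
            ZMatrix(("a", "b"), z)

    def test_off_diagonal_above_self_z_rejected(self):
        z = np.array([[10.0, 12.0], [12.0, 10.0]])
        with pytest.raises(ValueError):
            ZMatrix(("a", "b"), z)

    def test_normalization_scales_by_self_z(self):
        z = np.array([[16.0, 3.0], [3.0, 4.0]])
        norm = ZMatrix(("a", "b"), z).normalized()
        assert norm.z[0, 1] == pytest.approx(3.0 / 8.0)
        assert np.allclose(np.diag(norm.z), 1.0)


class TestZToDistance:
    def test_pair_achieving_zmax_lands_at_zero(self):
        z = np.array([[50.0, 30.0, 5.0], [30.0, 50.0, 8.0], [5.0, 8.0, 50.0]])
        d = zscores_to_distance(ZMatrix(("a", "b", "c"), z))
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(25.0)

    def test_symmetric_zero_diagonal_for_random_input(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, size=(5, 5))
        z = (base + base.T) / 2
        np.fill_diagonal(z, 20.0)
        d = zscores_to_distance(ZMatrix(tuple("abcde"), z))
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()

    def test_equal_offdiagonals_give_star_at_zero(self):
        z = np.full((3, 3), 7.0)
        np.fill_diagonal(z, 30.0)
        d = zscores_to_distance(ZMatrix(("a", "b", "c"), z))
        tree = upgma(d, ["a", "b", "c"])
        assert all(h == 0.0 for h in tree.leaf_depths().values())

    def test_reciprocal_transform(self):
        z = np.array([[10.0, 4.0], [4.0, 10.0]])
        d = zscores_to_distance(ZMatrix(("a", "b"), z), transform="reciprocal")
        assert d[0, 1] == pytest.approx(0.25)

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            zscores_to_distance(ZMatrix(("a",), np.array([[5.0]])))


class TestUpgma:
    def test_hand_worked_three_leaves(self):
        """d(A,B)=2, d(A,C)=d(B,C)=6 → ((A:1,B:1):2,C:3);"""
        d = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
        tree = upgma(d, ["A", "B", "C"])
        assert tree.to_newick() == "((A:1,B:1):2,C:3);"

    def test_two_leaves(self):
        tree = upgma(np.array([[0.0, 4.0], [4.0, 0.0]]), ["A", "B"])
        assert tree.to_newick() == "(A:2,B:2);"

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(1)
        d = random_distance_matrix(6, rng)
        labels = [f"L{i}" for i in range(6)]
        perm = rng.permutation(6)
        t1 = upgma(d, labels)
        t2 = upgma(d[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert t1.cophenetic() == pytest.approx(t2.cophenetic())
        assert sorted(t1.leaves()) == sorted(t2.leaves())

    def test_trees_are_ultrametric(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            d = random_distance_matrix(n, rng)
            tree = upgma(d, [f"x{i}" for i in range(n)])
            depths = list(tree.leaf_depths().values())
            assert max(depths) - min(depths) < 1e-9

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 7))
            labels = [f"x{i}" for i in range(n)]
            d = random_distance_matrix(n, rng)
            got = upgma(d, labels).cophenetic()
            expected = brute_force_upgma_cophenetic(d, labels)
            for key, value in expected.items():
                assert got[key] == pytest.approx(value, rel=1e-9)

    def test_matches_scipy_average_linkage(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            labels = [f"x{i}" for i in range(n)]
            d = random_distance_matrix(n, rng)
            tree = upgma(d, labels)
            link = average(squareform(d, checks=False))
            coph = squareform(cophenet(link))
            got = tree.cophenetic()
            for i in range(n):
                for j in range(i + 1, n):
                    assert got[frozenset((labels[i], labels[j]))] == pytest.approx(
                        coph[i, j], rel=1e-9
                    )

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            upgma(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            upgma(np.array([[0.0, -1.0], [-1.0, 0.0]]), ["a", "b"])

    def test_newick_parses_with_skbio(self):
        import io

        import skbio

        rng = np.random.default_rng(5)
        d = random_distance_matrix(5, rng)
        labels = [f"t{i}" for i in range(5)]
        newick = upgma(d, labels).to_newick()
        tree = skbio.TreeNode.read(io.StringIO(newick))
        assert sorted(t.name for t in tree.tips()) == labels


def test_zscore_tree_groups_block_structure():
    """Within-block Z of ~20 vs between-block ~5: the two blocks separate."""
    from contextscan.synthetic_data import generate_zmatrix

    labels, z = generate_zmatrix([f"S{i}" for i in range(8)], seed=3)
    tree = zscore_tree(ZMatrix(tuple(labels), z))
    # the root's two subtrees partition the leaves into the planted groups
    rng_groups = np.random.default_rng(3).integers(2, size=8)
    blocks = {tuple(sorted(l for l, g in zip(labels, rng_groups) if g == i))
              for i in (0, 1)}
    subtrees = {tuple(sorted(child.leaves())) for child in tree.children}
    assert subtrees == blocks
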