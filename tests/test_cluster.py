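import numpy as np
import pytest

import oracles
from reactvec.cluster import (
    DistanceMatrix,
    cut_tree,
    euclidean_distances,
    select_k_bic,
    upgma,
    write_newick,
)
from reactvec.reactions import ReactionVector
from reactvec.triplets import TripletVocabulary


def _rvecs(rows, ids=None):
    vocab = TripletVocabulary(tuple(f"K{i}" for i in range(len(rows[0]))))
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return [ReactionVector(i, np.array(r), vocab) for i, r in zip(ids, rows)]


@pytest.fixture
def three_leaf_tree():
    dm = DistanceMatrix(
        ("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    )
    return upgma(dm)


class TestDistances:
    def test_three_four_five(self):
        d = euclidean_distances(_rvecs([[0, 0], [3, 4]]))
        assert d.d[0, 1] == 5.0

    def test_identical_vectors_distance_zero(self):
        d = euclidean_distances(_rvecs([[1, 2], [1, 2]]))
        assert d.d[0, 1] == 0.0

    def test_matches_double_loop(self):
        rng = np.random.default_rng(4)
        rows = rng.integers(-5, 6, size=(10, 7))
        d = euclidean_distances(_rvecs(list(rows)))
        for i in range(10):
            for j in range(10):
                expected = float(np.sqrt(((rows[i] - rows[j]) ** 2).sum()))
                assert d.d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_mixed_vocabularies_rejected(self):
        va = ReactionVector("a", np.array([1]), TripletVocabulary(("HCH",)))
        vb = ReactionVector("b", np.array([1]), TripletVocabulary(("HOH",)))
        with pytest.raises(ValueError, match="vocabular"):
            euclidean_distances([va, vb])


class TestUpgma:
    def test_hand_agglomeration(self, three_leaf_tree):
        heights = three_leaf_tree.node_heights()
        assert heights.tolist() == [1.0, 2.0]

    def test_full_height_convention(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        )
        t = upgma(dm, height_convention="full")
        assert t.node_heights().tolist() == [2.0, 4.0]

    def test_all_equal_distances_merge_at_one_height(self):
        d = np.full((5, 5), 3.0)
        np.fill_diagonal(d, 0.0)
        t = upgma(DistanceMatrix(tuple("ABCDE"), d))
        assert np.allclose(t.linkage[:, 2], 3.0)
        assert np.allclose(t.cophenetic_matrix()[~np.eye(5, dtype=bool)], 3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_cophenetic_matches_cubic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        d = np.triu(rng.uniform(0.1, 10.0, size=(n, n)), k=1)
        d = d + d.T
        t = upgma(DistanceMatrix(tuple(f"i{i}" for i in range(n)), d))
        assert np.allclose(
            t.cophenetic_matrix(), oracles.upgma_cophenetic(d), atol=1e-9
        )

    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(1)
        d = np.triu(rng.uniform(0.1, 5.0, size=(8, 8)), k=1)
        d = d + d.T
        C = upgma(DistanceMatrix(tuple("abcdefgh"), d)).cophenetic_matrix()
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert C[i, j] <= max(C[i, k], C[j, k]) + 1e-9

    def test_non_finite_distances_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            upgma(DistanceMatrix(("a", "b"), d))


class TestNewick:
    def test_three_leaf_string(self, three_leaf_tree):
        assert write_newick(three_leaf_tree) == "((A:1,B:1):1,C:2);"

    def test_single_merge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert write_newick(upgma(dm)) == "(A:1,B:1);"

    def test_reserved_characters_quoted(self):
        dm = DistanceMatrix(("a b", "c:d"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        s = write_newick(upgma(dm))
        assert "'a b'" in s and "'c:d'" in s

    def test_round_trip_preserves_cophenetic_distances(self):
        import dendropy

        rng = np.random.default_rng(2)
        d = np.triu(rng.uniform(0.5, 8.0, size=(7, 7)), k=1)
        d = d + d.T
        ids = tuple(f"L{i}" for i in range(7))
        t = upgma(DistanceMatrix(ids, d))
        tree = dendropy.Tree.get(data=write_newick(t), schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in tree.taxon_namespace}
        C = t.cophenetic_matrix()
        for i in range(7):
            for j in range(i + 1, 7):
                # path length between leaves equals the cophenetic distance
                assert pdm.patristic_distance(
                    taxa[ids[i]], taxa[ids[j]]
                ) == pytest.approx(C[i, j], abs=1e-9)


class TestCutTree:
    def test_highest_merge_removed_first(self, three_leaf_tree):
        c = cut_tree(three_leaf_tree, 2)
        assert c.labels["A"] == c.labels["B"] != c.labels["C"]

    def test_boundary_cuts(self, three_leaf_tree):
        assert cut_tree(three_leaf_tree, 1).k == 1
        singletons = cut_tree(three_leaf_tree, 3)
        assert len(set(singletons.labels.values())) == 3

    def test_out_of_range_k(self, three_leaf_tree):
        with pytest.raises(ValueError):
            cut_tree(three_leaf_tree, 0)
        with pytest.raises(ValueError):
            cut_tree(three_leaf_tree, 4)

    def test_successive_cuts_are_refinements(self):
        rng = np.random.default_rng(3)
        d = np.triu(rng.uniform(0.1, 9.0, size=(12, 12)), k=1)
        d = d + d.T
        t = upgma(DistanceMatrix(tuple(f"i{i}" for i in range(12)), d))
        for k in range(1, 12):
            coarse = cut_tree(t, k).labels
            fine = cut_tree(t, k + 1).labels
            # items sharing a fine cluster must share the coarse cluster
            by_fine = {}
            for item, lab in fine.items():
                by_fine.setdefault(lab, []).append(item)
            for members in by_fine.values():
                assert len({coarse[m] for m in members}) == 1

    def test_identical_vectors_always_co_clustered(self):
        rows = [[0, 0], [0, 0], [5, 5], [9, 0]]
        vecs = _rvecs(rows)
        t = upgma(euclidean_distances(vecs))
        for k in range(1, 4):
            c = cut_tree(t, k)
            assert c.labels["r0"] == c.labels["r1"]


class TestSelectKBic:
    def test_recovers_three_separated_blobs(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(loc, 0.1, size=(20, 3)) for loc in (0.0, 10.0, 20.0)]
        )
        scan = select_k_bic(X, k_max=8, seed=0)
        assert scan.k_star == 3

    def test_single_blob_prefers_one_cluster(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0.0, 1.0, size=(80, 3))
        scan = select_k_bic(X, k_max=6, seed=0)
        assert scan.k_star == 1

    def test_scan_truncated_to_n_minus_one(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0.0, 1.0, size=(5, 2))
        scan = select_k_bic(X, k_max=100, seed=0)
        assert scan.k_values == [1, 2, 3, 4]

    def test_duplicated_points_do_not_break_fitting(self):
        X = np.array([[0.0, 0.0]] * 10 + [[10.0, 10.0]] * 10)
        scan = select_k_bic(X, k_max=4, seed=0)
        assert scan.k_star == 2
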