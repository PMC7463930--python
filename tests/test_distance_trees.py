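import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from peptraits import distance_trees as dt


def random_table(n, seed=0, ncol=36):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(size=(n, ncol)), index=[f"t{i}" for i in range(n)])


def tree_distances(newick: str, ids):
    """Leaf-to-leaf path lengths, as an oracle for additivity checks."""
    t = TreeNode.read([newick])
    return {(a, b): t.find(a).distance(t.find(b)) for a in ids for b in ids if a < b}


class TestEuclideanDistances:
    def test_identical_rows_distance_zero(self):
        X = pd.DataFrame(np.ones((3, 5)), index=list("abc"))
        dm = dt.euclidean_distances(X)
        assert dm["a", "b"] == 0.0

    def test_three_four_five(self):
        X = pd.DataFrame(
            [[0, 0, 0], [3, 4, 0], [0, 0, 0]], index=list("abc"), dtype=float
        )
        dm = dt.euclidean_distances(X)
        assert dm["a", "b"] == pytest.approx(5.0)

    def test_matches_naive_loop(self):
        X = random_table(10, seed=1)
        dm = dt.euclidean_distances(X)
        for i, a in enumerate(X.index):
            for j, b in enumerate(X.index):
                expected = math.sqrt(((X.iloc[i] - X.iloc[j]) ** 2).sum())
                assert dm[a, b] == pytest.approx(expected, abs=1e-9)

    def test_duplicate_ids_rejected(self):
        X = pd.DataFrame(np.eye(3), index=["a", "a", "b"])
        with pytest.raises(ValueError):
            dt.euclidean_distances(X)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = dt.neighbor_joining(DistanceMatrix(d, ids=list("abc")))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize(
        "newick,ids",
        [
            ("((a:2,b:3):1,c:4,d:5);", "abcd"),
            ("((a:2,b:3):1,(c:4,d:5):2,e:1);", "abcde"),
        ],
    )
    def test_additive_matrices_recovered_exactly(self, newick, ids):
        ids = list(ids)
        path = tree_distances(newick, ids)
        n = len(ids)
        d = np.zeros((n, n))
        for (a, b), v in path.items():
            i, j = ids.index(a), ids.index(b)
            d[i, j] = d[j, i] = v
        tree = dt.neighbor_joining(DistanceMatrix(d, ids=ids))
        recovered = tree_distances(dt.newick_string(tree), ids)
        for pair, v in path.items():
            assert recovered[pair] == pytest.approx(v, abs=1e-9)
        expected_splits = dt.bipartitions(TreeNode.read([newick]))
        assert set(dt.bipartitions(tree)) == set(expected_splits)

    def test_matches_reference_implementation_on_random_matrices(self):
        for seed in range(3):
            X = random_table(6, seed=seed)
            dm = dt.euclidean_distances(X)
            mine = dt.neighbor_joining(dm)
            ref = skbio_nj(dm)
            assert set(dt.bipartitions(mine)) == set(dt.bipartitions(ref))

    def test_leaf_order_invariance(self):
        X = random_table(7, seed=4)
        dm = dt.euclidean_distances(X)
        perm = [3, 0, 6, 2, 5, 1, 4]
        Xp = X.iloc[perm]
        dmp = dt.euclidean_distances(Xp)
        assert set(dt.bipartitions(dt.neighbor_joining(dm))) == set(
            dt.bipartitions(dt.neighbor_joining(dmp))
        )

    def test_internal_edge_count(self):
        for n in (4, 5, 8):
            X = random_table(n, seed=n)
            tree = dt.neighbor_joining(dt.euclidean_distances(X))
            assert len(dt.bipartitions(tree)) == n - 3

    def test_branch_lengths_non_negative(self):
        for seed in range(3):
            X = random_table(8, seed=seed + 20)
            tree = dt.neighbor_joining(dt.euclidean_distances(X))
            for node in tree.traverse(include_self=False):
                assert node.length >= 0


class TestBootstrap:
    def test_deterministic_given_seed(self):
        X = random_table(5, seed=6)
        a = dt.bootstrap_trees(X, B=10, seed=1)
        b = dt.bootstrap_trees(X, B=10, seed=1)
        assert [dt.newick_string(t) for t in a] == [dt.newick_string(t) for t in b]

    def test_identical_rows_stay_coincident(self):
        X = random_table(5, seed=7)
        X.iloc[1] = X.iloc[0]
        for t in dt.bootstrap_trees(X, B=5, seed=2):
            d = t.find("t0").distance(t.find("t1"))
            assert d == pytest.approx(0.0, abs=1e-9)

    def test_invalid_b_errors(self):
        with pytest.raises(ValueError):
            dt.bootstrap_trees(random_table(4), B=0)


class TestInternodeCertainty:
    def test_unanimous_bootstraps_give_ic_one_everywhere(self):
        X = random_table(6, seed=8)
        tree = dt.neighbor_joining(dt.euclidean_distances(X))
        supports, tc = dt.internode_certainty(tree, [tree.copy() for _ in range(20)])
        assert all(s.ic == pytest.approx(1.0) for s in supports)
        assert tc == pytest.approx(len(supports))  # n - 3 edges

    def test_maximal_conflict_gives_ic_zero(self):
        # quartet: main split ab|cd in half the bootstraps, ac|bd in the other half
        main = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        alt = TreeNode.read(["((a:1,c:1):1,(b:1,d:1):1);"])
        boots = [main.copy() for _ in range(10)] + [alt.copy() for _ in range(10)]
        supports, tc = dt.internode_certainty(main, boots)
        assert len(supports) == 1
        assert supports[0].ic == pytest.approx(0.0, abs=1e-12)

    def test_seventy_thirty_closed_form(self):
        main = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        alt = TreeNode.read(["((a:1,c:1):1,(b:1,d:1):1);"])
        boots = [main.copy() for _ in range(7)] + [alt.copy() for _ in range(3)]
        supports, _ = dt.internode_certainty(main, boots)
        expected = 1 + 0.7 * math.log2(0.7) + 0.3 * math.log2(0.3)
        assert supports[0].ic == pytest.approx(expected)
        assert supports[0].f1 == pytest.approx(0.7)
        assert supports[0].f2 == pytest.approx(0.3)

    def test_ic_bounded_and_leafset_mismatch_errors(self):
        X = random_table(7, seed=9)
        tree = dt.neighbor_joining(dt.euclidean_distances(X))
        boots = dt.bootstrap_trees(X, B=30, seed=3)
        supports, tc = dt.internode_certainty(tree, boots)
        assert all(0.0 <= s.ic <= 1.0 for s in supports)
        assert 0.0 <= tc <= len(supports)
        other = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        with pytest.raises(ValueError):
            dt.internode_certainty(tree, [other])


class TestOutput:
    def test_newick_round_trips_through_reference_parser(self, tmp_path):
        X = random_table(6, seed=10)
        tree = dt.neighbor_joining(dt.euclidean_distances(X))
        path = tmp_path / "t.nwk"
        dt.write_newick(tree, path)
        back = TreeNode.read([path.read_text()])
        assert {t.name for t in back.tips()} == {t.name for t in tree.tips()}
        assert set(dt.bipartitions(back)) == set(dt.bipartitions(tree))

    def test_ic_annotation_labels_internal_nodes(self):
        X = random_table(6, seed=11)
        tree = dt.neighbor_joining(dt.euclidean_distances(X))
        boots = dt.bootstrap_trees(X, B=10, seed=4)
        supports, _ = dt.internode_certainty(tree, boots)
        annotated = dt.annotate_ic(tree, supports)
        labels = [n.name for n in annotated.non_tips(include_self=False) if n.name]
        assert len(labels) == len(supports)
        table = dt.splits_table(supports)
        assert list(table.columns) == ["split", "f1", "f2", "IC"]
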