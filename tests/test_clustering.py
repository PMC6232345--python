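"""Average-linkage clustering, inconsistency statistics and dendrogram pruning."""

import numpy as np
import pytest
from scipy.cluster import hierarchy

from wavefc.clustering import (
    GLOBAL,
    InconsistencyTable,
    LinkageTree,
    average_linkage,
    inconsistency,
    leaf_order,
    prune_by_inconsistency,
    prune_to_k,
)


def brute_force_upgma(dist):
    """O(n^3) UPGMA by direct application of the average-linkage rule.

    Returns the merge sequence as (leaf frozenset, height) pairs.
    Independent of scipy: clusters are merged by exhaustively minimizing
    the mean cross-pair distance.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [dist[i, j] for i in clusters[a] for j in clusters[b]]
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        new = clusters.pop(a) | clusters.pop(b)
        key = min(new)
        clusters[key] = new
        merges.append((new, d))
    return merges


def merge_sets_from_tree(tree: LinkageTree):
    n = tree.n_leaves
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for k in range(n - 1):
        left, right = tree.children(k)
        members[n + k] = members[left] | members[right]
        out.append((members[n + k], tree.heights[k]))
    return out


def random_distance_matrix(rng, n):
    d = rng.uniform(0.1, 2.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return d


class TestAverageLinkage:
    def test_three_point_hand_example(self):
        # d(A,B)=1, d(A,C)=4, d(B,C)=5: merge (A,B) at 1, then C at (4+5)/2
        d = np.array([[0.0, 1, 4], [1, 0, 5], [4, 5, 0]])
        tree = average_linkage(d)
        np.testing.assert_allclose(tree.heights, [1.0, 4.5])
        assert set(tree.children(0)) == {0, 1}

    def test_identical_points_merge_at_zero(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = 1.0
        d[1, 2] = d[2, 1] = 1.0
        tree = average_linkage(d)
        assert tree.heights[0] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 9)
            d = random_distance_matrix(rng, n)
            got = merge_sets_from_tree(average_linkage(d))
            expected = brute_force_upgma(d)
            for (gs, gh), (es, eh) in zip(got, expected):
                assert gs == es
                assert gh == pytest.approx(eh, abs=1e-10)

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            average_linkage(d)


class TestInconsistency:
    def chain_tree(self, heights):
        """Caterpillar dendrogram with the given merge heights."""
        n = len(heights) + 1
        merges = []
        prev = 0
        for k, h in enumerate(heights):
            merges.append([prev, k + 1, h, k + 2])
            prev = n + k
        return LinkageTree(np.array(merges, dtype=float), n)

    def test_leaf_leaf_link_is_zero(self):
        tree = self.chain_tree([1.0, 2.0])
        table = inconsistency(tree, g=2)
        assert table.y4[0] == 0.0

    def test_hand_computed_window(self):
        # link z=4 with one sub-link z=2: Y1=3, Y2=sqrt(2), Y4=1/sqrt(2)
        tree = self.chain_tree([2.0, 4.0])
        table = inconsistency(tree, g=2)
        assert table.y1[1] == pytest.approx(3.0)
        assert table.y2[1] == pytest.approx(np.sqrt(2))
        assert table.y4[1] == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_uniform_heights_are_consistent(self):
        tree = self.chain_tree([1.0, 1.0, 1.0, 1.0])
        table = inconsistency(tree, g=3)
        np.testing.assert_allclose(table.y4, 0.0)

    @pytest.mark.parametrize("g,depth", [(2, 2), (3, 3), (4, 4)])
    def test_matches_scipy_inconsistent(self, g, depth):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tree = average_linkage(random_distance_matrix(rng, 10))
            mine = inconsistency(tree, g=g)
            ref = hierarchy.inconsistent(tree.merges, d=depth)
            np.testing.assert_allclose(mine.y1, ref[:, 0], atol=1e-10)
            np.testing.assert_allclose(mine.y2, ref[:, 1], atol=1e-10)
            np.testing.assert_allclose(mine.y4, ref[:, 3], atol=1e-8)

    def test_global_equals_deep_window(self):
        rng = np.random.default_rng(2)
        tree = average_linkage(random_distance_matrix(rng, 12))
        glob = inconsistency(tree, g=GLOBAL)
        deep = inconsistency(tree, g=500)
        np.testing.assert_allclose(glob.y4, deep.y4, atol=1e-10)

    def test_direct_two_level_window_oracle(self):
        # independent recomputation of the g=2 statistic on every link
        rng = np.random.default_rng(3)
        tree = average_linkage(random_distance_matrix(rng, 15))
        table = inconsistency(tree, g=2)
        n = tree.n_leaves
        for k in range(n - 1):
            window = [tree.heights[k]] + [
                tree.heights[int(c) - n]
                for c in tree.merges[k, :2]
                if c >= n
            ]
            if len(window) == 1 or np.std(window, ddof=1) < 1e-12:
                expected = 0.0
            else:
                expected = (window[0] - np.mean(window)) / np.std(window, ddof=1)
            assert table.y4[k] == pytest.approx(expected, abs=1e-10)

    def test_invalid_g_rejected(self):
        tree = self.chain_tree([1.0, 2.0])
        with pytest.raises(ValueError):
            inconsistency(tree, g=1)


class TestPruning:
    def two_block_tree(self):
        """10 leaves, two tight blocks joined by one high (inconsistent) root."""
        merges = []
        prev = 0
        for k in range(4):  # block {0..4} at heights 1
            merges.append([prev, k + 1, 1.0, k + 2])
            prev = 10 + k
        prev_b = 5
        for k in range(4):  # block {5..9} at heights 1
            merges.append([prev_b, 6 + k, 1.0, k + 2])
            prev_b = 14 + k
        merges.append([13, 17, 10.0, 10])
        return LinkageTree(np.array(merges, dtype=float), 10)

    def test_high_threshold_single_cluster(self):
        tree = self.two_block_tree()
        table = inconsistency(tree, g=2)
        part = prune_by_inconsistency(tree, table, threshold=table.y4.max())
        assert part.n_clusters == 1

    def test_negative_threshold_all_singletons(self):
        tree = self.two_block_tree()
        table = inconsistency(tree, g=2)
        part = prune_by_inconsistency(tree, table, threshold=-0.5)
        assert part.n_clusters == 10

    def test_one_inconsistent_link_gives_two_clusters(self):
        tree = self.two_block_tree()
        table = inconsistency(tree, g=2)
        assert np.argmax(table.y4) == 8  # the root
        part = prune_by_inconsistency(tree, table, threshold=1.0)
        assert part.n_clusters == 2
        labels = part.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_matches_scipy_fcluster(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            tree = average_linkage(random_distance_matrix(rng, 12))
            table = inconsistency(tree, g=2)
            rmat = np.column_stack([table.y1, table.y2, table.count, table.y4])
            for t in [0.3, 0.7, 1.0, 1.2]:
                ref = hierarchy.fcluster(
                    tree.merges, t=t, criterion="inconsistent", R=rmat
                )
                mine = prune_by_inconsistency(tree, table, t).labels
                # agreement up to relabeling
                assert len(np.unique(ref)) == len(np.unique(mine))
                joint = {(a, b) for a, b in zip(ref, mine)}
                assert len(joint) == len(np.unique(ref))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        tree = average_linkage(random_distance_matrix(rng, 20))
        table = inconsistency(tree, g=GLOBAL)
        counts = [
            prune_by_inconsistency(tree, table, t).n_clusters
            for t in np.linspace(-0.5, table.y4.max() + 0.1, 12)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_prune_to_k_exact_counts(self):
        rng = np.random.default_rng(6)
        tree = average_linkage(random_distance_matrix(rng, 15))
        for k in range(1, 16):
            assert prune_to_k(tree, k).n_clusters == k

    def test_prune_to_k_extremes_and_range(self):
        rng = np.random.default_rng(7)
        tree = average_linkage(random_distance_matrix(rng, 8))
        assert prune_to_k(tree, 1).n_clusters == 1
        assert prune_to_k(tree, 8).n_clusters == 8
        for k in (0, 9):
            with pytest.raises(ValueError):
                prune_to_k(tree, k)

    def test_prune_to_k_matches_height_cut(self):
        # membership equals an independent union of the n-k lowest merges
        rng = np.random.default_rng(8)
        d = random_distance_matrix(rng, 12)
        tree = average_linkage(d)
        for k in (2, 4, 7):
            labels = prune_to_k(tree, k).labels
            parent = list(range(23))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for m in range(12 - k):
                a, b = tree.children(m)
                parent[find(a)] = find(12 + m)
                parent[find(b)] = find(12 + m)
            roots = [find(i) for i in range(12)]
            assert len(set(roots)) == k
            joint = {(r, l) for r, l in zip(roots, labels)}
            assert len(joint) == k


class TestLeafOrder:
    def test_two_leaves(self):
        tree = LinkageTree(np.array([[0, 1, 1.0, 2]]), 2)
        np.testing.assert_array_equal(leaf_order(tree), [0, 1])

    def test_children_contiguous(self):
        rng = np.random.default_rng(9)
        d = random_distance_matrix(rng, 10)
        tree = average_linkage(d)
        order = leaf_order(tree, d)
        pos = np.empty(10, dtype=int)
        pos[order] = np.arange(10)
        for members, _ in merge_sets_from_tree(tree):
            positions = sorted(pos[list(members)])
            assert positions == list(range(positions[0], positions[-1] + 1))

    def test_reduces_adjacent_dissimilarity(self):
        rng = np.random.default_rng(10)
        d = random_distance_matrix(rng, 8)
        tree = average_linkage(d)
        order = leaf_order(tree, d)
        cost = sum(d[a, b] for a, b in zip(order, order[1:]))
        baseline = sum(d[i, i + 1] for i in range(7))
        assert cost <= baseline + 1e-12
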