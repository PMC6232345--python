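"""Average-linkage hierarchical clustering with inconsistency-based pruning.

Clustering proceeds agglomeratively from a voxel-by-voxel correlation
distance matrix: at each step the pair of clusters with the smallest
average cross-pair distance (UPGMA linkage,
``S2(a,b) = 1/(na*nb) * sum_{i in a, j in b} S1(i,j)``) merges, producing a
dendrogram.  Flat parcellations are obtained either by requesting a number
of clusters or by pruning links whose *inconsistency* — a z-score of a
link's height against the heights of links beneath it within a window of
``g`` dendrogram levels — exceeds a threshold.  Small ``g`` flags locally
abrupt merges; ``g = "global"`` uses each link's whole subtree and gives a
globally representative assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LinkageTree",
    "InconsistencyTable",
    "Partition",
    "GLOBAL",
    "average_linkage",
    "inconsistency",
    "prune_by_inconsistency",
    "prune_to_k",
    "leaf_order",
]

#: sentinel for a whole-subtree inconsistency window ("g >> 2")
GLOBAL = "global"


@dataclass
class LinkageTree:
    """Agglomerative merge structure in SciPy linkage format.

    ``merges`` is the ``(n - 1, 4)`` array whose row ``k`` holds
    ``(left id, right id, height z(k), merged size)``; ids below ``n`` are
    leaves, id ``n + k`` is the cluster created by merge ``k``.
    """

    merges: np.ndarray
    n_leaves: int

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError(
                f"expected {(self.n_leaves - 1, 4)} merge table, "
                f"got {self.merges.shape}"
            )

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def children(self, k: int) -> tuple[int, int]:
        return int(self.merges[k, 0]), int(self.merges[k, 1])

    def internal_children(self, k: int) -> list[int]:
        """Merge indices of the non-leaf children of merge ``k``."""
        return [int(c) - self.n_leaves for c in self.merges[k, :2] if c >= self.n_leaves]


@dataclass
class Partition:
    """Flat cluster labels per voxel, with provenance of the pruning."""

    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class InconsistencyTable:
    """Per-link inconsistency statistics.

    ``y1``/``y2`` are the mean and sample standard deviation of the link
    heights in each link's window, ``count`` the number of links in the
    window, and ``y4 = (z(k) - y1) / y2`` the inconsistency, defined as 0
    for degenerate windows (single link, or zero spread).
    """

    y1: np.ndarray
    y2: np.ndarray
    count: np.ndarray
    y4: np.ndarray
    g: object = 2

    def __len__(self) -> int:
        return len(self.y4)


def average_linkage(distance_matrix: np.ndarray) -> LinkageTree:
    """UPGMA (average-linkage) dendrogram of a symmetric distance matrix."""
    dist = np.asarray(distance_matrix, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    condensed = squareform(dist, checks=False)
    merges = hierarchy.linkage(condensed, method="average")
    return LinkageTree(merges=merges, n_leaves=n)


def inconsistency(tree: LinkageTree, g=2) -> InconsistencyTable:
    """Inconsistency of every link against the links beneath it.

    For integer ``g >= 2`` the window of link ``k`` contains the heights of
    ``k`` itself and of all links within ``g - 1`` dendrogram levels
    beneath it (the convention of the classic dendrogram-inconsistency
    statistic; ``g = 2`` uses the link and its direct sub-links).  With
    ``g = GLOBAL`` the window is the link's entire subtree of links.
    """
    n_links = tree.n_leaves - 1
    heights = tree.heights
    y1 = np.zeros(n_links)
    y2 = np.zeros(n_links)
    count = np.zeros(n_links, dtype=int)
    y4 = np.zeros(n_links)

    if g == GLOBAL or g is np.inf:
        cnt = np.zeros(n_links)
        s1 = np.zeros(n_links)
        s2 = np.zeros(n_links)
        for k in range(n_links):
            cnt[k], s1[k], s2[k] = 1.0, heights[k], heights[k] ** 2
            for c in tree.internal_children(k):
                cnt[k] += cnt[c]
                s1[k] += s1[c]
                s2[k] += s2[c]
        count[:] = cnt
        y1[:] = s1 / cnt
        with np.errstate(invalid="ignore"):
            var = np.maximum(s2 - cnt * y1**2, 0.0) / np.maximum(cnt - 1, 1)
        y2[:] = np.sqrt(var)
    else:
        if not (isinstance(g, (int, np.integer)) and g >= 2):
            raise ValueError(f"g must be an integer >= 2 or GLOBAL, got {g!r}")
        for k in range(n_links):
            window = [heights[k]]
            frontier = [k]
            for _ in range(g - 1):
                nxt: list[int] = []
                for node in frontier:
                    nxt.extend(tree.internal_children(node))
                window.extend(heights[c] for c in nxt)
                frontier = nxt
                if not frontier:
                    break
            w = np.asarray(window)
            count[k] = len(w)
            y1[k] = w.mean()
            y2[k] = w.std(ddof=1) if len(w) > 1 else 0.0
    degenerate = (count <= 1) | (y2 <= 1e-12)
    ok = ~degenerate
    y4[ok] = (heights[ok] - y1[ok]) / y2[ok]
    return InconsistencyTable(y1=y1, y2=y2, count=count, y4=y4, g=g)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _labels_from_merge_flags(tree: LinkageTree, keep: np.ndarray) -> np.ndarray:
    """Flat labels from the set of merges still in effect.

    Labels are contiguous from 1, numbered by first occurrence in voxel
    order.
    """
    n = tree.n_leaves
    uf = _UnionFind(2 * n - 1)
    for k in np.flatnonzero(keep):
        left, right = tree.children(k)
        uf.union(left, n + k)
        uf.union(right, n + k)
    roots = np.array([uf.find(i) for i in range(n)])
    _, labels = np.unique(roots, return_index=False, return_inverse=True)
    # renumber by first occurrence so labels are deterministic in voxel order
    order = np.full(labels.max() + 1, -1, dtype=int)
    nxt = 1
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if order[lab] < 0:
            order[lab] = nxt
            nxt += 1
        out[i] = order[lab]
    return out


def prune_by_inconsistency(
    tree: LinkageTree,
    table: InconsistencyTable,
    threshold: float,
) -> Partition:
    """Cut all links with inconsistency above ``threshold`` and their dependents.

    A cluster is a maximal subtree containing no link whose inconsistency
    exceeds the threshold: cutting a link also invalidates every link above
    it that depended on the merged cluster.  A threshold below the minimum
    inconsistency yields all singletons; one at or above the maximum yields
    a single cluster.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    n_links = tree.n_leaves - 1
    if len(table) != n_links:
        raise ValueError("inconsistency table does not match tree")
    consistent = np.zeros(n_links, dtype=bool)
    for k in range(n_links):
        ok = table.y4[k] <= threshold
        for c in tree.internal_children(k):
            ok = ok and consistent[c]
        consistent[k] = ok
    labels = _labels_from_merge_flags(tree, consistent)
    return Partition(
        labels=labels,
        provenance={"method": "inconsistency", "g": table.g, "threshold": threshold},
    )


def prune_to_k(tree: LinkageTree, k: int) -> Partition:
    """Cut the ``k - 1`` highest links, leaving exactly ``k`` clusters."""
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    keep = np.ones(n - 1, dtype=bool)
    if k > 1:
        # merges are height-ordered, so the last k-1 merges are the highest
        keep[n - k :] = False
    labels = _labels_from_merge_flags(tree, keep)
    return Partition(labels=labels, provenance={"method": "maxclust", "k": k})


def leaf_order(tree: LinkageTree, distance_matrix: np.ndarray | None = None) -> np.ndarray:
    """Leaf permutation for a 1-D dendrogram layout.

    Children of every merge remain contiguous.  When the distance matrix is
    supplied, the ordering additionally minimizes the summed dissimilarity
    between adjacent leaves (optimal leaf ordering); otherwise the plain
    dendrogram order is returned.  Deterministic in both cases.
    """
    if distance_matrix is None:
        return hierarchy.leaves_list(tree.merges.copy())
    condensed = squareform(np.asarray(distance_matrix, dtype=float), checks=False)
    ordered = hierarchy.optimal_leaf_ordering(tree.merges.copy(), condensed)
    return hierarchy.leaves_list(ordered)
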