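"""Jaccard similarity between window sets and hierarchical clusterograms."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .window_eval import WindowSet

__all__ = [
    "SimilarityMatrix",
    "Dendrogram",
    "jaccard",
    "similarity_matrix",
    "cluster",
    "cut_tree",
]


@dataclass
class SimilarityMatrix:
    labels: list[str]
    J: np.ndarray  # symmetric, diagonal 1, entries in [0, 1]

    def to_distance(self) -> np.ndarray:
        return 1.0 - self.J


@dataclass
class Dendrogram:
    """Agglomerative merge history.

    Each merge is (left cluster id, right cluster id, height, size); leaves
    are 0..n-1, the cluster created by merge i gets id n+i (scipy linkage
    convention).
    """

    merges: list[tuple[int, int, float, int]]
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order of the tree drawing."""
        children: dict[int, tuple[int, int]] = {}
        for i, (a, b, _, _) in enumerate(self.merges):
            children[self.n_leaves + i] = (a, b)

        def leaves(node: int) -> list[int]:
            if node < self.n_leaves:
                return [node]
            a, b = children[node]
            return leaves(a) + leaves(b)

        root = self.n_leaves + len(self.merges) - 1
        return leaves(root) if self.merges else [0]


def jaccard(a: WindowSet, b: WindowSet) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both sets are empty."""
    a._check_compatible(b)
    union = len(a.ids | b.ids)
    if union == 0:
        return 1.0
    return len(a.ids & b.ids) / union


def similarity_matrix(window_sets: list[WindowSet],
                      labels: list[str]) -> SimilarityMatrix:
    if len(window_sets) < 2:
        raise ValueError("need at least 2 window sets")
    if len(labels) != len(window_sets):
        raise ValueError("labels/window-set count mismatch")
    n = len(window_sets)
    J = np.ones((n, n), dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            J[i, j] = J[j, i] = jaccard(window_sets[i], window_sets[j])
    return SimilarityMatrix(list(labels), J)


def cluster(S: SimilarityMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering on the Jaccard distance D = 1 - J.

    Ties are broken by the smallest (i, j) cluster-id pair so the tree is
    reproducible across platforms.
    """
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    D = S.to_distance()
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances")
    n = len(S.labels)
    if n < 2:
        raise ValueError("need at least 2 labels")

    # active cluster id -> (members as leaf indices)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = active[a] + active[b]
        size = len(members)
        merges.append((a, b, h, size))
        del active[a], active[b]
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, cm in active.items():
            if linkage == "average":
                d = float(np.mean(D[np.ix_(members, cm)]))
            elif linkage == "single":
                d = float(np.min(D[np.ix_(members, cm)]))
            else:
                d = float(np.max(D[np.ix_(members, cm)]))
            dist[(min(c, next_id), max(c, next_id))] = d
        active[next_id] = members
        next_id += 1
    return Dendrogram(merges, list(S.labels))


def cut_tree(tree: Dendrogram, k: int) -> list[int]:
    """Flat cluster labels (0..k-1, in leaf order of first appearance)
    obtained by undoing the last k-1 merges."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (a, b, _, _) in enumerate(tree.merges[: n - k]):
        node = n + i
        parent[find(a)] = node
        parent[find(b)] = node

    roots: dict[int, int] = {}
    out = []
    for leaf in range(n):
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        out.append(roots[r])
    return out


def write_similarity_tsv(S: SimilarityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("label\t" + "\t".join(S.labels) + "\n")
        for i, lab in enumerate(S.labels):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in S.J[i]) + "\n")


def write_dendrogram_tsv(tree: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("# leaves\t" + "\t".join(tree.labels) + "\n")
        fh.write("left\tright\theight\tsize\n")
        for a, b, h, size in tree.merges:
            fh.write(f"{a}\t{b}\t{h:.10g}\t{size}\n")
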