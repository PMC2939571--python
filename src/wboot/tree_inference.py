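"""Neighbor-Joining tree inference, patristic distances and splits.

The NJ implementation follows Saitou & Nei's agglomeration with Studier &
Keppler's O(n^3) Q-criterion.  Two properties are pinned down that generic
library implementations leave open:

* ties in the Q matrix are broken by the lexicographically smallest
  (row, column) index pair, so results are identical across platforms;
* negative branch lengths are retained, not clamped — the least-squares
  fit downstream measures the tree exactly as NJ produced it.

A lightweight internal representation (:class:`NJTree`) carries the edge
list, per-cluster leaf sets and patristic matrix without the overhead of a
full :class:`~wboot.io_formats.Phylogeny`; the public operations wrap it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .io_formats import Phylogeny, SplitSet, WbootError

__all__ = [
    "neighbor_joining",
    "patristic_matrix",
    "nontrivial_splits",
    "NJTree",
    "nj_tree",
]


@dataclass
class NJTree:
    """Edge-list form of an NJ tree over leaves ``0 .. n-1``.

    ``edges`` entries are ``(node_a, node_b, length)``; internal node ids
    start at ``n``.  ``clusters`` is parallel to ``edges`` and holds, for
    each edge, the set of leaf indices on its far (child) side; trivial
    (single-leaf) entries are filtered out by :meth:`split_indices`.
    """

    n: int
    edges: list[tuple[int, int, float]]
    clusters: list[frozenset[int]]

    def split_indices(self) -> list[frozenset[int]]:
        """Canonical non-trivial splits as leaf-index sets (ordered)."""
        full = frozenset(range(self.n))
        out: list[frozenset[int]] = []
        seen: set[frozenset[int]] = set()
        for cluster in self.clusters:
            side = full - cluster if 0 in cluster else cluster
            if side not in seen and 2 <= len(side) <= self.n - 2:
                seen.add(side)
                out.append(side)
        return out

    def patristic(self) -> np.ndarray:
        adj: dict[int, list[tuple[int, float]]] = {}
        for a, b, w in self.edges:
            adj.setdefault(a, []).append((b, w))
            adj.setdefault(b, []).append((a, w))
        n = self.n
        out = np.zeros((n, n))
        for src in range(n):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nb, w in adj[node]:
                    if nb not in dist:
                        dist[nb] = dist[node] + w
                        stack.append(nb)
            for leaf in range(n):
                out[src, leaf] = dist[leaf]
        return out

    def to_phylogeny(self, taxa: tuple[str, ...]) -> Phylogeny:
        return Phylogeny(taxa, tuple(self.edges))


def nj_tree(d: np.ndarray) -> NJTree:
    """Run Neighbor-Joining on a raw distance array.

    Deterministic: Q-matrix ties resolve to the first minimum in row-major
    order, i.e. the lexicographically smallest (row, column) pair of active
    node indices.
    """
    d = np.array(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise WbootError(f"Neighbor-Joining needs at least 3 taxa, got {n}")
    if not np.all(np.isfinite(d)):
        raise WbootError("non-finite entries in distance matrix")

    # active working copy; `nodes` maps working index -> tree node id
    nodes = list(range(n))
    leafsets = [frozenset([i]) for i in range(n)]
    next_id = n
    edges: list[tuple[int, int, float]] = []
    clusters: list[frozenset[int]] = []

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # first minimum in row-major order = lexicographically smallest pair
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new_set = leafsets[i] | leafsets[j]
        edges.append((next_id, nodes[i], li))
        edges.append((next_id, nodes[j], lj))
        clusters.append(leafsets[i])
        clusters.append(leafsets[j])

        dk = 0.5 * (d[i, :] + d[j, :] - dij)
        # replace row i with the new cluster, drop row j
        d[i, :] = dk
        d[:, i] = dk
        d[i, i] = 0.0
        keep = [k for k in range(m) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = next_id
        leafsets[i] = new_set
        del nodes[j], leafsets[j]
        next_id += 1

    # terminal star over the last three nodes
    a, b, c = 0, 1, 2
    center = next_id
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        edges.append((center, nodes[k], lk))
        clusters.append(leafsets[k])
    return NJTree(n, edges, clusters)


def neighbor_joining(D: DistanceMatrix) -> Phylogeny:
    """Infer an unrooted NJ tree from a :class:`DistanceMatrix`.

    Fully resolved for n >= 4; deterministic given ``D``.
    """
    return nj_tree(D.values).to_phylogeny(D.taxa)


def patristic_matrix(tree: Phylogeny) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree with branch lengths."""
    values = tree.patristic()
    # NJ can yield negative branch lengths; the patristic sums may then dip
    # below zero on adversarial inputs — still a valid fit target for LS,
    # but DistanceMatrix requires symmetry/zero-diagonal only.
    return DistanceMatrix(tree.taxa, values)


def nontrivial_splits(tree: Phylogeny) -> SplitSet:
    """Canonical non-trivial splits of a tree (one per internal branch)."""
    if tree.n < 4:
        return frozenset()
    return tree.splits()
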