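"""Independent brute-force oracles used to validate the implementation.

Kept deliberately naive: topology enumeration plus ordinary least squares
for tree fitting, and plain Python loops for weighted support.  Nothing
here shares code with the package's own algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All distinct unrooted binary topologies over leaves 0..n-1.

    Built by inserting each new leaf into every edge of every smaller
    topology; yields 3, 15, 105 trees for n = 4, 5, 6.  Edge lists use
    internal node ids starting at n.
    """
    trees: list[list[tuple[int, int]]] = [[(n, 0), (n, 1), (n, 2)]]
    next_internal = n + 1
    for leaf in range(3, n):
        grown: list[list[tuple[int, int]]] = []
        for edges in trees:
            for k in range(len(edges)):
                a, b = edges[k]
                mid = next_internal
                new = edges[:k] + edges[k + 1:] + [(a, mid), (mid, b), (mid, leaf)]
                grown.append(new)
        trees = grown
        next_internal += 1
    return trees


def _paths(edges: list[tuple[int, int]], n: int) -> dict[tuple[int, int], list[int]]:
    """Edge indices on the path between each leaf pair."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for e, (a, b) in enumerate(edges):
        adj.setdefault(a, []).append((b, e))
        adj.setdefault(b, []).append((a, e))
    out = {}
    for src in range(n):
        prev: dict[int, tuple[int, int]] = {src: (-1, -1)}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, e in adj[node]:
                if nb not in prev:
                    prev[nb] = (node, e)
                    stack.append(nb)
        for dst in range(src + 1, n):
            path = []
            node = dst
            while node != src:
                node, e = prev[node]
                path.append(e)
            out[(src, dst)] = path
    return out


def ols_fit(edges: list[tuple[int, int]], d: np.ndarray) -> tuple[float, np.ndarray]:
    """Ordinary-least-squares edge lengths for a fixed topology.

    Returns (sum of squared residuals, fitted patristic matrix).
    """
    n = d.shape[0]
    paths = _paths(edges, n)
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([d[i, j] for i, j in pairs])
    for r, pair in enumerate(pairs):
        for e in paths[pair]:
            A[r, e] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ x
    resid = float(np.sum((fitted - y) ** 2))
    delta = np.zeros_like(d)
    for (i, j), f in zip(pairs, fitted):
        delta[i, j] = delta[j, i] = f
    return resid, delta


def topology_splits(edges: list[tuple[int, int]], n: int) -> frozenset[frozenset[int]]:
    """Canonical non-trivial splits (leaf-index sets not containing 0)."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    splits = set()
    for a, b in edges:
        # leaves reachable from b without crossing a
        seen = {a, b}
        stack = [b]
        side = set()
        while stack:
            node = stack.pop()
            if node < n:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return frozenset(splits)


def best_tree_by_enumeration(d: np.ndarray):
    """Exhaustive topology search with OLS fitting.

    Returns (splits, residual, fitted patristic) of the best-fitting
    topology; for an additive matrix the residual is ~0 and the topology
    is the generating one.
    """
    n = d.shape[0]
    best = None
    for edges in enumerate_topologies(n):
        resid, delta = ols_fit(edges, d)
        if best is None or resid < best[1]:
            best = (topology_splits(edges, n), resid, delta)
    return best


def weighted_support_bruteforce(ref_splits, rep_splits, weights):
    """Plain-loop reference for the weighted support score."""
    scores = []
    for split in ref_splits:
        total = 0.0
        for w, splits in zip(weights, rep_splits):
            if split in splits:
                total += w
        scores.append(100.0 * total)
    return scores
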