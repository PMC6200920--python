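"""Independent brute-force oracles for verification.

These deliberately naive implementations exist only to check the fast
paths: a substring-enumeration cleavage scanner to verify
:func:`rfamide.processing.predict_from_sequence`, and an exhaustive
unrooted-topology enumerator with least-squares branch fitting to verify
:func:`rfamide.phylo.neighbor_joining` on additive distance matrices.
They share no code with the implementations they test.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "brute_force_scan",
    "enumerate_topologies",
    "topology_bipartitions",
    "best_topology_ls",
    "random_additive_matrix",
]

_BASIC = set("KR")


def brute_force_scan(
    sequence: str,
    min_len: int = 4,
    max_len: int = 40,
) -> list[tuple[int, int, str]]:
    """Enumerate substrings and test the flank conditions directly.

    Returns (start, end, basic_run) triples; one call per amidation
    cassette, with the body chosen as the shortest substring of length
    >= ``min_len`` whose left flank is a basic residue (falling back to
    the shortest flanked substring, then to the full N-terminal prefix).
    """
    calls = []
    n = len(sequence)
    for g in range(n):
        if sequence[g] != "G" or g + 1 >= n or sequence[g + 1] not in _BASIC:
            continue
        run = sequence[g + 1 : g + 3]
        if len(run) == 2 and run[1] not in _BASIC:
            run = run[:1]
        # all substrings ending at the glycine with a basic left flank
        flanked = [
            s for s in range(1, g + 1) if sequence[s - 1] in _BASIC
        ]
        preferred = [s for s in flanked if g - s >= min_len]
        if preferred:
            start = max(preferred)  # shortest acceptable body
        elif flanked:
            start = max(flanked)
        else:
            start = 0
        body = sequence[start:g]
        if not min_len <= len(body) <= max_len:
            continue
        calls.append((start, g, run))
    return sorted(calls)


# ---------------------------------------------------------------------------
# exhaustive NJ oracle


def enumerate_topologies(n: int) -> list[list[tuple[int, int]]]:
    """All distinct unrooted binary topologies over leaves 0..n-1.

    Leaves are nodes 0..n-1; internal nodes are numbered from n upward.
    Built by inserting each leaf into every edge of every smaller topology
    ((2n-5)!! trees for n leaves).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    topologies = [[(0, n), (1, n), (2, n)]]
    for leaf in range(3, n):
        new_internal = n + leaf - 2
        expanded = []
        for edges in topologies:
            for idx in range(len(edges)):
                u, v = edges[idx]
                expanded.append(
                    edges[:idx]
                    + edges[idx + 1 :]
                    + [(u, new_internal), (v, new_internal), (leaf, new_internal)]
                )
        topologies = expanded
    return topologies


def _adjacency(edges):
    adj: dict[int, list[tuple[int, int]]] = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    return adj


def _leaf_paths(edges, n: int) -> np.ndarray:
    """Design matrix: rows = leaf pairs (i<j), cols = edges on the path."""
    adj = _adjacency(edges)
    n_pairs = n * (n - 1) // 2
    A = np.zeros((n_pairs, len(edges)))
    for i in range(n):
        # BFS from leaf i recording the edge used to reach each node
        parent_edge = {i: None}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, k in adj[u]:
                if v not in parent_edge:
                    parent_edge[v] = (u, k)
                    stack.append(v)
        row = 0
        for a in range(n):
            for b in range(a + 1, n):
                if a == i:
                    node = b
                    while node != i:
                        prev, k = parent_edge[node]
                        A[row, k] = 1
                        node = prev
                row += 1
    return A


def topology_bipartitions(edges, n: int) -> frozenset[frozenset[int]]:
    """Non-trivial leaf splits of a topology (canonical side excludes 0)."""
    adj = _adjacency(edges)
    splits = set()
    for u, v in edges:
        # leaves on v's side of the edge (u, v)
        seen = {u, v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(x)
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 0 in side:
            side = set(range(n)) - side
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(side))
    return frozenset(splits)


@lru_cache(maxsize=8)
def _topology_cache(n: int):
    """(residual operators stacked, bipartitions per topology)."""
    topologies = enumerate_topologies(n)
    n_pairs = n * (n - 1) // 2
    residual_ops = np.empty((len(topologies), n_pairs, n_pairs))
    splits = []
    eye = np.eye(n_pairs)
    for t, edges in enumerate(topologies):
        A = _leaf_paths(edges, n)
        residual_ops[t] = eye - A @ np.linalg.pinv(A)
        splits.append(topology_bipartitions(edges, n))
    return residual_ops, splits


def best_topology_ls(D: np.ndarray) -> tuple[frozenset[frozenset[int]], float]:
    """Least-squares best unrooted topology for a distance matrix.

    Exhaustively fits every topology (unconstrained least squares on
    branch lengths) and returns the bipartition set of the best fit plus
    its residual norm.  For an additive matrix the generating topology is
    the unique zero-residual fit.
    """
    n = D.shape[0]
    residual_ops, splits = _topology_cache(n)
    d = D[np.triu_indices(n, k=1)]
    residuals = np.linalg.norm(residual_ops @ d, axis=1)
    best = int(np.argmin(residuals))
    return splits[best], float(residuals[best])


def random_additive_matrix(
    rng: np.random.Generator, n: int, lo: float = 0.1, hi: float = 1.0
) -> tuple[np.ndarray, frozenset[frozenset[int]]]:
    """A random additive distance matrix plus its generating splits.

    Draws a uniform random unrooted binary topology (random edge insertion
    order) with branch lengths ~ U(lo, hi) and returns leaf path lengths.
    """
    edges = [(0, n), (1, n), (2, n)]
    for leaf in range(3, n):
        idx = int(rng.integers(0, len(edges)))
        u, v = edges.pop(idx)
        w = n + leaf - 2
        edges += [(u, w), (v, w), (leaf, w)]
    lengths = rng.uniform(lo, hi, size=len(edges))
    A = _leaf_paths(edges, n)
    d = A @ lengths
    D = np.zeros((n, n))
    D[np.triu_indices(n, k=1)] = d
    D = D + D.T
    return D, topology_bipartitions(edges, n)
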