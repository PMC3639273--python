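"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: plain BFS, explicit shortest-path
enumeration, residual regression.  None of it shares code with the package.
"""

from __future__ import annotations

import numpy as np


def bfs_distances(A: np.ndarray, source: int) -> np.ndarray:
    """Single-source unweighted distances by hand-rolled BFS."""
    n = A.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in range(n):
                if A[v, w] and np.isinf(dist[w]):
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def all_pairs_distances(A: np.ndarray) -> np.ndarray:
    return np.array([bfs_distances(A, s) for s in range(A.shape[0])])


def clustering_bruteforce(A: np.ndarray) -> np.ndarray:
    """C_i by explicit iteration over neighbour pairs."""
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1
            for a in range(k)
            for b in range(a + 1, k)
            if A[nbrs[a], nbrs[b]]
        )
        out[i] = links / (k * (k - 1) / 2)
    return out


def local_efficiency_bruteforce(A: np.ndarray) -> np.ndarray:
    """Eloc_i via BFS inside the neighbour-induced subgraph."""
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        d = all_pairs_distances(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]):
                    total += 1.0 / d[a, b]
        out[i] = total / (k * (k - 1))
    return out


def path_length_bruteforce(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal mean path length over reachable peers, and global efficiency."""
    n = A.shape[0]
    d = all_pairs_distances(A)
    li = np.full(n, np.nan)
    inv_sum = 0.0
    for i in range(n):
        finite = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if finite:
            li[i] = float(np.mean(finite))
        inv_sum += sum(
            1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])
        )
    geff = inv_sum / (n * (n - 1)) if n > 1 else np.nan
    return li, geff


def enumerate_shortest_paths(A: np.ndarray, h: int, j: int) -> list[list[int]]:
    """All shortest h-j paths by DFS restricted to distance-decreasing steps."""
    dist_to_j = bfs_distances(A, j)
    if np.isinf(dist_to_j[h]):
        return []
    paths: list[list[int]] = []

    def walk(v: int, path: list[int]) -> None:
        if v == j:
            paths.append(path.copy())
            return
        for w in range(A.shape[0]):
            if A[v, w] and dist_to_j[w] == dist_to_j[v] - 1:
                path.append(w)
                walk(w, path)
                path.pop()

    walk(h, [h])
    return paths


def betweenness_bruteforce(A: np.ndarray) -> np.ndarray:
    """b_i by exhaustive enumeration of every shortest path, unordered pairs."""
    n = A.shape[0]
    b = np.zeros(n)
    for h in range(n):
        for j in range(h + 1, n):
            paths = enumerate_shortest_paths(A, h, j)
            if not paths:
                continue
            sigma = len(paths)
            for i in range(n):
                if i in (h, j):
                    continue
                through = sum(1 for p in paths if i in p)
                b[i] += through / sigma
    return b


def partial_correlation_residual(X: np.ndarray) -> np.ndarray:
    """Partial correlations via residuals of each pair on the other rows."""
    n = X.shape[0]
    rho = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            others = [k for k in range(n) if k not in (i, j)]
            Z = np.vstack([np.ones(X.shape[1]), X[others]]).T
            ri = X[i] - Z @ np.linalg.lstsq(Z, X[i], rcond=None)[0]
            rj = X[j] - Z @ np.linalg.lstsq(Z, X[j], rcond=None)[0]
            r = float(np.corrcoef(ri, rj)[0, 1])
            rho[i, j] = rho[j, i] = r
    return rho


def random_adjacency(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Erdos-Renyi G(n, p) adjacency matrix."""
    upper = rng.random((n, n)) < p
    A = np.triu(upper, 1)
    return (A | A.T).astype(int)
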