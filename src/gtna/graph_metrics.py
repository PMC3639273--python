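"""Nodal and network-level graph metrics for binary/weighted brain networks.

Implements the full metric set of the analysis: degree K_i, density,
connection strength S_i (sum of partial-correlation weights), clustering
coefficient C_i, local efficiency Eloc_i, nodal mean path length L_i,
global efficiency, and unnormalised betweenness centrality b_i, plus the
small-world normalisation of clustering and path length against analytic
random-graph estimates (C_rand = k/N and, after Fronczak et al.,
L_rand = ((ln N - gamma) / ln k) + 0.5 with gamma Euler's constant).

Conventions (recorded in output metadata by the pipeline):

* clustering and local efficiency are 0 for nodes of degree < 2;
* nodal path length averages over *reachable* peers only; isolated nodes
  get a missing (NaN) value excluded from the network mean, and global
  efficiency (with 1/inf = 0) is reported alongside as the
  disconnection-robust integration measure;
* betweenness counts unordered pairs and is unnormalised, matching the
  magnitude of ~N for small brain networks.

All topological metrics operate on the binary adjacency; the weighted
companion matrix contributes only through strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .connectivity import NetworkGraph

__all__ = [
    "EULER_GAMMA",
    "NodalMetrics",
    "NetworkMetrics",
    "degree_and_density",
    "density_from_mean_degree",
    "strength",
    "clustering",
    "local_efficiency",
    "path_lengths",
    "betweenness",
    "small_world",
    "random_clustering_estimate",
    "random_path_length_estimate",
    "nodal_metrics",
    "network_metrics",
]

EULER_GAMMA = 0.5772156649


def _binary(graph) -> np.ndarray:
    if isinstance(graph, NetworkGraph):
        return graph.binary
    A = np.asarray(graph)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    return (A != 0).astype(int)


def degree_and_density(graph) -> tuple[np.ndarray, float, float]:
    """Nodal degrees, mean degree K, and density 2E / (N(N-1))."""
    A = _binary(graph)
    k = A.sum(axis=1)
    n = A.shape[0]
    n_edges = int(k.sum()) // 2
    density = 2 * n_edges / (n * (n - 1)) if n > 1 else 0.0
    return k, float(k.mean()), density


def density_from_mean_degree(mean_degree: float, n_nodes: int) -> float:
    """Density implied by a mean degree: K / (N - 1)."""
    return mean_degree / (n_nodes - 1)


def strength(graph: NetworkGraph) -> tuple[np.ndarray, float]:
    """Nodal connection strength S_i = sum of valid-edge weights, and mean."""
    s = graph.weights.sum(axis=1)
    return s, float(s.mean())


def clustering(graph) -> tuple[np.ndarray, float]:
    """Nodal clustering C_i = neighbour edges / possible neighbour edges.

    Nodes with fewer than two neighbours get C_i = 0; the network value is
    the plain average over all nodes.
    """
    A = _binary(graph)
    k = A.sum(axis=1)
    triangles = np.diag(A @ A @ A) / 2.0  # neighbour edge count per node
    possible = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(possible > 0, triangles / possible, 0.0)
    return c, float(c.mean())


def _pairwise_hops(A: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf where unreachable)."""
    if A.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(A, method="D", directed=False, unweighted=True)


def local_efficiency(graph) -> tuple[np.ndarray, float]:
    """Nodal local efficiency within the neighbour-induced subgraph.

    Eloc_i = (1 / (K_i (K_i - 1))) * sum over ordered neighbour pairs of
    1 / d_jh computed in the subgraph of i's neighbours with i removed
    (1/inf = 0); zero for degree < 2.
    """
    A = _binary(graph)
    n = A.shape[0]
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(A[i])[0]
        ki = len(nbrs)
        if ki < 2:
            continue
        sub = A[np.ix_(nbrs, nbrs)]
        d = _pairwise_hops(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        eloc[i] = inv.sum() / (ki * (ki - 1))
    return eloc, float(eloc.mean())


def path_lengths(graph) -> tuple[np.ndarray, float, float]:
    """Nodal mean path length, its network mean, and global efficiency.

    L_i averages the finite shortest-path lengths from i to its reachable
    peers; nodes with no reachable peer get NaN and are excluded from the
    network mean.  Global efficiency is the mean of 1/d over all ordered
    pairs with 1/inf = 0, so it remains defined on disconnected graphs.
    """
    A = _binary(graph)
    n = A.shape[0]
    d = _pairwise_hops(A)
    np.fill_diagonal(d, np.inf)
    finite = np.isfinite(d)
    li = np.full(n, np.nan)
    counts = finite.sum(axis=1)
    rows = counts > 0
    li[rows] = np.where(finite, d, 0.0)[rows].sum(axis=1) / counts[rows]
    mean_l = float(np.nanmean(li)) if rows.any() else float("nan")
    if n > 1:
        with np.errstate(divide="ignore"):
            inv = np.where(finite, 1.0 / d, 0.0)
        geff = float(inv.sum() / (n * (n - 1)))
    else:
        geff = float("nan")
    return li, mean_l, geff


def betweenness(graph) -> tuple[np.ndarray, float]:
    """Unnormalised betweenness over unordered pairs (Brandes accumulation).

    b_i sums, over every unordered pair (h, j) with h, j != i, the fraction
    of shortest h-j paths passing through i.
    """
    A = _binary(graph)
    n = A.shape[0]
    adj = [np.nonzero(A[v])[0] for v in range(n)]
    b = np.zeros(n)
    for s in range(n):
        # single-source shortest-path counts (BFS)
        dist = np.full(n, -1)
        sigma = np.zeros(n)
        dist[s] = 0
        sigma[s] = 1.0
        stack: list[int] = []
        preds: list[list[int]] = [[] for _ in range(n)]
        queue = [s]
        while queue:
            v = queue.pop(0)
            stack.append(v)
            for w in adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # dependency accumulation
        delta = np.zeros(n)
        for w in reversed(stack):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                b[w] += delta[w]
    b /= 2.0  # each unordered pair was counted from both endpoints
    return b, float(b.mean())


def random_clustering_estimate(mean_degree: float, n_nodes: int) -> float:
    """Watts-Strogatz random-graph clustering estimate C_rand = k / N."""
    return mean_degree / n_nodes


def random_path_length_estimate(mean_degree: float, n_nodes: int) -> float:
    """Analytic random-graph mean path length ((ln N - gamma)/ln k) + 0.5."""
    if mean_degree <= 1:
        raise ValueError(
            f"random path-length estimate undefined for mean degree "
            f"{mean_degree} <= 1"
        )
    return (np.log(n_nodes) - EULER_GAMMA) / np.log(mean_degree) + 0.5


def small_world(
    mean_clustering: float,
    mean_path_length: float,
    n_nodes: int,
    mean_degree: float,
) -> tuple[float, float]:
    """Normalised clustering and path-length ratios against a random graph.

    Returns ``(C / C_rand, L / L_rand)``; values near (>,~1) and (~1)
    respectively indicate small-world organisation.  Requires mean degree
    > 1 for the path-length estimate.
    """
    c_rand = random_clustering_estimate(mean_degree, n_nodes)
    l_rand = random_path_length_estimate(mean_degree, n_nodes)
    return mean_clustering / c_rand, mean_path_length / l_rand


@dataclass
class NodalMetrics:
    """Per-node metric vectors for one graph."""

    degree: np.ndarray
    strength: np.ndarray
    clustering: np.ndarray
    local_efficiency: np.ndarray
    path_length: np.ndarray
    betweenness: np.ndarray
    node_labels: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        labels = self.node_labels or [
            str(i) for i in range(len(self.degree))
        ]
        return pd.DataFrame(
            {
                "node": labels,
                "degree": self.degree,
                "connection_strength": self.strength,
                "cluster_coefficient": self.clustering,
                "efficiency": self.local_efficiency,
                "path_length": self.path_length,
                "betweenness": self.betweenness,
            }
        )


@dataclass
class NetworkMetrics:
    """Network-level means plus small-world normalisation for one graph."""

    n_nodes: int
    n_edges: int
    degree: float
    density: float
    connection_strength: float
    cluster_coefficient: float
    efficiency: float
    global_efficiency: float
    path_length: float
    betweenness: float
    swn_cluster_coefficient: float
    swn_path_length: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def nodal_metrics(graph: NetworkGraph) -> NodalMetrics:
    """All nodal metrics of one thresholded graph."""
    k, _, _ = degree_and_density(graph)
    s, _ = strength(graph)
    c, _ = clustering(graph)
    e, _ = local_efficiency(graph)
    li, _, _ = path_lengths(graph)
    b, _ = betweenness(graph)
    return NodalMetrics(
        degree=k,
        strength=s,
        clustering=c,
        local_efficiency=e,
        path_length=li,
        betweenness=b,
        node_labels=graph.node_labels,
    )


def network_metrics(graph: NetworkGraph) -> NetworkMetrics:
    """Network means of every metric plus the two small-world ratios.

    The small-world ratios are NaN when the mean degree is <= 1 (random
    estimates undefined) — recorded as missing rather than raised, so a
    sparse subject does not abort a cohort-level sweep.
    """
    k, mean_k, density = degree_and_density(graph)
    _, mean_s = strength(graph)
    _, mean_c = clustering(graph)
    _, mean_e = local_efficiency(graph)
    _, mean_l, geff = path_lengths(graph)
    _, mean_b = betweenness(graph)
    if mean_k > 1 and np.isfinite(mean_l):
        swn_c, swn_l = small_world(mean_c, mean_l, graph.n_nodes, mean_k)
    else:
        swn_c, swn_l = float("nan"), float("nan")
    return NetworkMetrics(
        n_nodes=graph.n_nodes,
        n_edges=graph.n_edges,
        degree=mean_k,
        density=density,
        connection_strength=mean_s,
        cluster_coefficient=mean_c,
        efficiency=mean_e,
        global_efficiency=geff,
        path_length=mean_l,
        betweenness=mean_b,
        swn_cluster_coefficient=swn_c,
        swn_path_length=swn_l,
    )
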