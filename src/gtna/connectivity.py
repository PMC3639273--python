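"""Partial-correlation network estimation and significance thresholding.

The unique (conditional) association between every pair of ROIs is the
partial correlation obtained from the inverse of the sample covariance of
the ROI time series: ``rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)``.
Edges are declared where a two-sided t test of the partial correlation
falls below a significance threshold alpha; the analysis is repeated at
five network densities (alpha = 0.0001, 0.0005, 0.001, 0.005, 0.01) so
results are not tied to a single threshold.  Binary adjacency and a
weighted companion (signed partial correlations on valid edges) are kept
side by side; self-connections are excluded throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .extraction import SubjectConditionSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCorrelationMatrix",
    "NetworkGraph",
    "partial_correlation",
    "edge_significance",
    "threshold",
    "PRESET_ALPHAS",
]

#: the five significance thresholds the multi-density analysis sweeps
PRESET_ALPHAS = (0.0001, 0.0005, 0.001, 0.005, 0.01)


@dataclass
class PartialCorrelationMatrix:
    """Symmetric N x N unique-association matrix with sample-size metadata."""

    values: np.ndarray
    n_samples: int
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("partial-correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("partial-correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("partial correlations must lie in [-1, 1]")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero (no self-connections)")
        if self.n_samples <= v.shape[0]:
            raise ValueError(
                f"n_samples ({self.n_samples}) must exceed the node count "
                f"({v.shape[0]})"
            )

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class NetworkGraph:
    """Thresholded network at one alpha: binary adjacency + signed weights."""

    alpha: float
    binary: np.ndarray
    weights: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.binary = np.asarray(self.binary, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        b, w = self.binary, self.weights
        if b.shape != w.shape or b.ndim != 2 or b.shape[0] != b.shape[1]:
            raise ValueError("binary and weight matrices must be square and match")
        if not np.array_equal(b, b.T) or not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(b) != 0):
            raise ValueError("self-connections are not allowed")
        if np.any((b == 0) & (w != 0)):
            raise ValueError("weights must be zero off the edge set")

    @property
    def n_nodes(self) -> int:
        return self.binary.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.binary.sum()) // 2

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (i, j, weight) with i < j."""
        ii, jj = np.nonzero(np.triu(self.binary, k=1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]


def _as_matrix(series) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(series, SubjectConditionSeries):
        return series.matrix, series.node_labels
    return np.asarray(series, dtype=float), None


def partial_correlation(
    series,
    condition_cap: float = 1e10,
    ridge: float = 0.0,
) -> PartialCorrelationMatrix:
    """Estimate the partial-correlation matrix of an ROI x scan series.

    The sample covariance of the rows is inverted and normalised:
    ``rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)`` with the diagonal
    fixed at zero.  Scans are treated as exchangeable samples.  A ridge
    term (``ridge * mean-variance`` added to the diagonal) is available for
    near-singular covariances but is off by default and always logged.
    """
    X, labels = _as_matrix(series)
    if X.ndim != 2:
        raise ValueError("series must be 2-D (ROI x scan)")
    n_nodes, n_scans = X.shape
    if n_scans <= n_nodes:
        raise ValueError(
            f"need more scans ({n_scans}) than nodes ({n_nodes})"
        )
    cov = np.cov(X)
    if ridge > 0:
        loading = ridge * float(np.mean(np.diag(cov)))
        logger.info("ridge regularisation enabled: adding %.3g to diagonal", loading)
        cov = cov + loading * np.eye(n_nodes)
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > condition_cap:
        raise np.linalg.LinAlgError(
            f"sample covariance is ill-conditioned (cond={cond:.3g} > "
            f"{condition_cap:.3g}); consider the ridge option"
        )
    omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    np.clip(rho, -1.0, 1.0, out=rho)
    np.fill_diagonal(rho, 0.0)
    return PartialCorrelationMatrix(
        values=rho, n_samples=n_scans, node_labels=labels
    )


def edge_significance(pcm: PartialCorrelationMatrix) -> np.ndarray:
    """Two-sided p-values for every partial correlation.

    Uses ``t = rho * sqrt(df / (1 - rho^2))`` with ``df = n_samples - N``,
    the degrees of freedom of a correlation controlling the other N - 2
    variables.  The diagonal (and any rho = 0) gets p = 1.
    """
    df = pcm.n_samples - pcm.n_nodes
    if df <= 0:
        raise ValueError(
            f"non-positive degrees of freedom ({df}); need n_samples > N"
        )
    rho = pcm.values
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt(df / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 1.0)
    return np.minimum(p, 1.0)


def threshold(
    pcm: PartialCorrelationMatrix,
    alpha: float,
    signed_weights: bool = True,
) -> NetworkGraph:
    """Binary + weighted network at significance level ``alpha``.

    An edge exists wherever the two-sided edge p-value is below alpha; on
    valid edges the weight is the (by default signed) partial correlation,
    elsewhere zero.  Edge sets are nested across alphas: every edge valid
    at a stricter alpha survives any looser one.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if alpha not in PRESET_ALPHAS:
        logger.info("non-preset threshold alpha=%g in use", alpha)
    p = edge_significance(pcm)
    binary = (p < alpha).astype(int)
    np.fill_diagonal(binary, 0)
    weights = pcm.values * binary
    if not signed_weights:
        weights = np.abs(weights)
    return NetworkGraph(
        alpha=alpha, binary=binary, weights=weights, node_labels=pcm.node_labels
    )


def graph_to_edge_table(graph: NetworkGraph, pcm: PartialCorrelationMatrix):
    """Edge-list rows (node_i, node_j, partial_r, p, alpha) for export."""
    import pandas as pd

    p = edge_significance(pcm)
    labels = graph.node_labels or [str(i) for i in range(graph.n_nodes)]
    rows = [
        {
            "node_i": labels[i],
            "node_j": labels[j],
            "partial_r": w,
            "p": float(p[i, j]),
            "alpha": graph.alpha,
        }
        for i, j, w in graph.edge_list()
    ]
    return pd.DataFrame(rows, columns=["node_i", "node_j", "partial_r", "p", "alpha"])


def graph_to_graphml(graph: NetworkGraph, path) -> None:
    """Write the weighted graph as minimal GraphML for visualisation tools."""
    labels = graph.node_labels or [str(i) for i in range(graph.n_nodes)]
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<graphml xmlns="http://graphml.graphdrawing.org/xmlns">',
        '  <key id="w" for="edge" attr.name="weight" attr.type="double"/>',
        '  <key id="label" for="node" attr.name="label" attr.type="string"/>',
        '  <graph edgedefault="undirected">',
    ]
    for i, label in enumerate(labels):
        safe = (
            label.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        )
        lines.append(f'    <node id="n{i}"><data key="label">{safe}</data></node>')
    for i, j, w in graph.edge_list():
        lines.append(
            f'    <edge source="n{i}" target="n{j}">'
            f'<data key="w">{w:.6f}</data></edge>'
        )
    lines += ["  </graph>", "</graphml>", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
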