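"""Weighted undirected network metrics for coherence graphs.

Two global metrics, following the Brain Connectivity Toolbox conventions
for weighted undirected graphs:

* Characteristic path length
      L^w = (1/n) * sum_i [ sum_{j != i} d_ij^w / (n - 1) ]
  the mean over ordered node pairs of the shortest-path distance on edge
  lengths d = 1/w (stronger coherence = shorter connection).

* Clustering coefficient
      C^w = (1/n) * sum_i 2 t_i^w / (k_i (k_i - 1))
  with the geometric-mean triangle intensity
      t_i^w = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^(1/3);
  nodes of degree < 2 contribute 0.

Coherence graphs are complete, so L^w is always finite; a disconnected
graph (possible after optional proportional thresholding) raises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .connectivity import CoherenceMatrixSet

__all__ = [
    "WeightedGraph",
    "GraphMetrics",
    "weights_to_lengths",
    "characteristic_path_length",
    "clustering_coefficient",
    "metrics_for_bands",
    "threshold_proportional",
]


@dataclass
class WeightedGraph:
    """Symmetric weighted graph without self-loops; weights in (0, 1]."""

    weights: np.ndarray
    nodes: tuple = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            w = w.copy()
            np.fill_diagonal(w, 0.0)  # self-coherence must not create loops
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w
        if not self.nodes:
            self.nodes = tuple(range(w.shape[0]))

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class GraphMetrics:
    cpl: float
    avg_cc: float
    node_cc: np.ndarray
    node_triangles: np.ndarray
    degrees: np.ndarray


def weights_to_lengths(g: WeightedGraph | np.ndarray, transform: str = "inverse") -> np.ndarray:
    """Edge-length matrix from connection weights.

    ``inverse`` gives d = 1/w (BCT default); ``log`` gives d = -log(w).
    Absent edges (w = 0) map to infinity; both transforms are monotone
    decreasing in w.
    """
    w = g.weights if isinstance(g, WeightedGraph) else np.asarray(g, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    with np.errstate(divide="ignore"):
        if transform == "inverse":
            d = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        elif transform == "log":
            if np.any(w > 1):
                raise ValueError("log transform requires weights <= 1")
            d = np.where(w > 0, -np.log(np.where(w > 0, w, 1.0)), np.inf)
        else:
            raise ValueError(f"unknown length transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    return d


def characteristic_path_length(
    g: WeightedGraph | np.ndarray, transform: str = "inverse"
) -> float:
    """Weighted characteristic path length L^w (mean over ordered pairs).

    Shortest-path distances are computed per source node on the 1/w length
    matrix.  Raises on disconnected graphs (infinite path length).
    """
    w = g.weights if isinstance(g, WeightedGraph) else WeightedGraph(np.asarray(g)).weights
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    lengths = weights_to_lengths(w, transform=transform)
    finite = np.where(np.isfinite(lengths), lengths, 0.0)
    mask = np.isfinite(lengths) & (lengths > 0)
    dist = dijkstra(np.where(mask, finite, 0.0), directed=False)
    off = ~np.eye(n, dtype=bool)
    if np.any(np.isinf(dist[off])):
        raise ValueError("infinite path length: graph is disconnected")
    return float(dist[off].mean())


def clustering_coefficient(g: WeightedGraph | np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted clustering coefficient: network average and per-node values.

    Uses the cube-root geometric-mean triangle intensity; nodes with fewer
    than 2 neighbours contribute 0.
    """
    w = g.weights if isinstance(g, WeightedGraph) else WeightedGraph(np.asarray(g)).weights
    n = w.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    cw = np.cbrt(w)
    t = np.diag(cw @ cw @ cw) / 2.0  # t_i = 1/2 sum_{j,h} (w_ij w_ih w_jh)^(1/3)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    node_cc = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1), 0.0)
    return float(node_cc.mean()), node_cc


def threshold_proportional(w: np.ndarray, density: float) -> np.ndarray:
    """Keep the strongest fraction ``density`` of off-diagonal edges."""
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    iu = np.triu_indices_from(w, k=1)
    vals = w[iu]
    n_keep = int(round(density * vals.size))
    if n_keep < vals.size:
        cut = np.sort(vals)[::-1][max(n_keep - 1, 0)]
        w[w < cut] = 0.0
    return w


def metrics_for_bands(
    cms: CoherenceMatrixSet,
    threshold: float | None = None,
    transform: str = "inverse",
) -> dict:
    """Per-band graph metrics from a coherence matrix set.

    ``threshold`` optionally prunes each band's graph to the stated
    proportional density before computing metrics (off by default: the
    analysis uses fully weighted complete graphs).  Raises if pruning
    disconnects a graph.
    """
    out = {}
    for band, _, _ in cms.bands:
        w = cms.graph_matrix(band)
        if threshold is not None:
            w = threshold_proportional(w, threshold)
        g = WeightedGraph(w, nodes=cms.channels)
        cpl = characteristic_path_length(g, transform=transform)
        avg_cc, node_cc = clustering_coefficient(g)
        cw = np.cbrt(g.weights)
        out[band] = GraphMetrics(
            cpl=cpl,
            avg_cc=avg_cc,
            node_cc=node_cc,
            node_triangles=np.diag(cw @ cw @ cw) / 2.0,
            degrees=(g.weights > 0).sum(axis=1),
        )
    return out
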