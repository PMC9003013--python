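"""Group-averaged networks and connectivity-preserving proportional thresholding.

The threshold is chosen on the *group-averaged* weighted networks: edges are
sorted ascending by weight and removed in steps of a fixed grid (1% by
default) until the averaged graph first disconnects; the common proportion
applied to every individual network is one grid step below the smallest
disconnection point over the groups.  Individual thresholded graphs may still
be disconnected — only the group averages are guaranteed connected by the
rule — and the metric layer handles that.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .connectivity import ConnectivityMatrix

__all__ = [
    "BrainGraph",
    "ThresholdResult",
    "average_network",
    "disconnect_point",
    "select_threshold",
    "apply_threshold",
]


@dataclass
class BrainGraph:
    """Weighted undirected graph over channels, stored as a symmetric matrix.

    A zero entry means "no edge"; all stored edge weights are positive.
    """

    weights: np.ndarray
    channel_labels: list

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("graph must be undirected (symmetric weights)")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed")
        if w.min() < 0:
            raise ValueError("edge weights must be positive")
        self.weights = 0.5 * (w + w.T)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edges(self):
        """Iterate over (i, j, weight) with i < j."""
        n = self.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                if self.weights[i, j] > 0:
                    yield i, j, self.weights[i, j]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.channel_labels)
        for i, j, w in self.edges():
            g.add_edge(self.channel_labels[i], self.channel_labels[j], weight=w)
        return g


@dataclass
class ThresholdResult:
    """Outcome of the connectivity-preserving threshold search."""

    proportion: float
    disconnect_point_per_group: dict
    step: float

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"group": g, "disconnect_point": p,
                 "selected_proportion": self.proportion}
                for g, p in sorted(self.disconnect_point_per_group.items())]
        return pd.DataFrame(rows)


def average_network(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of connectivity matrices sharing labels, method, band."""
    if not mats:
        raise ValueError("no matrices to average")
    first = mats[0]
    for m in mats[1:]:
        if list(m.channel_labels) != list(first.channel_labels):
            raise ValueError("matrices have mismatched channel labels")
        if m.method != first.method or m.band != first.band:
            raise ValueError("matrices mix methods or bands")
    mean = np.mean([m.weights for m in mats], axis=0)
    return ConnectivityMatrix(weights=mean, method=first.method,
                              band=first.band, channel_labels=first.channel_labels)


def _sorted_edges(weights: np.ndarray):
    """Edges with positive weight, ascending by (weight, i, j) — deterministic
    tie-break at equal weights."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    return iu[order], ju[order], w[order]


def _is_connected(adj: np.ndarray) -> bool:
    ncomp, _ = connected_components(csr_matrix(adj), directed=False)
    return ncomp == 1


def _grid_divisions(step: float) -> int:
    k = int(round(1.0 / step))
    if abs(k * step - 1.0) > 1e-9 or k < 1:
        raise ValueError(f"step {step} must evenly divide the unit interval")
    return k


def disconnect_point(avg: ConnectivityMatrix | BrainGraph, step: float = 0.01) -> float:
    """Smallest removal proportion on the grid at which the graph disconnects.

    For p = 0, step, 2*step, ... the ``floor(p * E)`` lowest-weight edges are
    removed and connectivity tested.  Returns 1.0 if the graph never
    disconnects (trivial graphs); raises if it is disconnected already at 0.
    """
    weights = avg.weights
    n = weights.shape[0]
    iu, ju, _ = _sorted_edges(weights)
    n_edges = len(iu)
    grid = _grid_divisions(step)

    adj = (weights > 0).astype(np.int8)
    if not _is_connected(adj):
        raise ValueError("graph is disconnected before any edge removal; "
                         "no valid threshold exists")
    removed = 0
    for k in range(1, grid + 1):
        n_remove = (k * n_edges) // grid  # floor(p * E) exactly, p = k/grid
        while removed < n_remove:
            adj[iu[removed], ju[removed]] = 0
            adj[ju[removed], iu[removed]] = 0
            removed += 1
        if not _is_connected(adj):
            return k / grid
    return 1.0


def select_threshold(avg_by_group: dict, step: float = 0.01) -> ThresholdResult:
    """Common removal proportion: one grid step below the earliest group
    disconnection point."""
    if not avg_by_group:
        raise ValueError("no group averages supplied")
    grid = _grid_divisions(step)
    points = {g: disconnect_point(m, step) for g, m in avg_by_group.items()}
    k_min = min(int(round(p * grid)) for p in points.values())
    proportion = max(k_min - 1, 0) / grid
    return ThresholdResult(proportion=proportion,
                           disconnect_point_per_group=points, step=step)


def apply_threshold(mat: ConnectivityMatrix, proportion: float) -> BrainGraph:
    """Remove the ``floor(proportion * E)`` lowest-weight edges of this matrix.

    Proportional (per-network) thresholding: E is the edge count of *this*
    matrix, surviving edges keep their weights, and the result may be
    disconnected.
    """
    if not 0 <= proportion < 1:
        raise ValueError("proportion must lie in [0, 1)")
    weights = mat.weights.copy()
    iu, ju, _ = _sorted_edges(weights)
    n_remove = int(np.floor(np.round(proportion * len(iu), 9)))
    for k in range(n_remove):
        weights[iu[k], ju[k]] = 0.0
        weights[ju[k], iu[k]] = 0.0
    return BrainGraph(weights=weights, channel_labels=list(mat.channel_labels))
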