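"""Sparsity thresholding of weighted connectivity into binary graphs.

A sparsity threshold s keeps the top s * N(N-1)/2 strongest connections
as unweighted edges. Because edges are selected by rank, the graphs of a
sweep are nested (every edge present at a lower sparsity survives at any
higher one) and the binarization is invariant under any strictly
increasing transform of the weights.

Conventions (the weighted-to-binary step is underdetermined in the
literature, so they are fixed here for bit-reproducibility):

* edges are ranked by *signed* weight descending, so strongly negative
  correlations enter last; pass ``absolute=True`` to rank by magnitude;
* the edge count is round-half-up of s * N(N-1)/2;
* ties at the cut are broken by ascending (i, j) lexicographic order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from netsweep.connectivity import ConnectivityMatrix

__all__ = [
    "SparsityGrid",
    "BinaryGraph",
    "binarize_at_sparsity",
    "sweep_graphs",
    "degree_distribution",
]

DEFAULT_SPARSITY_MIN = 0.10
DEFAULT_SPARSITY_MAX = 0.34
DEFAULT_SPARSITY_STEP = 0.01


def _default_thresholds() -> np.ndarray:
    n = int(round((DEFAULT_SPARSITY_MAX - DEFAULT_SPARSITY_MIN)
                  / DEFAULT_SPARSITY_STEP)) + 1
    return np.round(DEFAULT_SPARSITY_MIN
                    + DEFAULT_SPARSITY_STEP * np.arange(n), 10)


@dataclass
class SparsityGrid:
    """Ordered sparsity thresholds; default 0.10, 0.11, ..., 0.34."""

    thresholds: np.ndarray = field(default_factory=_default_thresholds)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size == 0:
            raise ValueError("thresholds must be a nonempty 1-D vector")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.thresholds[0] <= 0 or self.thresholds[-1] >= 1:
            raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "SparsityGrid":
        n = int(round((hi - lo) / step)) + 1
        return cls(np.round(lo + step * np.arange(n), 10))

    def __len__(self) -> int:
        return self.thresholds.size

    def __iter__(self):
        return iter(self.thresholds)


@dataclass
class BinaryGraph:
    """Undirected binary adjacency at one sparsity threshold."""

    adjacency: np.ndarray
    sparsity: float
    n_edges: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape[0] != a.shape[1] or a.ndim != 2:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.int8)
        self.n_edges = int(a.sum()) // 2

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_list(self) -> np.ndarray:
        """Edges as an (m, 2) array of node index pairs with i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu, ju] == 1
        return np.column_stack([iu[keep], ju[keep]])


def _ranked_pairs(fc: ConnectivityMatrix, absolute: bool) -> tuple:
    n = fc.n_rois
    iu, ju = np.triu_indices(n, k=1)
    w = fc.r[iu, ju]
    key = np.abs(w) if absolute else w
    # lexsort: last key is primary -> weight descending, then (i, j) ascending
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order], w.size


def _edge_count(s: float, n_pairs: int) -> int:
    return int(np.floor(s * n_pairs + 0.5))  # round half up


def binarize_at_sparsity(
    fc: ConnectivityMatrix, s: float, absolute: bool = False
) -> BinaryGraph:
    """Keep the top round(s * N(N-1)/2) connections as binary edges."""
    if not 0 < s < 1:
        raise ValueError(f"sparsity must lie in (0, 1), got {s}")
    iu, ju, n_pairs = _ranked_pairs(fc, absolute)
    k = _edge_count(s, n_pairs)
    if k == 0:
        raise ValueError(f"sparsity {s} keeps zero edges on {fc.n_rois} nodes")
    if k >= n_pairs:
        warnings.warn(f"sparsity {s} keeps every pair: complete graph")
        k = n_pairs
    adj = np.zeros((fc.n_rois, fc.n_rois), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adj, float(s))


def sweep_graphs(
    fc: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    absolute: bool = False,
) -> list[BinaryGraph]:
    """One binary graph per grid threshold; edge sets nested by rank."""
    grid = grid if grid is not None else SparsityGrid()
    iu, ju, n_pairs = _ranked_pairs(fc, absolute)
    out = []
    adj = np.zeros((fc.n_rois, fc.n_rois), dtype=np.int8)
    k_prev = 0
    for s in grid:
        k = _edge_count(float(s), n_pairs)
        if k == 0:
            raise ValueError(f"sparsity {s} keeps zero edges")
        if k >= n_pairs:
            warnings.warn(f"sparsity {s} keeps every pair: complete graph")
            k = n_pairs
        adj[iu[k_prev:k], ju[k_prev:k]] = 1
        adj[ju[k_prev:k], iu[k_prev:k]] = 1
        k_prev = max(k, k_prev)
        out.append(BinaryGraph(adj.copy(), float(s)))
    return out


def degree_distribution(g: BinaryGraph) -> np.ndarray:
    """Per-node degree: the number of connections in the binary network."""
    return g.adjacency.sum(axis=1).astype(np.int64)
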