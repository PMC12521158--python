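"""Global and nodal topological metrics on binary brain graphs.

Global metrics: clustering coefficient (Cp), characteristic path length
(Lp), global and local efficiency (Eglob, Eloc), assortativity,
modularity of the best partition found by seeded Louvain runs, and the
small-world triple gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>,
sigma = gamma / lambda, where the null ensemble consists of
degree-preserving rewired surrogates (Maslov–Sneppen double-edge swaps).

Nodal metrics: degree centrality, nodal efficiency, betweenness
(unnormalized unordered-pair counts) and clustering coefficient.

Every metric is evaluated at each threshold of a sparsity sweep and
integrated into a threshold-insensitive scalar via the trapezoidal area
under the curve (AUC) over the sweep.

Conventions for fragmented graphs: path length averages over connected
ordered pairs only; efficiency-type metrics count unreachable pairs as
zero (1/inf); nodes of degree < 2 have clustering 0 and contribute 0 to
local efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from netsweep._kernels import (
    bfs_distances,
    brandes_betweenness,
    double_edge_swap,
    local_efficiency_nodes,
    louvain_pass,
    null_ensemble_cp_lp,
)
from netsweep.connectivity import ConnectivityMatrix
from netsweep.graphs import BinaryGraph, SparsityGrid, sweep_graphs

__all__ = [
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
    "GlobalMetrics",
    "NodalMetrics",
    "MetricCurveSet",
    "auc_over_sweep",
    "clustering_vector",
    "generate_null_networks",
    "global_metrics",
    "metrics_for_subject",
    "modularity_q",
    "nodal_metrics",
]

GLOBAL_METRIC_NAMES = (
    "Cp", "Lp", "Eglob", "Eloc", "gamma", "lambda", "sigma",
    "assortativity", "modularity",
)
NODAL_METRIC_NAMES = (
    "degree_centrality", "nodal_efficiency", "betweenness", "clustering",
)


# ---------------------------------------------------------------------------
# elementary metric computations

def clustering_vector(adj: np.ndarray) -> np.ndarray:
    """Per-node clustering: fraction of neighbor pairs that are connected."""
    a = adj.astype(np.float64)
    k = a.sum(axis=1)
    tri2 = ((a @ a) * a).sum(axis=1)  # (A^3)_ii = 2 * triangles through i
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri2 / denom, 0.0)
    return c


def _distance_stats(adj: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(Lp over connected pairs, Eglob over all pairs, nodal efficiency)."""
    n = adj.shape[0]
    dist = bfs_distances(np.ascontiguousarray(adj, dtype=np.int8))
    off = ~np.eye(n, dtype=bool)
    d = dist[off].astype(np.float64)
    connected = d > 0
    lp = float(d[connected].mean()) if connected.any() else np.inf
    inv = np.where(dist > 0, 1.0 / np.maximum(dist, 1), 0.0)
    np.fill_diagonal(inv, 0.0)
    eglob = float(inv.sum() / (n * (n - 1)))
    nodal_eff = inv.sum(axis=1) / (n - 1)
    return lp, eglob, nodal_eff


def assortativity_coefficient(adj: np.ndarray) -> float:
    """Degree-degree Pearson correlation across edge endpoints.

    NaN when all degrees are equal (zero variance, e.g. complete graphs
    or rings), matching the usual convention.
    """
    deg = adj.sum(axis=1).astype(np.float64)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if iu.size == 0:
        raise ValueError("assortativity undefined on an empty graph")
    x = np.concatenate([deg[iu], deg[ju]])  # both orientations of each edge
    y = np.concatenate([deg[ju], deg[iu]])
    vx = x.std()
    if vx == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def modularity_q(adj: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2] of a partition."""
    a = np.asarray(adj)
    labels = np.asarray(labels)
    m = a.sum() / 2.0
    if m == 0:
        raise ValueError("modularity undefined on an empty graph")
    q = 0.0
    deg = a.sum(axis=1).astype(np.float64)
    for c in np.unique(labels):
        mask = labels == c
        e_c = a[np.ix_(mask, mask)].sum() / 2.0
        d_c = deg[mask].sum()
        q += e_c / m - (d_c / (2.0 * m)) ** 2
    return float(q)


# ---------------------------------------------------------------------------
# community detection (seeded Louvain, best of n_runs)

def _louvain_once(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n0 = w.shape[0]
    node_map = np.arange(n0, dtype=np.int32)
    wc = np.ascontiguousarray(w, dtype=np.float64)
    while True:
        n = wc.shape[0]
        comm = np.arange(n, dtype=np.int32)
        strength = wc.sum(axis=1)
        sigma_tot = strength.copy()
        m2 = wc.sum()
        if m2 == 0:
            break
        while True:
            order = rng.permutation(n).astype(np.int32)
            if louvain_pass(wc, comm, sigma_tot, strength, order, m2) == 0:
                break
        uniq, newcomm = np.unique(comm, return_inverse=True)
        if uniq.size == n:
            break
        node_map = newcomm.astype(np.int32)[node_map]
        z = np.zeros((n, uniq.size))
        z[np.arange(n), newcomm] = 1.0
        wc = np.ascontiguousarray(z.T @ wc @ z)
        if uniq.size == 1:
            break
    return node_map


def best_partition(
    adj: np.ndarray, n_runs: int = 10, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Best-of-``n_runs`` Louvain partition and its modularity Q."""
    rng_streams = np.random.SeedSequence(seed).spawn(n_runs)
    best_q, best_labels = -np.inf, None
    a = adj.astype(np.float64)
    for child in rng_streams:
        labels = _louvain_once(a, np.random.default_rng(child))
        q = modularity_q(adj, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_labels, best_q


# ---------------------------------------------------------------------------
# null networks

def generate_null_networks(
    g: BinaryGraph, n_nulls: int, seed: int
) -> list[BinaryGraph]:
    """Degree-preserving random surrogates of ``g`` by double-edge swaps.

    Each surrogate attempts 10 * n_edges swaps; proposals creating
    self-loops or duplicate edges are rejected, so every null keeps
    exactly the degree sequence of ``g``. Deterministic given ``seed``.
    Graphs admitting no valid swap (e.g. stars) come back as copies with
    a warning.
    """
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    children = np.random.SeedSequence(seed).spawn(n_nulls)
    nulls: list[BinaryGraph] = []
    stuck = 0
    for child in children:
        kernel_seed = int(child.generate_state(1)[0] % (2**31))
        edges = np.ascontiguousarray(g.edge_list(), dtype=np.int64)
        adj = np.ascontiguousarray(g.adjacency.copy(), dtype=np.int8)
        accepted = double_edge_swap(edges, adj, 10 * g.n_edges, kernel_seed)
        if accepted == 0:
            stuck += 1
        nulls.append(BinaryGraph(adj, g.sparsity))
    if stuck == n_nulls:
        warnings.warn(
            "no valid degree-preserving swap exists; nulls are copies"
        )
    return nulls


# ---------------------------------------------------------------------------
# metric containers

@dataclass
class NodalMetrics:
    """Per-node topological metrics of one binary graph."""

    degree_centrality: np.ndarray
    nodal_efficiency: np.ndarray
    betweenness: np.ndarray
    clustering: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in NODAL_METRIC_NAMES}


@dataclass
class GlobalMetrics:
    """Global topological metrics of one binary graph."""

    Cp: float
    Lp: float
    Eglob: float
    Eloc: float
    gamma: float
    lambda_: float
    sigma: float
    assortativity: float
    modularity: float

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in GLOBAL_METRIC_NAMES
             if name != "lambda"}
        d["lambda"] = self.lambda_
        return d


def nodal_metrics(g: BinaryGraph) -> NodalMetrics:
    """Degree, nodal efficiency, betweenness and clustering per node."""
    adj = np.ascontiguousarray(g.adjacency, dtype=np.int8)
    degree = adj.sum(axis=1).astype(np.int64)
    _, _, nodal_eff = _distance_stats(adj)
    bc = brandes_betweenness(adj) / 2.0  # unordered-pair convention
    return NodalMetrics(degree, nodal_eff, bc, clustering_vector(adj))


def global_metrics(
    g: BinaryGraph,
    nulls: list[BinaryGraph] | None = None,
    n_runs: int = 10,
    seed: int = 0,
) -> GlobalMetrics:
    """All global metrics of ``g``, normalized against ``nulls``.

    ``nulls`` must share the degree sequence of ``g``; with an empty or
    missing ensemble gamma, lambda and sigma are reported as NaN.
    """
    if g.n_edges == 0:
        raise ValueError("global metrics undefined on an empty graph")
    adj = np.ascontiguousarray(g.adjacency, dtype=np.int8)
    cp = float(clustering_vector(adj).mean())
    lp, eglob, _ = _distance_stats(adj)
    eloc = float(local_efficiency_nodes(adj).mean())
    assort = assortativity_coefficient(adj)
    _, q = best_partition(adj, n_runs=n_runs, seed=seed)
    if nulls:
        null_cp = np.mean([clustering_vector(nl.adjacency).mean()
                           for nl in nulls])
        null_lp = np.mean([_distance_stats(
            np.ascontiguousarray(nl.adjacency, dtype=np.int8))[0]
            for nl in nulls])
        gamma = cp / null_cp if null_cp > 0 else np.nan
        lambda_ = lp / null_lp if null_lp > 0 else np.nan
    else:
        gamma = lambda_ = np.nan
    sigma = gamma / lambda_
    return GlobalMetrics(cp, lp, eglob, eloc, float(gamma), float(lambda_),
                         float(sigma), assort, q)


# ---------------------------------------------------------------------------
# sweep integration

def auc_over_sweep(values: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal integral of a metric curve over the sparsity grid."""
    values = np.asarray(values, dtype=float)
    thresholds = grid.thresholds if isinstance(grid, SparsityGrid) \
        else np.asarray(grid, dtype=float)
    if values.shape != thresholds.shape:
        raise ValueError(
            f"curve length {values.size} != grid length {thresholds.size}"
        )
    return float(np.trapezoid(values, thresholds))


@dataclass
class MetricCurveSet:
    """One subject's metric curves over the sparsity sweep plus AUCs."""

    subject_id: str
    grid: SparsityGrid
    global_curves: dict[str, np.ndarray]
    nodal_curves: dict[str, np.ndarray]  # (n_nodes, n_thresholds) each
    node_labels: list[str]
    global_auc: dict[str, float] = field(default_factory=dict)
    nodal_auc: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.global_auc:
            self.global_auc = {
                name: auc_over_sweep(curve, self.grid)
                for name, curve in self.global_curves.items()
            }
        if not self.nodal_auc:
            self.nodal_auc = {
                name: np.array([auc_over_sweep(row, self.grid)
                                for row in mat])
                for name, mat in self.nodal_curves.items()
            }

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: subject, metric, scope, node, threshold, value."""
        rows = []
        for name, curve in self.global_curves.items():
            for s, v in zip(self.grid.thresholds, curve):
                rows.append((self.subject_id, name, "global", "", s, v))
        for name, mat in self.nodal_curves.items():
            for node, row in zip(self.node_labels, mat):
                for s, v in zip(self.grid.thresholds, row):
                    rows.append((self.subject_id, name, "node", node, s, v))
        return pd.DataFrame(
            rows, columns=["subject_id", "metric", "scope", "node_label",
                           "threshold", "value"])

    def auc_rows(self) -> pd.DataFrame:
        """AUC summary table: subject, metric, scope, node, auc."""
        rows = [(self.subject_id, name, "global", "", v)
                for name, v in self.global_auc.items()]
        for name, aucs in self.nodal_auc.items():
            rows.extend(
                (self.subject_id, name, "node", node, v)
                for node, v in zip(self.node_labels, aucs))
        return pd.DataFrame(
            rows, columns=["subject_id", "metric", "scope", "node_label",
                           "auc"])


def metrics_for_subject(
    fc: ConnectivityMatrix,
    grid: SparsityGrid | None = None,
    n_nulls: int = 100,
    seed: int = 0,
    include_nodal: bool = True,
    global_names: tuple[str, ...] = GLOBAL_METRIC_NAMES,
    n_runs: int = 10,
) -> MetricCurveSet:
    """Full sparsity-sweep metric profile of one subject.

    Thresholds the weighted matrix over ``grid``, computes the requested
    global metrics (with null normalization when gamma/lambda/sigma are
    requested) and, optionally, all nodal metrics, then AUC-integrates
    every curve. Deterministic given ``seed``.
    """
    grid = grid if grid is not None else SparsityGrid()
    graphs = sweep_graphs(fc, grid)
    need_nulls = bool({"gamma", "lambda", "sigma"} & set(global_names))
    need_dist = bool({"Lp", "Eglob"} & set(global_names)) or include_nodal
    n = fc.n_rois
    n_thr = len(grid)
    gcurves = {name: np.empty(n_thr) for name in global_names}
    ncurves = ({name: np.empty((n, n_thr)) for name in NODAL_METRIC_NAMES}
               if include_nodal else {})
    ss = np.random.SeedSequence(seed)
    thr_seeds = ss.spawn(n_thr)
    for t, g in enumerate(graphs):
        adj = np.ascontiguousarray(g.adjacency, dtype=np.int8)
        null_seed, louvain_seed = (
            int(s.generate_state(1)[0] % (2**31)) for s in
            thr_seeds[t].spawn(2))
        cvec = clustering_vector(adj)
        if need_dist:
            lp, eglob, nodal_eff = _distance_stats(adj)
        if "Cp" in gcurves:
            gcurves["Cp"][t] = cvec.mean()
        if "Lp" in gcurves:
            gcurves["Lp"][t] = lp
        if "Eglob" in gcurves:
            gcurves["Eglob"][t] = eglob
        if "Eloc" in gcurves:
            gcurves["Eloc"][t] = local_efficiency_nodes(adj).mean()
        if "assortativity" in gcurves:
            gcurves["assortativity"][t] = assortativity_coefficient(adj)
        if "modularity" in gcurves:
            _, q = best_partition(adj, n_runs=n_runs, seed=louvain_seed)
            gcurves["modularity"][t] = q
        if need_nulls:
            null_cp, null_lp = null_ensemble_cp_lp(adj, n_nulls, 10,
                                                   null_seed)
            gamma = cvec.mean() / null_cp if null_cp > 0 else np.nan
            if "Lp" not in gcurves and not need_dist:
                lp = _distance_stats(adj)[0]
            lambda_ = lp / null_lp if null_lp > 0 else np.nan
            if "gamma" in gcurves:
                gcurves["gamma"][t] = gamma
            if "lambda" in gcurves:
                gcurves["lambda"][t] = lambda_
            if "sigma" in gcurves:
                gcurves["sigma"][t] = gamma / lambda_
        if include_nodal:
            ncurves["degree_centrality"][:, t] = adj.sum(axis=1)
            ncurves["nodal_efficiency"][:, t] = nodal_eff
            ncurves["betweenness"][:, t] = brandes_betweenness(adj) / 2.0
            ncurves["clustering"][:, t] = cvec
    return MetricCurveSet(
        fc.subject_id, grid, gcurves, ncurves, list(fc.roi_labels))
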