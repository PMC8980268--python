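"""Weighted undirected graph-topology metrics.

All metrics are implemented here directly (no graph library), with the
conventions used throughout weighted brain-network analysis:

- Shortest paths use the edge length l_ij = 1/w_ij, so stronger
  connections are shorter; disconnected pairs have infinite distance.
- Degree (strength) is the sum of a node's incident edge weights.
- Nodal efficiency E_nodal(i) is the mean of 1/d_ij over all j != i
  (the reciprocal of the harmonic mean of shortest path lengths), and
  global efficiency E_global is the mean of E_nodal over nodes.
- Local efficiency E_local(i) is the global efficiency of the subgraph
  induced by i's neighbors (original weights retained).
- Betweenness centrality counts the fraction of shortest paths through a
  node, with multiplicities of equal-length paths, normalized by
  (n-1)(n-2)/2.
- Modularity Q = (1/2m) sum_ij [w_ij - k_i k_j / 2m] delta(c_i, c_j) is
  optimized by a greedy multilevel heuristic with randomized node
  visitation order; because the found optimum varies from run to run, the
  analysis is repeated (500 times by default) and the mean Q reported.
- Assortativity is the Pearson correlation, over the edge list with each
  undirected edge contributing both orientations, of endpoint strengths;
  it is undefined (NaN) when endpoint strengths have zero variance.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import HemisphericNetwork

__all__ = [
    "PathLengths",
    "MetricSet",
    "shortest_paths",
    "node_degree",
    "nodal_and_global_efficiency",
    "local_efficiency",
    "betweenness_centrality",
    "modularity_q",
    "modularity_repeated",
    "assortativity_coefficient",
    "compute_metric_set",
    "GLOBAL_METRICS",
    "NODE_METRICS",
]

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ["degree", "e_local", "e_global", "betweenness", "modularity", "assortativity"]
NODE_METRICS = ["degree", "e_nodal", "e_local", "betweenness"]

_TOL = 1e-12


@dataclass
class PathLengths:
    """All-pairs shortest path lengths under edge length 1/weight."""

    d: np.ndarray  # n x n, np.inf for unreachable pairs

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("path-length diagonal must be zero")


def _dijkstra_dense(lengths: np.ndarray, source: int) -> np.ndarray:
    """Single-source shortest paths on a dense length matrix (inf = no edge)."""
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    visited = np.zeros(n, dtype=bool)
    for _ in range(n):
        masked = np.where(visited, np.inf, dist)
        u = int(np.argmin(masked))
        if not np.isfinite(masked[u]):
            break
        visited[u] = True
        cand = dist[u] + lengths[u]
        better = cand < dist
        dist[better] = cand[better]
    return dist


def _length_matrix(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(lengths, np.inf)
    return lengths


def shortest_paths(net: HemisphericNetwork | np.ndarray) -> PathLengths:
    """All-pairs shortest paths from repeated single-source searches."""
    weights = net.weights if isinstance(net, HemisphericNetwork) else np.asarray(net, float)
    if np.any(weights < 0):
        raise ValueError("edge weights must be nonnegative")
    lengths = _length_matrix(weights)
    n = weights.shape[0]
    d = np.empty((n, n))
    for s in range(n):
        d[s] = _dijkstra_dense(lengths, s)
    return PathLengths(d=d)


def node_degree(net: HemisphericNetwork | np.ndarray) -> np.ndarray:
    """Weighted degree (strength): sum of incident edge weights."""
    weights = net.weights if isinstance(net, HemisphericNetwork) else np.asarray(net, float)
    return weights.sum(axis=1)


def nodal_and_global_efficiency(paths: PathLengths) -> tuple[np.ndarray, float]:
    """E_nodal(i) = mean over j != i of 1/d_ij (1/inf = 0); E_global = mean."""
    n = paths.d.shape[0]
    if n < 2:
        raise ValueError("efficiency requires at least 2 nodes")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(paths.d) & (paths.d > 0), 1.0 / paths.d, 0.0)
    e_nodal = inv.sum(axis=1) / (n - 1)
    return e_nodal, float(e_nodal.mean())


def _apsp_floyd(lengths: np.ndarray) -> np.ndarray:
    """Vectorized all-pairs relaxation (small dense subgraphs)."""
    d = lengths.copy()
    np.fill_diagonal(d, 0.0)
    for k in range(d.shape[0]):
        np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :], out=d)
    return d


def _global_efficiency_weights(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = _apsp_floyd(_length_matrix(weights))
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv.sum(axis=1).mean() / (n - 1))


def local_efficiency(net: HemisphericNetwork | np.ndarray) -> np.ndarray:
    """Global efficiency of each node's induced neighbor subgraph.

    Nodes with fewer than two neighbors score 0 (no neighbor pairs to
    route between).
    """
    weights = net.weights if isinstance(net, HemisphericNetwork) else np.asarray(net, float)
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(weights[i] > 0)
        if nb.size < 2:
            continue
        sub = weights[np.ix_(nb, nb)]
        out[i] = _global_efficiency_weights(sub)
    return out


def betweenness_centrality(net: HemisphericNetwork | np.ndarray) -> np.ndarray:
    """Normalized weighted betweenness (Brandes accumulation).

    Shortest paths use length 1/weight; equal-length alternatives (within
    1e-12) contribute through shortest-path counts sigma. The raw pair
    sums are normalized by (n-1)(n-2)/2 so values lie in [0, 1].
    """
    weights = net.weights if isinstance(net, HemisphericNetwork) else np.asarray(net, float)
    if np.any(weights < 0):
        raise ValueError("edge weights must be nonnegative")
    n = weights.shape[0]
    if n < 3:
        return np.zeros(n)
    nbrs = [np.flatnonzero(weights[i] > 0) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        sigma = np.zeros(n)
        sigma[s] = 1.0
        preds: list[list[int]] = [[] for _ in range(n)]
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d_v, v = heapq.heappop(heap)
            if done[v]:
                continue
            done[v] = True
            order.append(v)
            for w_node in nbrs[v]:
                nd = d_v + 1.0 / weights[v, w_node]
                if nd < dist[w_node] - _TOL:
                    dist[w_node] = nd
                    sigma[w_node] = sigma[v]
                    preds[w_node] = [v]
                    heapq.heappush(heap, (nd, int(w_node)))
                elif abs(nd - dist[w_node]) <= _TOL and not done[w_node]:
                    sigma[w_node] += sigma[v]
                    preds[w_node].append(v)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    bc /= 2.0  # each unordered pair (h, j) was counted from both endpoints
    return bc / ((n - 1) * (n - 2) / 2.0)


def modularity_q(weights: np.ndarray, communities: np.ndarray) -> float:
    """Q = (1/2m) sum_ij [w_ij - k_i k_j/(2m)] delta(c_i, c_j)."""
    weights = np.asarray(weights, dtype=float)
    communities = np.asarray(communities)
    m2 = weights.sum()
    if m2 <= 0:
        raise ValueError("modularity requires at least one edge")
    k = weights.sum(axis=1)
    q = 0.0
    for c in np.unique(communities):
        idx = np.flatnonzero(communities == c)
        q += weights[np.ix_(idx, idx)].sum() / m2 - (k[idx].sum() / m2) ** 2
    return float(q)


def _louvain_one_level(
    weights: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Greedy local node moves with randomized visitation order.

    ``weights`` may carry self-loops (aggregated graphs); self-loop weight
    moves with its node and cancels out of the move gain.
    """
    n = weights.shape[0]
    m2 = weights.sum()
    k = weights.sum(axis=1)
    comm = np.arange(n)
    sigma_tot = k.copy()
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            links = np.zeros(n)
            np.add.at(links, comm, weights[i])
            links[ci] -= weights[i, i]
            sigma_tot[ci] -= k[i]
            gains = links - k[i] * sigma_tot / m2
            candidates = np.flatnonzero(links > 0)
            best, best_gain = ci, gains[ci]
            for c in candidates:
                if gains[c] > best_gain + 1e-12:
                    best, best_gain = int(c), gains[c]
            comm[i] = best
            sigma_tot[best] += k[i]
            if best != ci:
                improved = True
                moved_any = True
    return comm, moved_any


def _aggregate(weights: np.ndarray, comm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, inv = np.unique(comm, return_inverse=True)
    nc = labels.size
    sel = np.zeros((weights.shape[0], nc))
    sel[np.arange(weights.shape[0]), inv] = 1.0
    return sel.T @ weights @ sel, inv


def louvain_once(weights: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One multilevel greedy optimization run; returns (partition, Q)."""
    n0 = weights.shape[0]
    node_to_comm = np.arange(n0)
    level = weights.astype(float).copy()
    while True:
        comm, moved = _louvain_one_level(level, rng)
        _, inv = np.unique(comm, return_inverse=True)
        node_to_comm = inv[node_to_comm]
        n_comms = inv.max() + 1
        if not moved or n_comms == level.shape[0]:
            break
        level, _ = _aggregate(level, comm)
    _, node_to_comm = np.unique(node_to_comm, return_inverse=True)
    return node_to_comm, modularity_q(weights, node_to_comm)


def modularity_repeated(
    net: HemisphericNetwork | np.ndarray,
    n_runs: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray, float]:
    """Repeat the randomized optimization; mean Q and the best partition.

    Returns ``(mean_q, best_partition, best_q)``. The heuristic's optimum
    differs slightly from run to run, so the mean over many repetitions is
    the stable summary reported downstream.
    """
    weights = net.weights if isinstance(net, HemisphericNetwork) else np.asarray(net, float)
    if weights.sum() <= 0:
        raise ValueError("modularity requires a network with at least one edge")
    if n_runs <= 0:
        raise ValueError(f"n_runs must be positive, got {n_runs}")
    rng = np.random.default_rng() if rng is None else rng
    qs = np.empty(n_runs)
    best_q = -np.inf
    best_partition = None
    for i in range(n_runs):
        partition, q = louvain_once(weights, rng)
        qs[i] = q
        if q > best_q:
            best_q = q
            best_partition = partition
    return float(qs.mean()), best_partition, float(best_q)


def assortativity_coefficient(net: HemisphericNetwork | np.ndarray) -> float:
    """Strength assortativity over the (both-orientation) edge list.

    Returns NaN when endpoint strengths have zero variance (e.g. regular
    graphs), in which case the coefficient is undefined and the value is
    excluded from downstream normative scoring.
    """
    weights = net.weights if isinstance(net, HemisphericNetwork) else np.asarray(net, float)
    iu, ju = np.nonzero(np.triu(weights, 1))
    if iu.size < 2:
        raise ValueError("assortativity requires at least 2 edges")
    k = weights.sum(axis=1)
    x = np.concatenate([k[iu], k[ju]])
    y = np.concatenate([k[ju], k[iu]])
    if x.std() < 1e-15 or y.std() < 1e-15:
        logger.info("assortativity undefined: zero variance of endpoint strengths")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class MetricSet:
    """Per-node and global metric values of one network at one sparsity."""

    roi_labels: list[str]
    sparsity: float
    degree: np.ndarray
    e_nodal: np.ndarray
    e_local: np.ndarray
    betweenness: np.ndarray
    e_global: float
    modularity_mean: float
    modularity_runs: int
    assortativity: float  # NaN = undefined

    def __post_init__(self):
        n = len(self.roi_labels)
        for name in ("degree", "e_nodal", "e_local", "betweenness"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (n,):
                raise ValueError(f"{name} must have length {n}, got shape {v.shape}")
        if not np.isclose(self.e_global, self.e_nodal.mean()):
            raise ValueError("e_global must equal the mean of e_nodal")

    def global_summary(self) -> dict[str, float]:
        """Hemispheric scalar summaries (node metrics averaged over nodes)."""
        return {
            "degree": float(self.degree.mean()),
            "e_local": float(self.e_local.mean()),
            "e_global": float(self.e_global),
            "betweenness": float(self.betweenness.mean()),
            "modularity": float(self.modularity_mean),
            "assortativity": float(self.assortativity),
        }

    def node_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_labels,
                "degree": self.degree,
                "e_nodal": self.e_nodal,
                "e_local": self.e_local,
                "betweenness": self.betweenness,
            }
        )

    def write(self, node_path: str | Path, global_path: str | Path) -> None:
        self.node_frame().to_csv(node_path, index=False, float_format="%.12g")
        pd.DataFrame(
            [
                {
                    "sparsity": self.sparsity,
                    "e_global": self.e_global,
                    "modularity_mean": self.modularity_mean,
                    "modularity_runs": self.modularity_runs,
                    "assortativity": self.assortativity,
                }
            ]
        ).to_csv(global_path, index=False, float_format="%.12g")


def read_metric_set(node_path: str | Path, global_path: str | Path) -> MetricSet:
    """Rebuild a :class:`MetricSet` from its two CSV files."""
    nodes = pd.read_csv(node_path)
    glob = pd.read_csv(global_path).iloc[0]
    e_nodal = nodes["e_nodal"].to_numpy(dtype=float)
    return MetricSet(
        roi_labels=[str(r) for r in nodes["roi"]],
        sparsity=float(glob["sparsity"]),
        degree=nodes["degree"].to_numpy(dtype=float),
        e_nodal=e_nodal,
        e_local=nodes["e_local"].to_numpy(dtype=float),
        betweenness=nodes["betweenness"].to_numpy(dtype=float),
        e_global=float(e_nodal.mean()),
        modularity_mean=float(glob["modularity_mean"]),
        modularity_runs=int(glob["modularity_runs"]),
        assortativity=float(glob["assortativity"]),
    )


def compute_metric_set(
    net: HemisphericNetwork,
    n_modularity_runs: int = 500,
    rng: np.random.Generator | None = None,
) -> MetricSet:
    """All node-level and global metrics of one thresholded network."""
    paths = shortest_paths(net)
    e_nodal, e_global = nodal_and_global_efficiency(paths)
    mod_mean, _, _ = modularity_repeated(net, n_runs=n_modularity_runs, rng=rng)
    return MetricSet(
        roi_labels=list(net.roi_labels),
        sparsity=net.sparsity,
        degree=node_degree(net),
        e_nodal=e_nodal,
        e_local=local_efficiency(net),
        betweenness=betweenness_centrality(net),
        e_global=e_global,
        modularity_mean=mod_mean,
        modularity_runs=n_modularity_runs,
        assortativity=assortativity_coefficient(net),
    )
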