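"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately written from first principles (exhaustive
enumeration, textbook formulas, scipy/networkx reference routines) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def lengths_from_weights(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def apsp_oracle(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths via scipy's Floyd-Warshall."""
    lengths = lengths_from_weights(weights)
    graph = np.where(np.isfinite(lengths) & (lengths > 0), lengths, 0.0)
    return floyd_warshall(graph, directed=False)


def global_efficiency_oracle(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    d = apsp_oracle(weights)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency_oracle(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if weights[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = weights[np.ix_(nb, nb)]
        out[i] = global_efficiency_oracle(sub)
    return out


def betweenness_oracle(weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Exhaustive simple-path enumeration (small n only).

    For every unordered pair, enumerate all simple paths, find those of
    minimal total length 1/w, and credit intermediate nodes with the
    fraction of minimal paths passing through them.
    """
    n = weights.shape[0]
    bc = np.zeros(n)
    adj = [[j for j in range(n) if weights[i, j] > 0] for i in range(n)]

    def all_simple_paths(s: int, t: int):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))

    for s, t in itertools.combinations(range(n), 2):
        paths = list(all_simple_paths(s, t))
        if not paths:
            continue
        costs = [sum(1.0 / weights[a, b] for a, b in zip(p, p[1:])) for p in paths]
        dmin = min(costs)
        minimal = [p for p, c in zip(paths, costs) if c <= dmin + tol]
        sigma = len(minimal)
        for p in minimal:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc / ((n - 1) * (n - 2) / 2.0)


def modularity_q_oracle(weights: np.ndarray, communities) -> float:
    """Direct evaluation of Q = (1/2m) sum_ij [w_ij - k_i k_j/2m] delta."""
    communities = np.asarray(communities)
    m2 = weights.sum()
    k = weights.sum(axis=1)
    q = 0.0
    n = weights.shape[0]
    for i in range(n):
        for j in range(n):
            if communities[i] == communities[j]:
                q += weights[i, j] - k[i] * k[j] / m2
    return q / m2


def set_partitions(items: list[int]):
    """All set partitions (restricted-growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def max_modularity_oracle(weights: np.ndarray) -> float:
    """Exhaustive maximum Q over all partitions (n <= 8)."""
    n = weights.shape[0]
    best = -np.inf
    for part in set_partitions(list(range(n))):
        comm = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            comm[list(block)] = c
        best = max(best, modularity_q_oracle(weights, comm))
    return best


def assortativity_oracle(weights: np.ndarray) -> float:
    """Newman's edge-sum formula for degree (strength) assortativity."""
    k = weights.sum(axis=1)
    edges = [(i, j) for i in range(weights.shape[0]) for j in range(weights.shape[0])
             if i < j and weights[i, j] > 0]
    m = len(edges)
    s_jk = sum(k[i] * k[j] for i, j in edges) / m
    s_half = sum(0.5 * (k[i] + k[j]) for i, j in edges) / m
    s_sq = sum(0.5 * (k[i] ** 2 + k[j] ** 2) for i, j in edges) / m
    denom = s_sq - s_half**2
    if denom <= 0:
        return float("nan")
    return (s_jk - s_half**2) / denom


def ttest_oracle(z: np.ndarray) -> tuple[float, float]:
    """One-sample t against 0 from the textbook formula."""
    from scipy.stats import t as t_dist

    z = np.asarray(z, dtype=float)
    n = z.size
    t = z.mean() / (z.std(ddof=1) / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return float(t), float(p)


def random_weighted_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with ~density edges."""
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w
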