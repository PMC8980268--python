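"""Correlation matrices and sparsity-thresholded weighted networks.

Interregional functional connectivity is the Pearson correlation of the
preprocessed ROI time series. The symmetric correlation matrix is turned
into a weighted undirected network by sparsity thresholding: the requested
edge density (ratio of retained edges to all n(n-1)/2 possible edges)
selects a network-specific correlation cutoff, so every network has the
same edge count regardless of its overall correlation level. Negative
correlations are discarded before thresholding and edge weights are the
raw (untransformed) correlation values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import RoiTimeSeries

__all__ = ["ConnectivityMatrix", "HemisphericNetwork", "pearson_matrix", "apply_sparsity"]


@dataclass
class ConnectivityMatrix:
    """Symmetric Pearson matrix with unit diagonal."""

    roi_labels: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.roi_labels)
        if self.r.shape != (n, n):
            raise ValueError(f"matrix shape {self.r.shape} does not match {n} labels")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric within 1e-12")
        if np.any(np.abs(self.r) > 1.0 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=self.roi_labels, columns=self.roi_labels).to_csv(
            path, float_format="%.12g"
        )

    @classmethod
    def read(cls, path: str | Path) -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(roi_labels=list(df.index), r=df.to_numpy(dtype=float))


@dataclass
class HemisphericNetwork:
    """Weighted undirected network at a fixed edge density."""

    roi_labels: list[str]
    weights: np.ndarray  # symmetric, nonnegative, zero diagonal
    sparsity: float
    n_edges: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.roi_labels)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights shape {self.weights.shape} does not match {n} labels")
        if np.any(self.weights < 0):
            raise ValueError("edge weights must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight diagonal must be zero")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weight matrix is not symmetric")
        actual = int(np.count_nonzero(np.triu(self.weights, 1)))
        if actual != self.n_edges:
            raise ValueError(f"n_edges={self.n_edges} but {actual} nonzero edges present")

    @property
    def n_nodes(self) -> int:
        return len(self.roi_labels)

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=self.roi_labels, columns=self.roi_labels).to_csv(
            path, float_format="%.12g"
        )

    @classmethod
    def read(cls, path: str | Path, sparsity: float) -> "HemisphericNetwork":
        df = pd.read_csv(path, index_col=0)
        w = df.to_numpy(dtype=float)
        n_edges = int(np.count_nonzero(np.triu(w, 1)))
        return cls(roi_labels=list(df.index), weights=w, sparsity=sparsity, n_edges=n_edges)


def pearson_matrix(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Product-moment correlation of all ROI pairs; diagonal exactly 1."""
    if ts.n_volumes < 3:
        raise ValueError(f"need at least 3 time points, got {ts.n_volumes}")
    sd = ts.data.std(axis=1)
    constant = np.flatnonzero(sd < 1e-14)
    if constant.size:
        names = ", ".join(ts.roi_labels[i] for i in constant)
        raise ValueError(f"constant time series for ROI(s): {names}; correlation undefined")
    r = np.corrcoef(ts.data)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(roi_labels=list(ts.roi_labels), r=r)


def apply_sparsity(cm: ConnectivityMatrix, sparsity: float) -> HemisphericNetwork:
    """Keep the largest positive correlations at the requested density.

    Retains exactly ``round(sparsity * n(n-1)/2)`` edges, breaking ties at
    the cutoff rank in deterministic lexicographic (i, j) order; negative
    entries and the diagonal are removed first and retained weights are
    the raw correlations (not binarized).
    """
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = len(cm.roi_labels)
    n_possible = n * (n - 1) // 2
    n_edges = int(round(sparsity * n_possible))
    iu, ju = np.triu_indices(n, k=1)
    w = cm.r[iu, ju]
    positive = w > 0
    n_positive = int(positive.sum())
    if n_positive < n_edges:
        raise ValueError(
            f"only {n_positive} positive correlations available but sparsity "
            f"{sparsity:g} requires {n_edges} edges; achievable maximum sparsity "
            f"is {n_positive / n_possible:.4f}"
        )
    # sort by (-weight, i, j): descending weight, lexicographic tie-break
    order = np.lexsort((ju, iu, -w))
    keep = order[:n_edges]
    weights = np.zeros((n, n))
    weights[iu[keep], ju[keep]] = w[keep]
    weights += weights.T
    return HemisphericNetwork(
        roi_labels=list(cm.roi_labels), weights=weights, sparsity=sparsity, n_edges=n_edges
    )
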