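"""Correlation-based functional connectivity of active neurons.

Pairwise Pearson correlation of epoch-restricted traces, thresholded into
an undirected, unweighted graph (edge where r exceeds a positive
threshold), summarized by the mean degree. The edge rule — positive r
above a configurable threshold, default 0.5 — is deliberately surfaced as
a free parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

DEFAULT_R_THRESHOLD = 0.5


@dataclass
class CorrelationMatrix:
    """m x m Pearson r of active-neuron traces; NaN rows mark zero-variance traces."""

    values: np.ndarray
    neuron_ids: np.ndarray
    valid: np.ndarray  # False where the trace had zero variance in the epoch

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        m = self.values.shape[0]
        if self.values.shape != (m, m):
            raise ValueError("correlation matrix must be square")
        self.neuron_ids = np.asarray(self.neuron_ids)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class ConnectivityGraph:
    """Symmetric 0/1 adjacency with zero diagonal; invalid nodes are isolated."""

    adjacency: np.ndarray
    r_threshold: float
    neuron_ids: np.ndarray
    valid: np.ndarray

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        nx.relabel_nodes(g, dict(enumerate(self.neuron_ids)), copy=False)
        return g


def correlation_matrix(traces: np.ndarray, neuron_ids: np.ndarray | None = None) -> CorrelationMatrix:
    """Pairwise Pearson correlation of an (m, t) matrix of epoch traces.

    Zero-variance traces cannot be correlated; their row and column are set
    to NaN and flagged invalid.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need at least 2 neurons (m x t matrix)")
    if traces.shape[1] < 3:
        raise ValueError("epoch must span at least 3 frames")
    if neuron_ids is None:
        neuron_ids = np.arange(traces.shape[0])

    sd = traces.std(axis=1)
    valid = sd > 0
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} zero-variance trace(s) flagged missing")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(traces)
    r[~valid, :] = np.nan
    r[:, ~valid] = np.nan
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    return CorrelationMatrix(values=r, neuron_ids=neuron_ids, valid=valid)


def build_graph(corr: CorrelationMatrix, r_threshold: float = DEFAULT_R_THRESHOLD) -> ConnectivityGraph:
    """Edge (i, j) iff r_ij > r_threshold, i != j; NaN never makes an edge."""
    if not 0.0 < r_threshold < 1.0:
        raise ValueError("r_threshold must be in (0, 1)")
    with np.errstate(invalid="ignore"):
        adj = (corr.values > r_threshold).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return ConnectivityGraph(
        adjacency=adj,
        r_threshold=r_threshold,
        neuron_ids=corr.neuron_ids,
        valid=corr.valid,
    )


def mean_degree(g: ConnectivityGraph) -> float:
    """Mean number of edges per node, over valid (non-degenerate) nodes only."""
    if g.adjacency.shape[0] < 1:
        raise ValueError("graph must have at least one node")
    if not g.valid.any():
        return float("nan")
    degrees = g.adjacency.sum(axis=1)
    return float(degrees[g.valid].mean())
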