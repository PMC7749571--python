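"""Weighted graph summaries: strength, degree, characteristic path length,
clustering coefficient.

All four metrics consume the absolute values of the signed correlation
weights (negative edge lengths and complex cube roots are otherwise
ill-defined); the sign of each connection is preserved separately by the
connectivity stage for reporting.

Definitions, for a weighted undirected graph with weights w_ij >= 0:

* strength       S_i = sum_j w_ij;            SA = mean_i S_i
* degree         d_i = #{j : w_ij > 0};       DA = mean_i d_i
* path length    edge length = 1/w_ij; L_ij = weighted shortest-path length;
                 LA = 1 / [ (1/(N(N-1))) * sum_{i != j} 1/L_ij ]
                 (harmonic-mean form; a disconnected pair contributes
                 1/L_ij = 0, and a fully disconnected graph has LA = +inf)
* clustering     weights are first rescaled by the maximum weight,
                 C_i = (1/(d_i(d_i-1))) * sum_{j,k} (w'_ij w'_jk w'_ki)^(1/3)
                 over ordered neighbour pairs (the geometric-mean / Onnela
                 form), C_i = 0 when d_i < 2; CA = mean_i C_i
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import WeightedGraph
from .io_core import ParameterError


@dataclass
class GraphMetricsRecord:
    """Per-subject, per-band metric bundle: node vectors + network scalars."""

    subject_id: str
    band: str
    S: np.ndarray
    d: np.ndarray
    C: np.ndarray
    L: np.ndarray  # pairwise shortest-path lengths (inf when disconnected)
    SA: float
    DA: float
    LA: float
    CA: float

    def scalars(self) -> dict[str, float]:
        return {"SA": self.SA, "DA": self.DA, "LA": self.LA, "CA": self.CA}


def _abs_adjacency(g: WeightedGraph) -> np.ndarray:
    W = g.abs_weights().astype(np.float64)
    np.fill_diagonal(W, 0.0)
    return W


def node_strength(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """S_i = row sums of |W|; SA = their mean.  Empty graph -> all zeros."""
    W = _abs_adjacency(g)
    S = W.sum(axis=1)
    return S, float(S.mean())


def node_degree(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """d_i = number of incident nonzero edges; DA = mean degree."""
    W = _abs_adjacency(g)
    d = (W > 0).sum(axis=1)
    return d, float(d.mean())


def path_length(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """Weighted shortest paths with edge length 1/w, plus the harmonic-form
    network average LA.

    Returns the full L matrix (diagonal 0, +inf for disconnected pairs).  A
    graph with < 2 nodes has no node pairs and is an error; a graph whose
    every pair is disconnected yields LA = +inf.
    """
    W = _abs_adjacency(g)
    n = W.shape[0]
    if n < 2:
        raise ParameterError("path length undefined for graphs with < 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    L = dijkstra(csr_matrix(lengths), directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(L), 0.0, 1.0 / np.where(L > 0, L, np.inf))
    harmonic_sum = inv[off].sum() / (n * (n - 1))
    LA = float(1.0 / harmonic_sum) if harmonic_sum > 0 else float("inf")
    return L, LA


def clustering(g: WeightedGraph) -> tuple[np.ndarray, float]:
    """Geometric-mean weighted clustering with max-weight normalization.

    C_i sums (w'_ij w'_jk w'_ki)^(1/3) over ordered neighbour pairs and
    divides by d_i(d_i-1); nodes of degree < 2 get C_i = 0.
    """
    W = _abs_adjacency(g)
    wmax = W.max()
    What = W / wmax if wmax > 0 else W
    cube = np.cbrt(What)
    # diag of cube^3 counts ordered pairs (j,k), j != k, through node i
    tri = np.diagonal(cube @ cube @ cube).copy()
    d = (W > 0).sum(axis=1).astype(np.float64)
    denom = d * (d - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, tri / denom, 0.0)
    return C, float(C.mean())


def metrics_record(g: WeightedGraph) -> GraphMetricsRecord:
    """Bundle all four metrics for one thresholded graph."""
    S, SA = node_strength(g)
    d, DA = node_degree(g)
    L, LA = path_length(g)
    C, CA = clustering(g)
    return GraphMetricsRecord(
        subject_id=g.subject_id,
        band=g.band,
        S=S, d=d, C=C, L=L,
        SA=SA, DA=DA, LA=LA, CA=CA,
    )
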