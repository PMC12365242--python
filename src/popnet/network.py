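"""Multilayer network container and degree-level descriptive statistics.

The network is an undirected, single-aspect multilayer graph over a shared
vertex set: per-layer intra-layer adjacency only, no self-loops, no
coupling edges.  Degrees come in three flavours: the per-layer degree
k_{u,l}, the total degree k_u (summed over layers, so a dyad present in
two layers counts twice), and the number of unique neighbors k'_u — the
degree in the flattened (monoplex) aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "MultilayerNetwork",
    "FlattenedGraph",
    "DegreeSummary",
    "layer_degree_correlation",
    "edge_overlap_matrix",
    "degree_distributions",
    "inverse_ccdf",
    "tail_slope",
]


class FlattenedGraph:
    """Monoplex aggregation of a multilayer network.

    An edge joins u and v iff they are adjacent in at least one layer.
    """

    def __init__(self, vertices: np.ndarray, adjacency: sp.csr_matrix):
        self.vertices = vertices
        self.adjacency = adjacency  # boolean-valued csr, symmetric, no diagonal

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def edge_array(self) -> np.ndarray:
        """(m, 2) array of vertex indices with u < v."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.vertices.tolist())
        for i, j in self.edge_array():
            g.add_edge(self.vertices[i], self.vertices[j])
        return g


class MultilayerNetwork:
    """Vertex set plus one undirected edge set per layer.

    Vertices are arbitrary hashable ids (the analysis-year persons);
    internally they map to dense indices 0..n-1.  Layer adjacency is kept
    as boolean CSR matrices.
    """

    def __init__(
        self,
        vertices: Sequence,
        layer_edges: Mapping[str, pd.DataFrame | np.ndarray | Iterable[tuple]],
        layers: Sequence[str] | None = None,
    ):
        self.vertices = np.asarray(sorted(vertices))
        self._index = {v: i for i, v in enumerate(self.vertices)}
        self.layers = tuple(layers) if layers is not None else tuple(layer_edges)
        n = len(self.vertices)
        self._adj: dict[str, sp.csr_matrix] = {}
        self._edges: dict[str, np.ndarray] = {}
        for layer in self.layers:
            edges = layer_edges.get(layer)
            idx = self._edge_indices(edges)
            self._edges[layer] = idx
            if len(idx):
                data = np.ones(len(idx), dtype=np.int64)
                a = sp.coo_matrix(
                    (np.concatenate([data, data]),
                     (np.concatenate([idx[:, 0], idx[:, 1]]),
                      np.concatenate([idx[:, 1], idx[:, 0]]))),
                    shape=(n, n),
                ).tocsr()
                a.data[:] = 1
            else:
                a = sp.csr_matrix((n, n), dtype=np.int64)
            self._adj[layer] = a

    def _edge_indices(self, edges) -> np.ndarray:
        if edges is None:
            return np.empty((0, 2), dtype=np.int64)
        if isinstance(edges, pd.DataFrame):
            pairs = edges[["u", "v"]].to_numpy()
        else:
            pairs = np.asarray(list(edges) if not isinstance(edges, np.ndarray) else edges)
            if pairs.size == 0:
                return np.empty((0, 2), dtype=np.int64)
            pairs = pairs.reshape(-1, 2)
        if pairs.size == 0:
            return np.empty((0, 2), dtype=np.int64)
        try:
            iu = np.array([self._index[u] for u in pairs[:, 0]], dtype=np.int64)
            iv = np.array([self._index[v] for v in pairs[:, 1]], dtype=np.int64)
        except KeyError as e:  # endpoint outside the vertex set
            raise KeyError(f"edge endpoint {e.args[0]!r} not in vertex set") from None
        if (iu == iv).any():
            raise ValueError("self-loops are not allowed")
        lo, hi = np.minimum(iu, iv), np.maximum(iu, iv)
        idx = np.unique(np.column_stack([lo, hi]), axis=0)
        return idx

    # -- basic accessors ----------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def index_of(self, u) -> int:
        try:
            return self._index[u]
        except KeyError:
            raise KeyError(f"unknown vertex {u!r}") from None

    def adjacency(self, layer: str) -> sp.csr_matrix:
        if layer not in self._adj:
            raise KeyError(f"unknown layer {layer!r}")
        return self._adj[layer]

    def edge_indices(self, layer: str) -> np.ndarray:
        if layer not in self._edges:
            raise KeyError(f"unknown layer {layer!r}")
        return self._edges[layer]

    def n_edges(self, layer: str) -> int:
        return len(self.edge_indices(layer))

    # -- degrees (per layer, total, unique neighbors) -----------------------

    def degree_matrix(self) -> np.ndarray:
        """(n, n_layers) matrix of per-layer degrees k_{u,l}."""
        cols = [np.asarray(self._adj[l].sum(axis=1)).ravel() for l in self.layers]
        return np.column_stack(cols).astype(np.int64)

    def multiplicity_matrix(self) -> sp.csr_matrix:
        """Entry (u, v) = number of layers in which u and v are adjacent."""
        n = self.n_vertices
        s = sp.csr_matrix((n, n), dtype=np.int64)
        for l in self.layers:
            s = s + self._adj[l]
        return s

    def layer_degree(self, u, layer: str) -> int:
        i = self.index_of(u)
        return int(self.adjacency(layer)[i].sum())

    def total_degree(self, u) -> int:
        i = self.index_of(u)
        return int(sum(self._adj[l][i].sum() for l in self.layers))

    def unique_neighbors(self, u) -> int:
        i = self.index_of(u)
        s = self.multiplicity_matrix()[i]
        return int((s > 0).sum())

    def total_degrees(self) -> np.ndarray:
        return self.degree_matrix().sum(axis=1)

    def flattened_degrees(self) -> np.ndarray:
        return self.flatten().degrees()

    def flatten(self) -> FlattenedGraph:
        s = self.multiplicity_matrix()
        b = s.copy()
        b.data = np.ones_like(b.data)
        return FlattenedGraph(self.vertices, b)


# ---------------------------------------------------------------------------
# layer comparison matrices
# ---------------------------------------------------------------------------

def layer_degree_correlation(network: MultilayerNetwork) -> pd.DataFrame:
    """Pearson correlation of per-layer degrees over all vertices.

    Zero-degree vertices are included.  Layers with zero degree variance
    produce missing (NaN) entries; the diagonal is 1 where defined.
    """
    k = network.degree_matrix().astype(float)
    L = len(network.layers)
    out = np.full((L, L), np.nan)
    std = k.std(axis=0)
    for i in range(L):
        for j in range(L):
            if std[i] > 0 and std[j] > 0:
                out[i, j] = np.corrcoef(k[:, i], k[:, j])[0, 1]
    return pd.DataFrame(out, index=network.layers, columns=network.layers)


def edge_overlap_matrix(network: MultilayerNetwork) -> pd.DataFrame:
    """Edge overlap ratios between layers.

    Entry (row l1, column l2) = |E_l1 ∩ E_l2| / |E_l1| over unordered
    dyads, so a nested layer (E_l1 ⊆ E_l2) shows 1.00 in its own row.
    Diagonal is 1 for non-empty layers, NaN for empty ones.
    """
    L = network.layers
    sets = {l: set(map(tuple, network.edge_indices(l))) for l in L}
    out = np.full((len(L), len(L)), np.nan)
    for i, l1 in enumerate(L):
        if not sets[l1]:
            continue
        for j, l2 in enumerate(L):
            out[i, j] = len(sets[l1] & sets[l2]) / len(sets[l1])
    return pd.DataFrame(out, index=L, columns=L)


# ---------------------------------------------------------------------------
# degree distributions and tail slopes
# ---------------------------------------------------------------------------

@dataclass
class DegreeSummary:
    """Histogram bundle for per-layer, total and flattened degrees."""

    layer_histograms: dict[str, pd.Series]  # degree -> count
    disconnected: dict[str, int]  # zero-degree vertices per layer
    total_histogram: pd.Series
    flattened_histogram: pd.Series
    active_layer_histogram: pd.Series  # #layers with non-zero degree -> count
    layer_ccdf: dict[str, pd.DataFrame]  # columns degree, ccdf
    total_ccdf: pd.DataFrame
    tail_slopes: dict[str, float]  # per layer + "total"; NaN when undefined


def _histogram(values: np.ndarray) -> pd.Series:
    vals, counts = np.unique(values, return_counts=True)
    return pd.Series(counts, index=vals)


def inverse_ccdf(degrees: np.ndarray) -> pd.DataFrame:
    """P(K >= k) evaluated at the observed positive degrees."""
    degrees = np.asarray(degrees)
    pos = np.sort(degrees[degrees > 0])
    if len(pos) == 0:
        return pd.DataFrame({"degree": [], "ccdf": []})
    vals, counts = np.unique(pos, return_counts=True)
    tail = counts[::-1].cumsum()[::-1] / len(degrees)
    return pd.DataFrame({"degree": vals, "ccdf": tail})


def tail_slope(
    ccdf: pd.DataFrame | np.ndarray,
    *,
    top_fraction: float = 0.1,
    min_ccdf: float = 1e-4,
    min_points: int = 10,
) -> float:
    """Tail exponent as the negated OLS slope of log10 CCDF vs log10 degree.

    Fitted over the top ``top_fraction`` of observations — CCDF points
    with P(K >= k) <= ``top_fraction`` — excluding the ultra-sparse
    extreme where the CCDF drops below ``min_ccdf`` (order statistics
    there are too noisy to regress on).  Returns NaN when fewer than
    ``min_points`` distinct degrees fall in the window.  On an exactly
    Pareto CCDF (x^-alpha on a grid) this recovers alpha to numerical
    precision.
    """
    if isinstance(ccdf, pd.DataFrame):
        x = ccdf["degree"].to_numpy(dtype=float)
        y = ccdf["ccdf"].to_numpy(dtype=float)
    else:
        arr = np.asarray(ccdf, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    ok = (x > 0) & (y > 0)
    x, y = x[ok], y[ok]
    if len(x) == 0:
        return float("nan")
    sel = (y <= top_fraction) & (y >= min_ccdf)
    if sel.sum() < min_points:
        return float("nan")
    lx, ly = np.log10(x[sel]), np.log10(y[sel])
    slope = np.polyfit(lx, ly, 1)[0]
    return float(-slope)


def degree_distributions(network: MultilayerNetwork) -> DegreeSummary:
    """Degree histograms, zero-degree counts, active-layer counts, inverse
    CCDFs and tail slopes for each layer, the total and the flattened
    degree."""
    k = network.degree_matrix()
    total = k.sum(axis=1)
    flat = network.flattened_degrees()
    active = (k > 0).sum(axis=1)

    layer_hist = {}
    layer_ccdf = {}
    slopes = {}
    for i, l in enumerate(network.layers):
        layer_hist[l] = _histogram(k[:, i])
        layer_ccdf[l] = inverse_ccdf(k[:, i])
        slopes[l] = tail_slope(layer_ccdf[l])
    total_ccdf = inverse_ccdf(total)
    slopes["total"] = tail_slope(total_ccdf)
    return DegreeSummary(
        layer_histograms=layer_hist,
        disconnected={l: int((k[:, i] == 0).sum()) for i, l in enumerate(network.layers)},
        total_histogram=_histogram(total),
        flattened_histogram=_histogram(flat),
        active_layer_histogram=_histogram(active),
        layer_ccdf=layer_ccdf,
        total_ccdf=total_ccdf,
        tail_slopes=slopes,
    )
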