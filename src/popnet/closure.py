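"""Multilayer closure: embeddedness, tie range, triangles, excess closure.

Embeddedness of an edge counts common neighbors of its endpoints with
layer multiplicity on both sides: sum over layer pairs (l1, l2) and
vertices w of A[u,w,l1] * A[v,w,l2].  Tie range is the length of the
second-shortest path between an edge's endpoints — the flattened shortest
path after deleting the edge in every layer — computed by bidirectional
BFS and defined only for zero-embeddedness edges whose endpoints both have
flattened degree above one.  A wormhole is such an edge with a finite tie
range of at least six.

Triangle quantities per vertex use distinct vertex-triple semantics:
T_unique counts distinct flattened triangles at u; T_pure counts those
whose three edges all co-exist within at least one single layer (a
triangle pure in two layers counts once).  The alter-tie-pair count
P_u = C(k_u, 2) - sum_v C(m_uv, 2) with m_uv the layer multiplicity of the
(u, v) tie, and excess closure is
(T_unique - T_pure) / (P_u - T_pure), defined when P_u > T_pure.

The literal multiplicity reading of the triangle sums (ordered layer
triples) is retained behind ``semantics="multiplicity"`` for sensitivity
checks; it can push the excess-closure numerator negative and is not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import MultilayerNetwork

__all__ = [
    "WORMHOLE_THRESHOLD",
    "TIE_RANGE_MAX_DEPTH",
    "edge_embeddedness",
    "embeddedness_table",
    "tie_range",
    "bridge_records",
    "wormhole_census",
    "local_clustering",
    "alter_tie_pairs",
    "triangle_census",
    "excess_closure",
    "closure_profiles",
    "closure_by_degree",
]

#: minimum (finite) tie range that qualifies an edge as a network wormhole
WORMHOLE_THRESHOLD = 6
#: bidirectional BFS gives up beyond this depth and reports "unreachable"
TIE_RANGE_MAX_DEPTH = 15


# ---------------------------------------------------------------------------
# embeddedness
# ---------------------------------------------------------------------------

def edge_embeddedness(network: MultilayerNetwork, u, v) -> int:
    """Embeddedness of the edge (u, v); errors if (u, v) is in no layer."""
    i, j = network.index_of(u), network.index_of(v)
    s = network.multiplicity_matrix()
    if s[i, j] == 0:
        raise ValueError(f"({u!r}, {v!r}) is not an edge in any layer")
    row_i = s[i].toarray().ravel()
    row_j = s[j].toarray().ravel()
    return int((row_i * row_j).sum())


def embeddedness_table(network: MultilayerNetwork) -> pd.DataFrame:
    """Per flattened edge: endpoints (vertex indices), layer multiplicity
    and embeddedness."""
    s = network.multiplicity_matrix()
    flat = network.flatten()
    edges = flat.edge_array()
    if len(edges) == 0:
        return pd.DataFrame({"u": [], "v": [], "multiplicity": [], "embeddedness": []})
    s2 = (s @ s).tocsr()
    emb = np.asarray(s2[edges[:, 0], edges[:, 1]]).ravel()
    mult = np.asarray(s[edges[:, 0], edges[:, 1]]).ravel()
    return pd.DataFrame(
        {"u": edges[:, 0], "v": edges[:, 1],
         "multiplicity": mult.astype(np.int64),
         "embeddedness": emb.astype(np.int64)}
    )


# ---------------------------------------------------------------------------
# tie range and wormholes
# ---------------------------------------------------------------------------

def _adjacency_lists(adj: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
    return adj.indptr, adj.indices


def _bidirectional_bfs(
    indptr: np.ndarray,
    indices: np.ndarray,
    src: int,
    dst: int,
    max_depth: int,
    skip_edge: tuple[int, int],
) -> int | None:
    """Shortest path length src->dst ignoring the (src, dst) edge; None if
    longer than ``max_depth`` or disconnected."""
    a, b = skip_edge
    dist_s = {src: 0}
    dist_t = {dst: 0}
    frontier_s = [src]
    frontier_t = [dst]
    best = None
    depth = 0
    while frontier_s and frontier_t and depth < max_depth:
        # expand the smaller frontier
        if len(frontier_s) <= len(frontier_t):
            frontier, dist, other = frontier_s, dist_s, dist_t
            forward = True
        else:
            frontier, dist, other = frontier_t, dist_t, dist_s
            forward = False
        depth += 1
        nxt = []
        base = dist[frontier[0]]
        for x in frontier:
            for y in indices[indptr[x] : indptr[x + 1]]:
                y = int(y)
                if (x == a and y == b) or (x == b and y == a):
                    continue
                if y in dist:
                    continue
                dist[y] = base + 1
                if y in other:
                    total = dist[y] + other[y]
                    if best is None or total < best:
                        best = total
                nxt.append(y)
        if best is not None:
            # any meeting at completed radii certifies the minimum: a
            # shorter path would have produced an earlier meeting
            return best if best <= max_depth else None
        if forward:
            frontier_s = nxt
        else:
            frontier_t = nxt
    return best


def tie_range(
    network: MultilayerNetwork,
    u,
    v,
    max_depth: int = TIE_RANGE_MAX_DEPTH,
) -> int | None:
    """Tie range of the edge (u, v): flattened shortest path after removing
    the (u, v) edge from every layer; None when unreachable within
    ``max_depth``.

    Preconditions (errors otherwise): (u, v) is an edge with embeddedness
    zero and both endpoints have flattened degree > 1.  A returned value is
    always >= 3 — embeddedness zero rules out any length-2 detour.
    """
    i, j = network.index_of(u), network.index_of(v)
    flat = network.flatten()
    if edge_embeddedness(network, u, v) != 0:
        raise ValueError("tie range requires an edge with embeddedness zero")
    deg = flat.degrees()
    if deg[i] <= 1 or deg[j] <= 1:
        raise ValueError("tie range requires both endpoints' degree > 1")
    indptr, indices = _adjacency_lists(flat.adjacency)
    return _bidirectional_bfs(indptr, indices, i, j, max_depth, (i, j))


def bridge_records(
    network: MultilayerNetwork,
    *,
    max_depth: int = TIE_RANGE_MAX_DEPTH,
    threshold: int = WORMHOLE_THRESHOLD,
    max_edges: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tie range for every qualifying zero-embeddedness edge.

    Qualifying edges have embeddedness zero and both endpoints' flattened
    degree > 1.  ``max_edges`` caps the census at a seeded uniform sample
    (population-scale runs).  Columns: u, v (vertex indices), embeddedness,
    tie_range (NaN = unreachable within ``max_depth``), is_wormhole.
    """
    emb = embeddedness_table(network)
    flat = network.flatten()
    deg = flat.degrees()
    zero = emb[emb["embeddedness"] == 0]
    qual = zero[(deg[zero["u"]] > 1) & (deg[zero["v"]] > 1)]
    if max_edges is not None and len(qual) > max_edges:
        rng = np.random.default_rng(seed)
        qual = qual.iloc[np.sort(rng.choice(len(qual), size=max_edges, replace=False))]
    indptr, indices = _adjacency_lists(flat.adjacency)
    ranges: list[float] = []
    for i, j in qual[["u", "v"]].itertuples(index=False):
        r = _bidirectional_bfs(indptr, indices, int(i), int(j), max_depth, (int(i), int(j)))
        ranges.append(np.nan if r is None else float(r))
    out = qual[["u", "v", "embeddedness"]].copy().reset_index(drop=True)
    out["tie_range"] = ranges
    out["is_wormhole"] = pd.notna(out["tie_range"]) & (out["tie_range"] >= threshold)
    return out


@dataclass
class WormholeCensus:
    n_edges: int  # flattened edges in the network
    n_zero_embedded: int  # embeddedness-zero edges (any degree)
    n_qualifying: int  # zero-embedded with both flattened degrees > 1
    n_examined: int  # qualifying edges whose tie range was computed
    n_wormholes: int
    n_unreachable: int
    tie_range_histogram: pd.Series  # finite tie range -> count


def wormhole_census(
    network: MultilayerNetwork,
    threshold: int = WORMHOLE_THRESHOLD,
    *,
    max_depth: int = TIE_RANGE_MAX_DEPTH,
    max_edges: int | None = None,
    seed: int = 0,
) -> WormholeCensus:
    """Count zero-embeddedness edges and wormholes (finite tie range >=
    ``threshold``).  Edges disconnected by their own removal are reported
    as unreachable, not as wormholes."""
    emb = embeddedness_table(network)
    n_zero = int((emb["embeddedness"] == 0).sum())
    rec = bridge_records(
        network, max_depth=max_depth, threshold=threshold,
        max_edges=max_edges, seed=seed,
    )
    finite = rec["tie_range"].dropna().astype(int)
    hist = finite.value_counts().sort_index() if len(finite) else pd.Series(dtype=int)
    flat_deg = network.flatten().degrees()
    zero_all = emb[emb["embeddedness"] == 0]
    n_qual = int(((flat_deg[zero_all["u"]] > 1) & (flat_deg[zero_all["v"]] > 1)).sum())
    return WormholeCensus(
        n_edges=int(len(emb)),
        n_zero_embedded=n_zero,
        n_qualifying=n_qual,
        n_examined=int(len(rec)),
        n_wormholes=int(rec["is_wormhole"].sum()),
        n_unreachable=int(rec["tie_range"].isna().sum()),
        tie_range_histogram=hist,
    )


# ---------------------------------------------------------------------------
# triangles, clustering, excess closure
# ---------------------------------------------------------------------------

def _triangle_counts(b: sp.csr_matrix) -> np.ndarray:
    """Triangles per vertex in a boolean symmetric adjacency."""
    if b.nnz == 0:
        return np.zeros(b.shape[0], dtype=np.int64)
    paths = (b @ b).multiply(b)
    return (np.asarray(paths.sum(axis=1)).ravel() // 2).astype(np.int64)


def _pure_triangle_counts(network: MultilayerNetwork) -> np.ndarray:
    """Distinct triples forming a triangle inside at least one layer.

    Inclusion-exclusion over layer subsets: a triple pure in several layers
    is a triangle of the elementwise intersection graph of those layers.
    Subsets whose intersection has no edges are pruned.
    """
    n = network.n_vertices
    total = np.zeros(n, dtype=np.int64)
    layers = network.layers
    adjs = {l: network.adjacency(l) for l in layers}

    def recurse(start: int, inter: sp.csr_matrix, depth: int) -> None:
        nonlocal total
        for idx in range(start, len(layers)):
            nxt = inter.multiply(adjs[layers[idx]]) if inter is not None else adjs[layers[idx]]
            nxt = nxt.tocsr()
            if nxt.nnz == 0:
                continue
            if nxt.nnz:
                nxt.data = np.ones_like(nxt.data)
            sign = 1 if depth % 2 == 0 else -1
            total = total + sign * _triangle_counts(nxt)
            recurse(idx + 1, nxt, depth + 1)

    recurse(0, None, 0)
    return total


def triangle_census(
    network: MultilayerNetwork, u=None, *, semantics: str = "distinct"
):
    """(T_unique, T_pure) for one vertex, or arrays for all vertices.

    ``semantics="distinct"`` (default): distinct vertex triples.
    ``semantics="multiplicity"``: the literal ordered-layer-triple sums —
    every (l1, l2, l3) assignment of the three edges counts separately.
    """
    if semantics not in ("distinct", "multiplicity"):
        raise ValueError("semantics must be 'distinct' or 'multiplicity'")
    if semantics == "distinct":
        b = network.flatten().adjacency
        t_unique = _triangle_counts(b)
        t_pure = _pure_triangle_counts(network)
    else:
        s = network.multiplicity_matrix()
        t_unique = (np.asarray((s @ s).multiply(s).sum(axis=1)).ravel() // 2).astype(np.int64)
        t_pure = np.zeros(network.n_vertices, dtype=np.int64)
        for l in network.layers:
            t_pure += _triangle_counts(network.adjacency(l))
    if u is None:
        return t_unique, t_pure
    i = network.index_of(u)
    return int(t_unique[i]), int(t_pure[i])


def alter_tie_pairs(network: MultilayerNetwork, u=None):
    """P_u = C(k_u, 2) - sum_v C(m_uv, 2): unordered pairs of u's incident
    ties (with layer multiplicity) whose alters differ."""
    s = network.multiplicity_matrix()
    k = np.asarray(s.sum(axis=1)).ravel()
    m = s.copy()
    m.data = m.data * (m.data - 1) // 2
    same = np.asarray(m.sum(axis=1)).ravel()
    p = (k * (k - 1)) // 2 - same
    if u is None:
        return p.astype(np.int64)
    return int(p[network.index_of(u)])


def local_clustering(network: MultilayerNetwork, u=None):
    """Local clustering on the flattened graph: triangles at u over
    k'_u (k'_u - 1) / 2.  Vertices with k'_u < 2 report 0 (undefined)."""
    flat = network.flatten()
    kf = flat.degrees()
    t = _triangle_counts(flat.adjacency)
    with np.errstate(divide="ignore", invalid="ignore"):
        lcc = np.where(kf >= 2, 2.0 * t / (kf * (kf - 1.0)), 0.0)
    if u is None:
        return lcc
    return float(lcc[network.index_of(u)])


def excess_closure(network: MultilayerNetwork, u=None, *, semantics: str = "distinct"):
    """c_excess = (T_unique - T_pure) / (P_u - T_pure); NaN when
    P_u = T_pure (undefined)."""
    t_unique, t_pure = triangle_census(network, semantics=semantics)
    p = alter_tie_pairs(network)
    denom = p - t_pure
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, (t_unique - t_pure) / denom, np.nan)
    if u is None:
        return c
    return float(c[network.index_of(u)])


def closure_profiles(network: MultilayerNetwork) -> pd.DataFrame:
    """Per-vertex closure bundle.

    Columns: person_id, k_flat (unique neighbors), k_total, lcc,
    lcc_defined, T_unique, T_pure, P, c_excess (NaN when undefined).
    """
    flat = network.flatten()
    kf = flat.degrees()
    kt = network.total_degrees()
    t_unique, t_pure = triangle_census(network)
    p = alter_tie_pairs(network)
    lcc = local_clustering(network)
    denom = p - t_pure
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, (t_unique - t_pure) / denom, np.nan)
    return pd.DataFrame(
        {
            "person_id": network.vertices,
            "k_flat": kf,
            "k_total": kt,
            "lcc": lcc,
            "lcc_defined": kf >= 2,
            "T_unique": t_unique,
            "T_pure": t_pure,
            "P": p,
            "c_excess": c,
        }
    )


def closure_by_degree(network: MultilayerNetwork | pd.DataFrame) -> pd.DataFrame:
    """Mean and quartiles of lcc and excess closure per flattened degree.

    Accepts a network or a precomputed :func:`closure_profiles` frame.
    Degrees with no vertices are absent; the excess-closure statistics use
    only vertices where it is defined.
    """
    prof = network if isinstance(network, pd.DataFrame) else closure_profiles(network)
    rows = []
    for k, grp in prof.groupby("k_flat", sort=True):
        ce = grp["c_excess"].dropna()
        rows.append(
            {
                "k_flat": int(k),
                "n": len(grp),
                "lcc_mean": grp["lcc"].mean(),
                "lcc_q25": grp["lcc"].quantile(0.25),
                "lcc_q75": grp["lcc"].quantile(0.75),
                "c_excess_mean": ce.mean() if len(ce) else np.nan,
                "c_excess_q25": ce.quantile(0.25) if len(ce) else np.nan,
                "c_excess_q75": ce.quantile(0.75) if len(ce) else np.nan,
                "n_excess_defined": int(len(ce)),
            }
        )
    return pd.DataFrame(rows)
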