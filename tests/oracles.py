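"""Independent brute-force oracles for the multilayer measures.

Everything here works on a plain ``dict[layer] -> set of frozenset dyads``
representation and enumerates exhaustively — no shared code with the
package implementation under test.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx

Layers = dict[str, set[frozenset]]


def neighbors(layers: Layers, u, layer=None) -> set:
    out = set()
    for l, edges in layers.items():
        if layer is not None and l != layer:
            continue
        for e in edges:
            if u in e:
                out |= e - {u}
    return out


def layer_degree(layers: Layers, u, layer) -> int:
    return sum(1 for e in layers[layer] if u in e)


def total_degree(layers: Layers, u) -> int:
    return sum(layer_degree(layers, u, l) for l in layers)


def unique_neighbors(layers: Layers, u) -> int:
    return len(neighbors(layers, u))


def multiplicity(layers: Layers, u, v) -> int:
    return sum(1 for edges in layers.values() if frozenset((u, v)) in edges)


def embeddedness(layers: Layers, vertices, u, v) -> int:
    """Sum over layer pairs and third vertices of A[u,w,l1] * A[v,w,l2]."""
    total = 0
    for l1 in layers:
        for l2 in layers:
            for w in vertices:
                if w in (u, v):
                    continue
                a_uw = 1 if frozenset((u, w)) in layers[l1] else 0
                a_vw = 1 if frozenset((v, w)) in layers[l2] else 0
                total += a_uw * a_vw
    return total


def alter_tie_pairs(layers: Layers, u) -> int:
    k = total_degree(layers, u)
    same = sum(comb(multiplicity(layers, u, v), 2) for v in neighbors(layers, u))
    return comb(k, 2) - same


def flat_graph(layers: Layers, vertices) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(vertices)
    for edges in layers.values():
        for e in edges:
            u, v = tuple(e)
            g.add_edge(u, v)
    return g


def triangle_census(layers: Layers, vertices, u) -> tuple[int, int]:
    """(T_unique, T_pure) over distinct vertex triples at u."""
    nb = neighbors(layers, u)
    t_unique = 0
    t_pure = 0
    for v, w in itertools.combinations(sorted(nb), 2):
        if not any(frozenset((v, w)) in edges for edges in layers.values()):
            continue
        t_unique += 1
        for edges in layers.values():
            if (
                frozenset((u, v)) in edges
                and frozenset((u, w)) in edges
                and frozenset((v, w)) in edges
            ):
                t_pure += 1
                break
    return t_unique, t_pure


def local_clustering(layers: Layers, vertices, u) -> float:
    k = unique_neighbors(layers, u)
    if k < 2:
        return 0.0
    t, _ = triangle_census(layers, vertices, u)
    return 2.0 * t / (k * (k - 1))


def excess_closure(layers: Layers, vertices, u) -> float | None:
    t_unique, t_pure = triangle_census(layers, vertices, u)
    p = alter_tie_pairs(layers, u)
    if p <= t_pure:
        return None
    return (t_unique - t_pure) / (p - t_pure)


def tie_range(layers: Layers, vertices, u, v) -> int | None:
    """Second-shortest path: shortest path after deleting the (u, v) edge."""
    g = flat_graph(layers, vertices)
    g.remove_edge(u, v)
    try:
        return nx.shortest_path_length(g, u, v)
    except nx.NetworkXNoPath:
        return None


def components_union_find(vertices, edge_list) -> list[set]:
    """Hand-coded disjoint-set partition (isolates are singletons)."""
    parent = {v: v for v in vertices}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edge_list:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict = {}
    for v in vertices:
        groups.setdefault(find(v), set()).add(v)
    return sorted(groups.values(), key=lambda s: (-len(s), min(s)))


def pedigree_relations(parent_pairs, partner_pairs):
    """Hand-coded kinship enumeration from explicit (parent, child) and
    partner pairs: grandparents, uncles/aunts (incl. by marriage), cousins.
    """
    parents: dict = {}
    for p, c in parent_pairs:
        parents.setdefault(c, set()).add(p)
    children: dict = {}
    for p, c in parent_pairs:
        children.setdefault(p, set()).add(c)
    partner: dict = {}
    for a, b in partner_pairs:
        partner.setdefault(a, set()).add(b)
        partner.setdefault(b, set()).add(a)

    def siblings(x):
        out = set()
        for p in parents.get(x, ()):  # share at least one parent
            out |= children.get(p, set())
        out.discard(x)
        return out

    grand = set()
    uncle = set()
    cousin = set()
    for c, ps in parents.items():
        for p in ps:
            for g in parents.get(p, ()):
                grand.add(frozenset((g, c)))
            for s in siblings(p):
                if s not in ps:
                    uncle.add(frozenset((s, c)))
                for t in partner.get(s, ()):
                    if t not in ps:
                        uncle.add(frozenset((t, c)))
                for c2 in children.get(s, ()):
                    if c2 != c:
                        cousin.add(frozenset((c, c2)))
    return grand, uncle, cousin
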