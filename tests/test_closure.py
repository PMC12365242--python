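"""Embeddedness, tie range, wormholes, triangle census and excess closure."""

import numpy as np
import pandas as pd
import pytest

import oracles
from conftest import random_multilayer
from popnet.closure import (
    alter_tie_pairs,
    bridge_records,
    closure_by_degree,
    closure_profiles,
    edge_embeddedness,
    excess_closure,
    local_clustering,
    tie_range,
    triangle_census,
    wormhole_census,
)
from popnet.network import MultilayerNetwork


def net_of(layer_dict, n):
    return MultilayerNetwork(
        range(n),
        {l: sorted(map(tuple, map(sorted, es))) for l, es in layer_dict.items()},
        layers=tuple(layer_dict),
    )


class TestEmbeddedness:
    def test_single_layer_triangle(self):
        net = net_of({"A": [(0, 1), (1, 2), (0, 2)]}, 3)
        for u, v in [(0, 1), (1, 2), (0, 2)]:
            assert edge_embeddedness(net, u, v) == 1

    def test_layer_multiplicity_multiplies(self):
        # u-w in two layers, v-w in one: 2 * 1 = 2
        net = net_of({"C": [(0, 1), (0, 2), (1, 2)], "H": [(0, 2)]}, 3)
        assert edge_embeddedness(net, 0, 1) == 2

    def test_path_edge_zero(self):
        net = net_of({"A": [(0, 1), (1, 2)]}, 3)
        assert edge_embeddedness(net, 0, 1) == 0

    def test_non_edge_rejected(self):
        net = net_of({"A": [(0, 1), (1, 2)]}, 3)
        with pytest.raises(ValueError):
            edge_embeddedness(net, 0, 2)


class TestTieRange:
    def test_four_cycle_edge(self):
        net = net_of({"A": [(0, 1), (1, 2), (2, 3), (3, 0)]}, 4)
        assert tie_range(net, 0, 1) == 3

    def test_bridge_unreachable(self):
        net = net_of({"A": [(0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 5), (5, 3)]}, 6)
        assert tie_range(net, 2, 3) is None

    def test_embedded_edge_rejected(self):
        net = net_of({"A": [(0, 1), (1, 2), (0, 2)]}, 3)
        with pytest.raises(ValueError):
            tie_range(net, 0, 1)

    def test_beyond_max_depth_unreachable(self):
        cycle = [(i, (i + 1) % 40) for i in range(40)]
        net = net_of({"A": cycle}, 40)
        assert tie_range(net, 0, 1, max_depth=40) == 39
        assert tie_range(net, 0, 1) is None  # default depth cap is 15

    @pytest.mark.parametrize("seed", [61, 62, 63])
    def test_matches_shortest_path_oracle(self, seed):
        import oracles as orc
        layers, vertices, net = random_multilayer(seed, n_max=25)
        rec = bridge_records(net, max_depth=50)
        for r in rec.itertuples():
            expected = orc.tie_range(layers, vertices, int(r.u), int(r.v))
            got = None if pd.isna(r.tie_range) else int(r.tie_range)
            assert got == expected


class TestWormholes:
    def test_clique_has_none(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        net = net_of({"A": edges}, 5)
        census = wormhole_census(net)
        assert census.n_zero_embedded == 0
        assert census.n_wormholes == 0

    def test_constructed_shortcut_is_the_only_wormhole(self):
        # a chain of seven vertex-sharing triangles (every triangle edge is
        # embedded) closed by one distant shortcut of tie range 7, plus two
        # cliques joined by one bridge -- the bridge disconnects on removal
        # and must not count as a wormhole
        triangles = []
        for t in range(7):
            a = 2 * t
            triangles += [(a, a + 1), (a + 1, a + 2), (a, a + 2)]
        shortcut = [(0, 14)]
        k1 = [(i, j) for i in range(20, 25) for j in range(i + 1, 25)]
        k2 = [(i, j) for i in range(25, 30) for j in range(i + 1, 30)]
        bridge = [(24, 25)]
        net = net_of({"A": triangles + shortcut + k1 + k2 + bridge}, 30)
        rec = bridge_records(net)
        by_edge = {(r.u, r.v): r for r in rec.itertuples()}
        assert by_edge[(0, 14)].tie_range == 7
        census = wormhole_census(net)
        assert census.n_wormholes == 1
        assert census.n_unreachable == 1  # the clique-joining bridge

    def test_wormholes_bounded_by_zero_embedded(self):
        _, _, net = random_multilayer(41)
        census = wormhole_census(net)
        assert census.n_wormholes <= census.n_zero_embedded


class TestTriangleCensusAndClosure:
    def test_pure_triangle_single_layer(self):
        net = net_of({"C": [(0, 1), (1, 2), (0, 2)]}, 3)
        assert triangle_census(net, 0) == (1, 1)

    def test_mixed_layer_triangle_not_pure(self):
        net = net_of({"C": [(0, 1), (1, 2)], "H": [(0, 2)]}, 3)
        assert triangle_census(net, 0) == (1, 0)

    def test_triangle_pure_in_two_layers_counted_once(self):
        tri = [(0, 1), (1, 2), (0, 2)]
        net = net_of({"C": tri, "H": tri}, 3)
        assert triangle_census(net, 0) == (1, 1)

    def test_alter_tie_pairs_expands_formula(self):
        # u-v in C and H, u-w in C: C(3,2) - C(2,2) - C(1,2) = 2
        net = net_of({"C": [(0, 1), (0, 2)], "H": [(0, 1)]}, 3)
        assert alter_tie_pairs(net, 0) == 2

    def test_single_tie_no_pairs(self):
        net = net_of({"C": [(0, 1)]}, 2)
        assert alter_tie_pairs(net, 0) == 0

    def test_all_single_layer_ties_give_binomial(self):
        net = net_of({"C": [(0, 1), (0, 2), (0, 3)]}, 4)
        assert alter_tie_pairs(net, 0) == 3  # C(3, 2)

    def test_local_clustering_extremes(self):
        tri = net_of({"C": [(0, 1), (1, 2), (0, 2)]}, 3)
        assert local_clustering(tri, 0) == pytest.approx(1.0)
        star = net_of({"C": [(0, 1), (0, 2), (0, 3)]}, 4)
        assert local_clustering(star, 0) == pytest.approx(0.0)
        # undefined for degree < 2, reported as 0
        pair = net_of({"C": [(0, 1)]}, 2)
        assert local_clustering(pair, 0) == 0.0

    def test_excess_closure_unit_case(self):
        # ties u-v (C), u-w (H), v-w (C): T_unique=1, T_pure=0, P=1 -> 1.0
        net = net_of({"C": [(0, 1), (1, 2)], "H": [(0, 2)]}, 3)
        assert excess_closure(net, 0) == pytest.approx(1.0)

    def test_excess_closure_pure_triangles_zero(self):
        net = net_of({"C": [(0, 1), (1, 2), (0, 2), (0, 3), (3, 4), (0, 4)]}, 5)
        assert excess_closure(net, 0) == pytest.approx(0.0)

    def test_excess_closure_star_zero(self):
        net = net_of({"C": [(0, 1), (0, 2), (0, 3)]}, 4)
        assert excess_closure(net, 0) == pytest.approx(0.0)

    def test_excess_closure_undefined_when_saturated(self):
        # one triangle in one layer: P = 1 = T_pure -> undefined
        net = net_of({"C": [(0, 1), (1, 2), (0, 2)]}, 3)
        assert np.isnan(excess_closure(net, 0))

    def test_multiplicity_semantics_available(self):
        tri = [(0, 1), (1, 2), (0, 2)]
        net = net_of({"C": tri, "H": tri}, 3)
        t_unique, t_pure = triangle_census(net, 0, semantics="multiplicity")
        assert t_unique == 8  # 2^3 layer assignments
        assert t_pure == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [101, 102, 103, 104, 105])
    def test_closure_bundle_matches_brute_force(self, seed):
        layers, vertices, net = random_multilayer(seed, n_max=30)
        prof = closure_profiles(net).set_index("person_id")
        for u in vertices:
            t_u, t_p = oracles.triangle_census(layers, vertices, u)
            assert prof.loc[u, "T_unique"] == t_u
            assert prof.loc[u, "T_pure"] == t_p
            assert prof.loc[u, "P"] == oracles.alter_tie_pairs(layers, u)
            assert prof.loc[u, "lcc"] == pytest.approx(
                oracles.local_clustering(layers, vertices, u)
            )
            expected = oracles.excess_closure(layers, vertices, u)
            got = prof.loc[u, "c_excess"]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_triangle_sum_identity(self):
        _, _, net = random_multilayer(55)
        t_unique, _ = triangle_census(net)
        b = net.flatten().adjacency
        paths = (b @ b).multiply(b)
        n_triangles = int(paths.sum()) // 6
        assert t_unique.sum() == 3 * n_triangles


class TestClosureByDegree:
    def test_clique_network_all_ones(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        net = net_of({"A": edges}, 5)
        table = closure_by_degree(net)
        assert (table["lcc_mean"] == 1.0).all()

    def test_empty_degree_bins_absent(self):
        net = net_of({"A": [(0, 1), (1, 2), (0, 2), (3, 4)]}, 5)
        table = closure_by_degree(net)
        assert set(table["k_flat"]) == {1, 2}
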