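"""Layer builders: kinship inference, household cliques, affiliation
grouping and degree-targeted edge sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popnet.layers import (
    ExpectedDegree,
    build_close_family,
    build_extended_family,
    build_household,
    build_neighbors,
    build_school,
    build_work,
    expected_degree,
    sample_group_edges,
)

from conftest import registry_frame


def edge_set(df):
    return set(zip(df["u"], df["v"]))


def subtype_of(df, a, b):
    u, v = min(a, b), max(a, b)
    row = df[(df["u"] == u) & (df["v"] == v)]
    return row["subtype"].iloc[0] if len(row) else None


class TestCloseFamily:
    def test_partner_and_parent_child_from_age_gaps(self):
        # family {A born 1960, B born 1962, K born 1990}
        rows = [
            {"person_id": i, "year": 2017, "birth_year": b, "family_id": 0,
             "household_id": 0}
            for i, b in [(0, 1960), (1, 1962), (2, 1990)]
        ]
        c = build_close_family(registry_frame(rows), 2017)
        assert subtype_of(c, 0, 1) == "partner"
        assert subtype_of(c, 0, 2) == "parent_child"
        assert subtype_of(c, 1, 2) == "parent_child"
        assert len(c) == 3

    def test_no_family_id_means_no_edges(self):
        rows = [
            {"person_id": 0, "year": 2017, "birth_year": 1970},
            {"person_id": 1, "year": 2017, "birth_year": 1972, "family_id": 1,
             "household_id": 1},
        ]
        c = build_close_family(registry_frame(rows), 2017)
        assert len(c) == 0  # the singleton family has no dyads either

    def test_siblings_via_shared_parent_despite_large_gap(self):
        # children born 16 years apart still siblings through the parent
        rows = [
            {"person_id": i, "year": 2017, "birth_year": b, "family_id": 0,
             "household_id": 0}
            for i, b in [(0, 1955), (1, 1980), (2, 1996)]
        ]
        c = build_close_family(registry_frame(rows), 2017)
        assert subtype_of(c, 1, 2) == "sibling"
        assert subtype_of(c, 0, 1) == "parent_child"
        assert subtype_of(c, 0, 2) == "parent_child"

    def test_cross_year_aggregation_restricted_to_analysis_year(self):
        # co-residence in 2000 creates the tie; a person absent in 2017
        # is excluded from the layer
        rows = [
            {"person_id": 0, "year": 2000, "birth_year": 1950, "family_id": 0,
             "household_id": 0},
            {"person_id": 1, "year": 2000, "birth_year": 1980, "family_id": 0,
             "household_id": 0},
            {"person_id": 2, "year": 2000, "birth_year": 1982, "family_id": 0,
             "household_id": 0},
            {"person_id": 0, "year": 2017, "birth_year": 1950},
            {"person_id": 1, "year": 2017, "birth_year": 1980},
        ]
        c = build_close_family(registry_frame(rows), 2017)
        assert edge_set(c) == {(0, 1)}
        assert subtype_of(c, 0, 1) == "parent_child"

    def test_analysis_year_outside_panel_errors(self):
        rows = [{"person_id": 0, "year": 2017, "birth_year": 1950}]
        with pytest.raises(ValueError):
            build_close_family(registry_frame(rows), 1999)


class TestExtendedFamily:
    def test_grandparent_is_parent_of_parent(self):
        rows = [
            {"person_id": 0, "year": 2000, "birth_year": 1940, "family_id": 0,
             "household_id": 0},
            {"person_id": 1, "year": 2000, "birth_year": 1965, "family_id": 0,
             "household_id": 0},
            {"person_id": 1, "year": 2017, "birth_year": 1965, "family_id": 1,
             "household_id": 1},
            {"person_id": 2, "year": 2017, "birth_year": 1990, "family_id": 1,
             "household_id": 1},
            {"person_id": 0, "year": 2017, "birth_year": 1940},
        ]
        c = build_close_family(registry_frame(rows), 2017)
        e = build_extended_family(c)
        assert edge_set(e) == {(0, 2)}
        assert e["subtype"].iloc[0] == "grandparent"

    def test_no_parents_no_extended_family(self):
        rows = [
            {"person_id": i, "year": 2017, "birth_year": 1960 + i,
             "family_id": 0, "household_id": 0}
            for i in range(2)
        ]
        c = build_close_family(registry_frame(rows), 2017)
        assert set(c["subtype"]) == {"partner"}
        assert len(build_extended_family(c)) == 0

    def test_missing_orientation_errors(self):
        bad = pd.DataFrame({"u": [0], "v": [1], "subtype": ["parent_child"]})
        with pytest.raises(ValueError):
            build_extended_family(bad)


class TestHousehold:
    def _rows(self, households):
        rows = []
        pid = 0
        for hh, size in enumerate(households):
            for _ in range(size):
                rows.append(
                    {"person_id": pid, "year": 2017, "birth_year": 1980,
                     "family_id": hh, "household_id": hh}
                )
                pid += 1
        return registry_frame(rows)

    def test_household_of_three_is_triangle(self):
        h = build_household(self._rows([3]), 2017)
        assert len(h) == 3

    def test_single_person_household_no_edges(self):
        h = build_household(self._rows([1]), 2017)
        assert len(h) == 0

    def test_clique_sizes_sum(self):
        # households of sizes 2 and 4 -> 1 + 6 edges
        h = build_household(self._rows([2, 4]), 2017)
        assert len(h) == 7

    def test_close_family_edges_of_coresidents_also_in_household(self):
        # partner/parent ties within one co-resident family household
        rows = [
            {"person_id": i, "year": 2017, "birth_year": b, "family_id": 0,
             "household_id": 0}
            for i, b in [(0, 1960), (1, 1962), (2, 1992)]
        ]
        reg = registry_frame(rows)
        c = build_close_family(reg, 2017)
        h = build_household(reg, 2017)
        assert edge_set(c) <= edge_set(h)


def affiliation_rows(groups, column):
    """Rows with persons assigned to affiliation groups via ``column``."""
    rows = []
    pid = 0
    for gid, size in enumerate(groups):
        for _ in range(size):
            r = {"person_id": pid, "year": 2017, "birth_year": 1980}
            if column == "school":
                r.update({"education_level": 3, "municipality": gid,
                          "graduation_year": 1999})
            elif column == "property":
                r.update({"property_id": gid})
            else:
                r.update({"company_id": gid, "workplace_id": gid})
            rows.append(r)
            pid += 1
    return registry_frame(rows)


class TestSchool:
    def test_pair_connected(self):
        s = build_school(affiliation_rows([2], "school"), 2017,
                         np.random.default_rng(0))
        assert len(s) == 1

    def test_group_above_cap_emits_nothing(self):
        # a single (level, municipality, year, field) group of 12,000
        rows = [
            {"person_id": i, "year": 2017, "birth_year": 1980,
             "education_level": 5, "municipality": 0, "graduation_year": 2005,
             "field_of_study": 1}
            for i in range(12_000)
        ]
        s = build_school(registry_frame(rows), 2017, np.random.default_rng(0))
        assert len(s) == 0

    def test_field_split_isolates_fields(self):
        # 1,500 graduates, three fields of 500: no cross-field edges
        rows = [
            {"person_id": i, "year": 2017, "birth_year": 1980,
             "education_level": 5, "municipality": 0, "graduation_year": 2005,
             "field_of_study": i % 3}
            for i in range(1_500)
        ]
        reg = registry_frame(rows)
        s = build_school(reg, 2017, np.random.default_rng(0))
        assert len(s) > 0
        field = dict(zip(reg["person_id"], reg["field_of_study"]))
        assert all(field[u] == field[v] for u, v in edge_set(s))


class TestNeighbors:
    def test_pair_and_loner(self):
        reg = affiliation_rows([2, 1], "property")
        n = build_neighbors(reg, 2017, np.random.default_rng(0))
        assert edge_set(n) == {(0, 1)}

    def test_small_property_clique_large_property_sampled(self):
        reg = affiliation_rows([3, 60], "property")
        n = build_neighbors(reg, 2017, np.random.default_rng(0))
        small = [e for e in edge_set(n) if e[0] < 3 and e[1] < 3]
        assert len(small) == 3  # rural triple fully connected
        big = [e for e in edge_set(n) if e[0] >= 3]
        target = expected_degree(60) * 60 / 2
        assert abs(len(big) - target) / target < 0.35  # one draw, loose band


class TestWork:
    def test_small_company_clique(self):
        w = build_work(affiliation_rows([5], "work"), 2017,
                       np.random.default_rng(0))
        assert len(w) == 10

    def test_large_company_split_by_workplace(self):
        rows = [
            {"person_id": i, "year": 2017, "birth_year": 1980,
             "company_id": 0, "workplace_id": i % 4}
            for i in range(1_000)
        ]
        reg = registry_frame(rows)
        w = build_work(reg, 2017, np.random.default_rng(0))
        assert len(w) > 0
        wp = dict(zip(reg["person_id"], reg["workplace_id"]))
        assert all(wp[u] == wp[v] for u, v in edge_set(w))

    def test_unemployed_person_isolated(self):
        rows = [
            {"person_id": 0, "year": 2017, "birth_year": 1980},
            {"person_id": 1, "year": 2017, "birth_year": 1980, "company_id": 0},
            {"person_id": 2, "year": 2017, "birth_year": 1980, "company_id": 0},
        ]
        w = build_work(registry_frame(rows), 2017, np.random.default_rng(0))
        assert 0 not in {p for e in edge_set(w) for p in e}


class TestExpectedDegree:
    def test_cap_at_group_size_minus_one(self):
        assert expected_degree(2) == 1

    def test_continuous_at_break(self):
        f = ExpectedDegree(a=1.0, b=0.55, s_break=200.0)
        lo = f(200.0)
        hi = f(200.0 + 1e-9)
        assert abs(lo - hi) < 1e-6

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            expected_degree(1)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.3, max_value=0.95),
           st.floats(min_value=50, max_value=500))
    def test_monotone_nondecreasing(self, b, s_break):
        f = ExpectedDegree(a=1.0, b=b, s_break=s_break)
        sizes = np.arange(2, 10_001, 37)
        vals = [f(s) for s in sizes]
        assert all(y >= x - 1e-12 for x, y in zip(vals, vals[1:]))


class TestSampleGroupEdges:
    def test_same_seed_same_edges(self):
        ids = np.arange(200)
        a = sample_group_edges(ids, np.random.default_rng(99))
        b = sample_group_edges(ids, np.random.default_rng(99))
        pd.testing.assert_frame_equal(a, b)

    def test_saturated_targets_build_clique(self):
        ids = np.arange(12)
        df = sample_group_edges(
            ids, np.random.default_rng(0),
            targets=np.full(12, 11), max_rounds=400,
        )
        assert len(df) == 12 * 11 // 2

    def test_infeasible_targets_clamped(self, caplog):
        ids = np.arange(10)
        with caplog.at_level("WARNING"):
            df = sample_group_edges(ids, np.random.default_rng(0),
                                    targets=np.full(10, 50), max_rounds=400)
        assert "clamping" in caplog.text
        assert len(df) <= 45

    def test_mean_degree_tracks_target(self):
        # group of 1,000 with target degree 20: realized mean within 10%
        ids = np.arange(1_000)
        means = []
        for seed in range(10):
            df = sample_group_edges(
                ids, np.random.default_rng(seed),
                expected_degree_fn=lambda s: 20.0,
            )
            means.append(2 * len(df) / 1_000)
        assert 18.0 <= np.mean(means) <= 22.0

    def test_no_self_loops_or_duplicates(self):
        df = sample_group_edges(np.arange(300), np.random.default_rng(7))
        assert (df["u"] != df["v"]).all()
        assert not df.duplicated(["u", "v"]).any()
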