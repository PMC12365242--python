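"""Shared fixtures: random multilayer instances and a toy pedigree panel."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from popnet.network import MultilayerNetwork
from popnet.registry import SCHEMA, _DTYPES


def random_multilayer(seed: int, n_max: int = 50, n_layers: int = 3):
    """A random multilayer instance: returns (layers_dict, vertices, net).

    Vertices 0..n-1; per-layer edge density uniform in [0.05, 0.3].
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, n_max + 1))
    vertices = list(range(n))
    names = [f"L{i}" for i in range(n_layers)]
    layers: dict[str, set[frozenset]] = {}
    all_pairs = list(itertools.combinations(vertices, 2))
    for name in names:
        density = rng.uniform(0.05, 0.3)
        mask = rng.random(len(all_pairs)) < density
        layers[name] = {frozenset(p) for p, m in zip(all_pairs, mask) if m}
    net = MultilayerNetwork(
        vertices,
        {name: [tuple(sorted(e)) for e in sorted(map(sorted, layers[name]))]
         for name in names},
        layers=names,
    )
    return layers, vertices, net


@pytest.fixture
def small_random_net():
    return random_multilayer(12345)


def registry_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a schema-complete register frame from sparse row dicts."""
    defaults = {
        "family_id": pd.NA,
        "household_id": pd.NA,
        "property_id": pd.NA,
        "municipality": 0,
        "education_level": 1,
        "field_of_study": pd.NA,
        "graduation_year": pd.NA,
        "company_id": pd.NA,
        "workplace_id": pd.NA,
        "income_band": 1,
        "urbanization_level": 1,
        "immigrant_without_family": False,
    }
    full = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(full)
    for c in SCHEMA:
        df[c] = df[c].astype(_DTYPES[c])
    return df[SCHEMA]


# three-generation, two-branch pedigree:
#   grandparents A, B; their children C1, C2; partners D1, D2;
#   grandchildren K1 (of C1/D1) and K2 (of C2/D2)
PEDIGREE_BIRTH = {
    "A": 1945, "B": 1947,
    "C1": 1972, "C2": 1975,
    "D1": 1973, "D2": 1976,
    "K1": 1998, "K2": 2000,
}
PEDIGREE_IDS = {name: i for i, name in enumerate(PEDIGREE_BIRTH)}


@pytest.fixture
def pedigree_registry() -> pd.DataFrame:
    """Person-year panel realizing the pedigree through co-residence:
    C1/C2 share the grandparents' family in 2000; each branch family is
    co-resident in 2017."""
    ids, birth = PEDIGREE_IDS, PEDIGREE_BIRTH

    def row(name, year, fam):
        return {
            "person_id": ids[name],
            "year": year,
            "birth_year": birth[name],
            "family_id": fam,
            "household_id": fam,
        }

    rows = [row(n, 2000, 0) for n in ("A", "B", "C1", "C2")]
    for n in ("A", "B"):
        rows.append(row(n, 2017, 0))
    for n in ("C1", "D1", "K1"):
        rows.append(row(n, 2017, 1))
    for n in ("C2", "D2", "K2"):
        rows.append(row(n, 2017, 2))
    return registry_frame(rows)
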