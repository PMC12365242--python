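"""Synthetic person-year register panels.

Emulates the structure of a Nordic-style administrative register (one row
per person per year, ages 15+): family/household identifiers, a property
identifier for co-residence, education (level, municipality, graduation
year, field of study), main employment (company, workplace), and banded
sociodemographics.  The generator reproduces the *structural* features the
layer builders depend on — single-person households, children co-residing
with parents until a sampled move-out age, cross-generation family links
only where the panel window overlaps the co-residence years, immigrants
without any family identifier, multi-modal property sizes, and a
heavy-tailed firm-size distribution — without attempting demographic
calibration to any real country.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA",
    "GeneratorConfig",
    "RegistryConfigError",
    "RegistryFormatError",
    "generate_population",
    "read_registry",
    "write_registry",
    "validate_registry",
    "analysis_year_frame",
]

#: Column order of a person-year register row.
SCHEMA = [
    "person_id",
    "year",
    "birth_year",
    "family_id",
    "household_id",
    "property_id",
    "municipality",
    "education_level",
    "field_of_study",
    "graduation_year",
    "company_id",
    "workplace_id",
    "income_band",
    "urbanization_level",
    "immigrant_without_family",
]

_NULLABLE = [
    "family_id",
    "household_id",
    "property_id",
    "field_of_study",
    "graduation_year",
    "company_id",
    "workplace_id",
]

_DTYPES = {c: ("Int64" if c in _NULLABLE else "int64") for c in SCHEMA}
_DTYPES["immigrant_without_family"] = "bool"


class RegistryConfigError(ValueError):
    """Invalid generator configuration."""


class RegistryFormatError(ValueError):
    """A register file violates the person-year schema."""


def _check_pmf(name: str, pmf: Mapping[int, float]) -> None:
    if not pmf:
        raise RegistryConfigError(f"{name} is empty")
    total = float(sum(pmf.values()))
    if abs(total - 1.0) > 1e-9:
        raise RegistryConfigError(f"{name} sums to {total!r}, expected 1")
    if any(p < 0 for p in pmf.values()):
        raise RegistryConfigError(f"{name} has negative mass")


@dataclass(frozen=True)
class PropertyComponent:
    """One mode of the property-size mixture (households per property)."""

    name: str
    weight: float
    min_households: int
    max_households: int
    urbanization: int  # ordinal 1 (rural) .. 5 (metropolitan)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic register generator.

    Household sizes count only persons aged 15+, because younger persons
    never appear in the register.  ``single_person_household_share``, when
    set, overrides the mass that ``household_size_pmf`` puts on size 1.
    """

    population_size: int = 10_000
    year_range: tuple[int, int] = (2000, 2017)
    rng_seed: int = 0
    household_size_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.40, 2: 0.31, 3: 0.12, 4: 0.11, 5: 0.04, 6: 0.02}
    )
    single_person_household_share: float | None = None
    property_size_mixture: tuple[PropertyComponent, ...] = (
        PropertyComponent("rural", 0.35, 1, 2, 1),
        PropertyComponent("town", 0.30, 3, 12, 3),
        PropertyComponent("urban_block", 0.25, 12, 60, 4),
        PropertyComponent("large_complex", 0.10, 60, 180, 5),
    )
    school_group_size_pmf: dict[int, float] = field(
        default_factory=lambda: {10: 0.2, 20: 0.4, 30: 0.3, 60: 0.1}
    )
    firm_size_pmf: dict[int, float] = field(
        default_factory=lambda: {
            2: 0.30,
            5: 0.25,
            12: 0.18,
            30: 0.12,
            80: 0.08,
            200: 0.04,
            500: 0.02,
            1500: 0.01,
        }
    )
    immigrant_share: float = 0.08
    moveout_age_pmf: dict[int, float] = field(
        default_factory=lambda: {
            18: 0.06,
            19: 0.12,
            20: 0.16,
            21: 0.16,
            22: 0.14,
            23: 0.12,
            24: 0.09,
            25: 0.07,
            26: 0.04,
            27: 0.02,
            28: 0.02,
        }
    )
    #: probability that an adult householder is linked back to a parent
    #: household generated in the same run (the cross-generation wiring
    #: behind the extended-family layer).
    lineage_link_prob: float = 0.7
    education_level_pmf: dict[int, float] = field(
        default_factory=lambda: {1: 0.05, 2: 0.10, 3: 0.25, 4: 0.15, 5: 0.20, 6: 0.18, 7: 0.07}
    )
    employment_rate: float = 0.85

    def validate(self) -> None:
        if self.population_size < 0:
            raise RegistryConfigError("population_size must be >= 0")
        y0, y1 = self.year_range
        if y1 < y0:
            raise RegistryConfigError("empty year_range")
        for name in (
            "household_size_pmf",
            "school_group_size_pmf",
            "firm_size_pmf",
            "moveout_age_pmf",
            "education_level_pmf",
        ):
            _check_pmf(name, getattr(self, name))
        if self.single_person_household_share is not None and not (
            0.0 <= self.single_person_household_share <= 1.0
        ):
            raise RegistryConfigError("single_person_household_share outside [0, 1]")
        if not 0.0 <= self.immigrant_share <= 1.0:
            raise RegistryConfigError("immigrant_share outside [0, 1]")
        w = sum(c.weight for c in self.property_size_mixture)
        if abs(w - 1.0) > 1e-9:
            raise RegistryConfigError("property_size_mixture weights must sum to 1")

    def effective_household_pmf(self) -> dict[int, float]:
        pmf = dict(self.household_size_pmf)
        if self.single_person_household_share is None:
            return pmf
        s = self.single_person_household_share
        rest = {k: v for k, v in pmf.items() if k != 1}
        rest_total = sum(rest.values())
        out = {1: s}
        if rest_total > 0 and s < 1.0:
            out.update({k: v * (1 - s) / rest_total for k, v in rest.items()})
        return out


def _draw_pmf(rng: np.random.Generator, pmf: Mapping[int, float], size: int) -> np.ndarray:
    keys = np.array(sorted(pmf))
    probs = np.array([pmf[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=size, p=probs)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a person-year panel as a DataFrame with columns ``SCHEMA``.

    Deterministic given ``config.rng_seed``.  Every person has a row in the
    final year of ``year_range``; earlier rows run from the year the person
    turns 15 (or the panel start).  Family and household identifiers follow
    the person's co-residence history: at-home children and lineage-linked
    adults carry their parents' identifiers before the sampled move-out age.
    """
    config.validate()
    n = config.population_size
    if n == 0:
        return _empty_frame()
    rng = np.random.default_rng(config.rng_seed)
    first_year, final_year = config.year_range

    # ---- person and household scaffolding (final-year cross-section) ----
    n_imm = int(round(config.immigrant_share * n))
    n_house = n - n_imm

    pmf = config.effective_household_pmf()
    sizes: list[int] = []
    remaining = n_house
    while remaining > 0:
        k = int(_draw_pmf(rng, pmf, 1)[0])
        k = min(k, remaining)
        sizes.append(k)
        remaining -= k

    # per-person arrays
    age = np.empty(n, dtype=np.int64)
    household = np.full(n, -1, dtype=np.int64)
    role_child = np.zeros(n, dtype=bool)  # at-home child in the final year
    immigrant = np.zeros(n, dtype=bool)

    hh_members: list[list[int]] = []
    pid = 0
    for hh_id, k in enumerate(sizes):
        members = list(range(pid, pid + k))
        pid += k
        hh_members.append(members)
        for m in members:
            household[m] = hh_id
        if k == 1:
            if rng.random() < 0.5:
                age[members[0]] = rng.integers(18, 36)
            else:
                age[members[0]] = rng.integers(36, 91)
        elif k == 2 and rng.random() < 0.15:
            # single parent + teen child
            child, parent = members
            age[child] = rng.integers(15, 20)
            age[parent] = age[child] + rng.integers(24, 37)
            role_child[child] = True
        else:
            base = int(rng.integers(24, 89)) if k == 2 else int(rng.integers(40, 63))
            age[members[0]] = base
            age[members[1]] = int(np.clip(base + rng.integers(-5, 6), 18, 95))
            for m in members[2:]:
                hi = min(24, base - 16)
                age[m] = rng.integers(15, max(16, hi + 1))
                role_child[m] = True
    next_hh = len(sizes)

    # immigrants without family: single persons, no family/household ids ever
    for i in range(n_imm):
        p = n_house + i
        immigrant[p] = True
        age[p] = rng.integers(18, 76)
        household[p] = -1
    age = np.clip(age, 15, 95)
    birth_year = final_year - age

    # ---- cross-generation lineage wiring ----
    # parent households: oldest member >= 45; their "parents" are the one or
    # two oldest non-child members.
    parent_of: dict[int, int] = {}  # person -> parent household id
    moveout: dict[int, int] = {}
    parent_hh_by_age: dict[int, list[int]] = {}
    hh_parents: dict[int, list[int]] = {}
    for hh_id, members in enumerate(hh_members):
        adults = [m for m in members if not role_child[m]]
        if not adults:
            continue
        adults.sort(key=lambda m: (-age[m], m))
        heads = adults[:2]
        hh_parents[hh_id] = heads
        a = int(age[heads[0]])
        if a >= 45:
            parent_hh_by_age.setdefault(a, []).append(hh_id)

    candidates = [
        m
        for members in hh_members
        for m in members
        if not role_child[m] and age[m] <= 42
    ]
    for m in candidates:
        if rng.random() >= config.lineage_link_prob:
            continue
        lo, hi = int(age[m]) + 22, int(age[m]) + 36
        pool = [h for a in range(lo, hi + 1) for h in parent_hh_by_age.get(a, [])]
        if not pool:
            continue
        hh = pool[int(rng.integers(len(pool)))]
        if m in hh_parents.get(hh, []):
            continue
        parent_of[m] = hh
        mo = int(_draw_pmf(rng, config.moveout_age_pmf, 1)[0])
        moveout[m] = min(mo, int(age[m]))

    # at-home children: move-out age still in the future
    for hh_id, members in enumerate(hh_members):
        for m in members:
            if role_child[m]:
                parent_of[m] = hh_id
                mo = int(_draw_pmf(rng, config.moveout_age_pmf, 1)[0])
                moveout[m] = max(mo, int(age[m]) + 1)

    # ---- properties, municipalities, urbanization ----
    # residential units: non-immigrant households plus immigrant singles
    units: list[list[int]] = list(hh_members)
    for i in range(n_imm):
        units.append([n_house + i])
    order = rng.permutation(len(units))
    comps = config.property_size_mixture
    comp_w = np.array([c.weight for c in comps])
    comp_w = comp_w / comp_w.sum()

    property_of = np.full(n, -1, dtype=np.int64)
    urban = np.full(n, 1, dtype=np.int64)
    prop_id = 0
    properties: list[int] = []  # component index per property
    i = 0
    while i < len(order):
        ci = int(rng.choice(len(comps), p=comp_w))
        c = comps[ci]
        take = int(rng.integers(c.min_households, c.max_households + 1))
        for u in order[i : i + take]:
            for m in units[u]:
                property_of[m] = prop_id
                urban[m] = c.urbanization
        properties.append(ci)
        prop_id += 1
        i += take

    mean_group = sum(k * v for k, v in config.school_group_size_pmf.items())
    n_muni = max(1, int(round(n / (320.0 * mean_group))))
    muni_of_prop = rng.integers(0, n_muni, size=prop_id)
    municipality = muni_of_prop[property_of]

    # ---- education ----
    edu = _draw_pmf(rng, config.education_level_pmf, n)
    # cap the attained level by age so graduation precedes the final year
    edu = np.minimum(edu, np.select([age < 19, age < 22, age < 25], [2, 4, 6], 7))
    grad_offset = np.select(
        [edu <= 2, edu <= 4, edu == 5, edu == 6], [16, 19, 22, 24], 28
    )
    grad_year = birth_year + grad_offset + rng.integers(-1, 3, size=n)
    grad_year = np.minimum(grad_year, final_year)
    has_field = edu >= 5
    study_field = np.where(has_field, rng.integers(0, 10, size=n), -1)

    # ---- income and employment ----
    hump = -((age - 50) / 30.0) ** 2
    score = 0.45 * edu + 2.0 * hump + rng.normal(0, 0.8, size=n)
    ranks = np.empty(n, dtype=np.int64)
    ranks[np.argsort(score, kind="stable")] = np.arange(n)
    income_band = (ranks * 5) // n + 1  # quintile bands 1..5

    working_age = (age >= 19) & (age <= 67)
    employed = working_age & (rng.random(n) < config.employment_rate)
    emp_idx = np.flatnonzero(employed)
    firm_sizes: list[int] = []
    capacity = 0
    while capacity < len(emp_idx):
        chunk = _draw_pmf(rng, config.firm_size_pmf, 64)
        firm_sizes.extend(int(s) for s in chunk)
        capacity += int(chunk.sum())
    firm_sizes_arr = np.array(firm_sizes, dtype=float)
    company = np.full(n, -1, dtype=np.int64)
    for band in range(1, 6):
        sel = emp_idx[income_band[emp_idx] == band]
        if len(sel) == 0:
            continue
        # higher bands preferentially join larger firms
        w = firm_sizes_arr ** (1.0 + 0.35 * (band - 3))
        company[sel] = rng.choice(len(firm_sizes_arr), size=len(sel), p=w / w.sum())
    # workplaces subdivide firms with >= 200 realized employees
    workplace = np.full(n, -1, dtype=np.int64)
    order_emp = emp_idx[np.argsort(company[emp_idx], kind="stable")]
    firms_sorted = company[order_emp]
    uniq_firms, starts = np.unique(firms_sorted, return_index=True)
    bounds = np.append(starts, len(order_emp))
    wp_id = 0
    for f in range(len(uniq_firms)):
        members = order_emp[bounds[f] : bounds[f + 1]]
        count = len(members)
        if count >= 200:
            n_wp = int(np.ceil(count / 150.0))
            workplace[members] = wp_id + rng.integers(0, n_wp, size=count)
            wp_id += n_wp
        else:
            workplace[members] = wp_id
            wp_id += 1

    # ---- expand to the person-year panel ----
    start = np.maximum(first_year, birth_year + 15)
    n_rows = (final_year - start + 1).astype(np.int64)
    person_idx = np.repeat(np.arange(n), n_rows)
    year = np.concatenate([np.arange(s, final_year + 1) for s in start])
    age_y = year - birth_year[person_idx]

    fam = household[person_idx].astype(np.float64)
    fam[immigrant[person_idx]] = np.nan
    # pre-move-out years: parents' household/family identifiers
    if parent_of:
        p_arr = np.full(n, -1, dtype=np.int64)
        m_arr = np.full(n, 10_000, dtype=np.int64)
        for m, hh in parent_of.items():
            p_arr[m] = hh
            m_arr[m] = moveout[m]
        linked = p_arr[person_idx] >= 0
        pre = linked & (age_y < m_arr[person_idx])
        fam[pre] = p_arr[person_idx][pre]
        # a linked mover-out occupies their own household only after moving
        post_own = linked & ~pre
        fam[post_own] = household[person_idx][post_own]
        fam[post_own & immigrant[person_idx]] = np.nan

    company_y = company[person_idx].astype(np.float64)
    workplace_y = workplace[person_idx].astype(np.float64)
    off_age = (age_y < 19) | (age_y > 67)
    company_y[(company_y < 0) | off_age] = np.nan
    workplace_y[(workplace_y < 0) | off_age] = np.nan

    grad_y = grad_year[person_idx].astype(np.float64)
    grad_y[grad_y > year] = np.nan
    field_y = study_field[person_idx].astype(np.float64)
    field_y[field_y < 0] = np.nan

    df = pd.DataFrame(
        {
            "person_id": person_idx,
            "year": year,
            "birth_year": birth_year[person_idx],
            "family_id": fam,
            "household_id": fam,
            "property_id": property_of[person_idx].astype(np.float64),
            "municipality": municipality[person_idx],
            "education_level": edu[person_idx],
            "field_of_study": field_y,
            "graduation_year": grad_y,
            "company_id": company_y,
            "workplace_id": workplace_y,
            "income_band": np.asarray(income_band)[person_idx],
            "urbanization_level": urban[person_idx],
            "immigrant_without_family": immigrant[person_idx],
        }
    )
    for c in _NULLABLE:
        df[c] = df[c].round().astype("Int64")
    for c in SCHEMA:
        if c not in _NULLABLE and c != "immigrant_without_family":
            df[c] = df[c].astype("int64")
    df = df.sort_values(["person_id", "year"], kind="mergesort").reset_index(drop=True)
    return df[SCHEMA]


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in SCHEMA})
    return df


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

_HEADER_COMMENT = "# person-year register; missing values are empty fields\n"


def write_registry(df: pd.DataFrame, path: str | Path) -> None:
    """Write a register panel to CSV (``.csv``) or Parquet (``.parquet``).

    The CSV carries a leading comment line documenting the missing-value
    sentinel (empty field).
    """
    path = Path(path)
    df = df[SCHEMA]
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
        return
    buf = io.StringIO()
    buf.write(_HEADER_COMMENT)
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())


def read_registry(path: str | Path) -> pd.DataFrame:
    """Read a register panel written by :func:`write_registry`.

    Raises :class:`RegistryFormatError` on unknown/missing columns or a
    duplicated ``(person_id, year)`` key.
    """
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path, comment="#")
    unknown = [c for c in df.columns if c not in SCHEMA]
    missing = [c for c in SCHEMA if c not in df.columns]
    if unknown:
        raise RegistryFormatError(f"unknown columns: {unknown}")
    if missing:
        raise RegistryFormatError(f"missing columns: {missing}")
    for c in SCHEMA:
        df[c] = df[c].astype(_DTYPES[c])
    if df.duplicated(["person_id", "year"]).any():
        dup = df[df.duplicated(["person_id", "year"], keep=False)]
        raise RegistryFormatError(
            f"duplicated (person_id, year) keys, e.g. rows\n{dup.head()}"
        )
    return df[SCHEMA].reset_index(drop=True)


def validate_registry(df: pd.DataFrame) -> list[str]:
    """Check register invariants.

    Hard invariants (duplicate person-year key, age under 15, a household
    identifier without a family identifier) raise
    :class:`RegistryFormatError`; soft problems (graduation year after the
    row year) are returned as warning strings listing the offending rows.
    """
    if df.duplicated(["person_id", "year"]).any():
        raise RegistryFormatError("duplicated (person_id, year)")
    under = df["year"] - df["birth_year"] < 15
    if bool(under.any()):
        raise RegistryFormatError(
            f"{int(under.sum())} rows violate the age-15 floor"
        )
    orphan_hh = df["household_id"].notna() & df["family_id"].isna()
    if bool(orphan_hh.any()):
        raise RegistryFormatError(
            f"{int(orphan_hh.sum())} rows have household_id without family_id"
        )
    warnings: list[str] = []
    late = df["graduation_year"].notna() & (df["graduation_year"] > df["year"])
    if bool(late.any()):
        rows = df.index[late].tolist()
        warnings.append(f"graduation_year after row year in rows {rows}")
    return warnings


def analysis_year_frame(df: pd.DataFrame, year: int) -> pd.DataFrame:
    """One row per person for the analysis year; errors if the year is
    outside the panel."""
    years = df["year"]
    if len(df) and not ((years == year).any()):
        raise ValueError(f"analysis year {year} not present in the panel")
    return df[df["year"] == year].reset_index(drop=True)


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serializable view of a config (for manifests)."""
    d = dataclasses.asdict(config)
    d["property_size_mixture"] = [dataclasses.asdict(c) for c in config.property_size_mixture]
    return d
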