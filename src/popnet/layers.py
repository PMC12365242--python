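"""Builders for the six social-opportunity layers.

Layers over the analysis-year population:

* ``C`` close family — parent/child, partner and sibling ties inferred from
  age differences among persons sharing a family identifier in *any* panel
  year (family co-membership is aggregated over the full panel, then
  restricted to persons present in the analysis year).
* ``E`` extended family — compositions of close-family ties: grandparent =
  parent of a parent, uncle/aunt = sibling (or sibling's partner) of a
  parent, cousin = child of a parent's sibling.
* ``H`` household — clique among persons sharing a household identifier in
  the analysis year (family relatives only, by register construction).
* ``S`` school — shared (education level, municipality, graduation year),
  split by field of study above 1,000 members, dropped above 10,000.
* ``N`` neighbors — shared property identifier.
* ``W`` work — shared company (shared workplace for companies with at
  least 200 employees), from the analysis-year main employment.

Affiliation groups (S, N, W) up to ``full_connect_max`` members become
cliques; larger groups receive sampled edges whose per-member target degree
follows a piecewise power-law/linear function of group size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple

import numpy as np
import pandas as pd

from .registry import analysis_year_frame

__all__ = [
    "LAYERS",
    "LayerEdge",
    "AffiliationGroup",
    "ExpectedDegree",
    "build_close_family",
    "build_extended_family",
    "build_household",
    "build_school",
    "build_neighbors",
    "build_work",
    "build_all_layers",
    "sample_group_edges",
]

logger = logging.getLogger(__name__)

LAYERS = ("C", "E", "H", "S", "N", "W")

SUBTYPES = (
    "parent_child",
    "partner",
    "sibling",
    "grandparent",
    "uncle_aunt",
    "niece_nephew",
    "cousin",
    "none",
)

#: groups above this size receive sampled edges instead of a clique
FULL_CONNECT_MAX = 30
#: school groups above this size are split by field of study
SCHOOL_FIELD_SPLIT = 1_000
#: school groups above this size emit no edges
SCHOOL_GROUP_CAP = 10_000
#: companies with at least this many employees are split by workplace
WORK_SPLIT = 200
#: minimum age gap (years) for a parent/child tie
PARENT_GAP_MIN = 15
#: maximum age gap (years) for a co-resident sibling tie
SIBLING_GAP_MAX = 15


class LayerEdge(NamedTuple):
    u: int
    v: int
    layer: str
    subtype: str = "none"


@dataclass(frozen=True)
class AffiliationGroup:
    """A shared-context group that induces opportunity edges."""

    group_key: tuple
    members: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def _edge_frame(u, v, subtype=None) -> pd.DataFrame:
    """Canonical edge frame: u < v, deduplicated, stable order."""
    u = np.asarray(u, dtype=np.int64)
    v = np.asarray(v, dtype=np.int64)
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    df = pd.DataFrame({"u": lo, "v": hi})
    if subtype is not None:
        df["subtype"] = subtype
    else:
        df["subtype"] = "none"
    df = df[df["u"] != df["v"]]
    df = df.drop_duplicates(["u", "v"]).sort_values(["u", "v"], kind="mergesort")
    return df.reset_index(drop=True)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame({"u": pd.Series(dtype="int64"),
                         "v": pd.Series(dtype="int64"),
                         "subtype": pd.Series(dtype="object")})


# ---------------------------------------------------------------------------
# family layers
# ---------------------------------------------------------------------------

def build_close_family(
    registry: pd.DataFrame,
    analysis_year: int,
    *,
    parent_gap_min: int = PARENT_GAP_MIN,
    sibling_gap_max: int = SIBLING_GAP_MAX,
) -> pd.DataFrame:
    """Close-family edges (layer C) with subtypes.

    Family co-membership is aggregated across all panel years; the age-gap
    rules classify each within-family dyad.  Per family (members sorted
    oldest first):

    * the two oldest members with age gap < ``parent_gap_min`` are partners;
    * a pair sharing at least one within-family parent are siblings;
    * otherwise a gap >= ``parent_gap_min`` makes a parent/child tie;
    * otherwise a gap < ``sibling_gap_max`` makes a sibling tie.

    Output is restricted to persons with a row in ``analysis_year``.
    Persons without a family identifier in any year receive no C edges.
    The returned frame carries ``parent``/``child`` orientation columns
    (NA outside parent/child rows) consumed by the extended-family builder.
    """
    present = set(analysis_year_frame(registry, analysis_year)["person_id"])
    fam = registry.loc[registry["family_id"].notna(),
                       ["person_id", "family_id", "birth_year"]].drop_duplicates(
        ["person_id", "family_id"]
    )
    rows: list[tuple[int, int, str]] = []
    for _, grp in fam.groupby("family_id", sort=True):
        members = sorted(zip(grp["birth_year"], grp["person_id"]))
        m = len(members)
        if m < 2:
            continue
        births = [b for b, _ in members]
        pids = [p for _, p in members]
        partner_pair = None
        if births[1] - births[0] < parent_gap_min:
            partner_pair = (0, 1)
        # within-family parent candidates of j: strictly older by >= gap
        parents = [
            {i for i in range(m) if births[j] - births[i] >= parent_gap_min}
            for j in range(m)
        ]
        for i in range(m):
            for j in range(i + 1, m):
                gap = births[j] - births[i]
                if partner_pair == (i, j):
                    t = "partner"
                elif parents[i] & parents[j]:
                    t = "sibling"
                elif gap >= parent_gap_min:
                    t = "parent_child"
                elif gap < sibling_gap_max:
                    t = "sibling"
                else:
                    continue
                rows.append((pids[i], pids[j], t))  # pids[i] is the older
    if not rows:
        return _empty_edges()
    df = _edge_frame_subtyped(rows, priority=("parent_child", "partner", "sibling"))
    keep = df["u"].isin(present) & df["v"].isin(present)
    return df[keep].reset_index(drop=True)


def _edge_frame_subtyped(rows, priority: tuple[str, ...]) -> pd.DataFrame:
    """Canonicalize (older, younger, subtype) rows and deduplicate keeping
    the highest-priority subtype; parent/child orientation preserved."""
    older = np.asarray([r[0] for r in rows], dtype=np.int64)
    younger = np.asarray([r[1] for r in rows], dtype=np.int64)
    t = [r[2] for r in rows]
    lo, hi = np.minimum(older, younger), np.maximum(older, younger)
    df = pd.DataFrame({"u": lo, "v": hi, "subtype": t})
    is_pc = df["subtype"] == "parent_child"
    df["parent"] = pd.array(np.where(is_pc, older, -1), dtype="Int64")
    df["child"] = pd.array(np.where(is_pc, younger, -1), dtype="Int64")
    df.loc[~is_pc, ["parent", "child"]] = pd.NA
    df = df[df["u"] != df["v"]]
    rank = {s: i for i, s in enumerate(priority)}
    df["_r"] = df["subtype"].map(rank).fillna(len(priority))
    df = df.sort_values(["u", "v", "_r"], kind="mergesort")
    df = df.drop_duplicates(["u", "v"]).drop(columns="_r")
    return df.sort_values(["u", "v"], kind="mergesort").reset_index(drop=True)


def build_extended_family(close_edges: pd.DataFrame) -> pd.DataFrame:
    """Extended-family edges (layer E) composed from close-family ties.

    grandparent = parent∘parent; uncle/aunt = sibling∘parent and
    partner∘sibling∘parent; cousin = child∘sibling∘parent.  E never
    duplicates a C dyad.
    """
    if "subtype" not in close_edges.columns:
        raise ValueError("close_edges must carry subtypes")
    if not {"parent", "child"}.issubset(close_edges.columns):
        raise ValueError(
            "close_edges must carry 'parent'/'child' orientation columns "
            "(produced by build_close_family)"
        )
    parents_of: dict[int, set[int]] = {}
    children_of: dict[int, set[int]] = {}
    siblings: dict[int, set[int]] = {}
    partner: dict[int, set[int]] = {}
    pc = close_edges[close_edges["subtype"] == "parent_child"]
    for p, c in pc[["parent", "child"]].itertuples(index=False):
        p, c = int(p), int(c)
        parents_of.setdefault(c, set()).add(p)
        children_of.setdefault(p, set()).add(c)
    for u, v, t in close_edges[["u", "v", "subtype"]].itertuples(index=False):
        if t == "sibling":
            siblings.setdefault(u, set()).add(v)
            siblings.setdefault(v, set()).add(u)
        elif t == "partner":
            partner.setdefault(u, set()).add(v)
            partner.setdefault(v, set()).add(u)

    out: list[tuple[int, int, str]] = []
    for c, ps in parents_of.items():
        for p in ps:
            for g in parents_of.get(p, ()):  # grandparent = parent of parent
                if g != c:
                    out.append((g, c, "grandparent"))
            for s in siblings.get(p, ()):  # uncle/aunt = sibling of parent
                if s != c and s not in ps:
                    out.append((s, c, "uncle_aunt"))
                for t2 in partner.get(s, ()):  # and the sibling's partner
                    if t2 != c and t2 not in ps:
                        out.append((t2, c, "uncle_aunt"))
                for c2 in children_of.get(s, ()):  # cousin = their child
                    if c2 != c:
                        out.append((c, c2, "cousin"))
    if not out:
        return _empty_edges()
    df = _edge_frame_subtyped(out, priority=("grandparent", "uncle_aunt", "cousin"))
    df = df.drop(columns=["parent", "child"])
    # E never duplicates an existing C dyad
    c_keys = set(zip(close_edges["u"], close_edges["v"]))
    mask = [((u, v) not in c_keys) for u, v in zip(df["u"], df["v"])]
    return df[mask].reset_index(drop=True)


def build_household(registry: pd.DataFrame, analysis_year: int) -> pd.DataFrame:
    """Household edges (layer H): clique among persons sharing a household
    identifier in the analysis year."""
    snap = analysis_year_frame(registry, analysis_year)
    snap = snap[snap["household_id"].notna()]
    us: list[np.ndarray] = []
    vs: list[np.ndarray] = []
    for _, grp in snap.groupby("household_id", sort=True):
        ids = np.sort(grp["person_id"].to_numpy())
        if len(ids) < 2:
            continue
        iu, iv = np.triu_indices(len(ids), k=1)
        us.append(ids[iu])
        vs.append(ids[iv])
    if not us:
        return _empty_edges()
    return _edge_frame(np.concatenate(us), np.concatenate(vs))


# ---------------------------------------------------------------------------
# affiliation layers: expected degree and edge sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedDegree:
    """Expected connections per member as a function of group size.

    Power law ``a * size**b`` up to ``s_break``; linear above, with slope
    and intercept chosen so the two pieces join smoothly (value and first
    derivative continuous at ``s_break``).  Capped at ``size - 1``.
    """

    a: float = 1.0
    b: float = 0.55
    s_break: float = 200.0

    def __call__(self, group_size: float) -> float:
        if group_size < 2:
            raise ValueError("group_size must be >= 2")
        if group_size <= self.s_break:
            val = self.a * group_size ** self.b
        else:
            c = self.a * self.b * self.s_break ** (self.b - 1.0)
            d = self.a * self.s_break ** self.b - c * self.s_break
            val = c * group_size + d
        return min(val, group_size - 1.0)


expected_degree = ExpectedDegree()


def sample_group_edges(
    members: Iterable[int] | AffiliationGroup,
    rng: np.random.Generator,
    expected_degree_fn: Callable[[float], float] = expected_degree,
    *,
    targets: np.ndarray | None = None,
    max_rounds: int = 12,
) -> pd.DataFrame:
    """Sample within-group edges by degree-targeted stub matching.

    Each member draws a Poisson target degree around
    ``expected_degree_fn(group size)`` (clamped to ``size - 1``, with a
    warning when clamping occurs); stubs are shuffled and paired, rejecting
    self-loops and duplicate dyads, with leftover stubs re-shuffled for up
    to ``max_rounds`` rounds.  Deterministic given ``rng``'s state.
    """
    if isinstance(members, AffiliationGroup):
        members = members.members
    ids = np.asarray(sorted(members), dtype=np.int64)
    s = len(ids)
    if s < 2:
        return _empty_edges()
    if targets is None:
        mu = expected_degree_fn(s)
        targets = rng.poisson(mu, size=s)
    else:
        targets = np.asarray(targets, dtype=np.int64)
    if (targets > s - 1).any():
        logger.warning("clamping %d infeasible degree targets to group size - 1",
                       int((targets > s - 1).sum()))
        targets = np.minimum(targets, s - 1)

    seen: set[tuple[int, int]] = set()
    stubs = np.repeat(np.arange(s), targets)
    edges_u: list[int] = []
    edges_v: list[int] = []
    for _ in range(max_rounds):
        if len(stubs) < 2:
            break
        if len(stubs) % 2:
            stubs = stubs[:-1]
        rng.shuffle(stubs)
        a = stubs[0::2]
        b = stubs[1::2]
        leftover: list[int] = []
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        for x, y in zip(lo, hi):
            if x == y or (x, y) in seen:
                leftover.append(x)
                leftover.append(y)
                continue
            seen.add((int(x), int(y)))
            edges_u.append(int(x))
            edges_v.append(int(y))
        stubs = np.asarray(leftover, dtype=np.int64)
    if not edges_u:
        return _empty_edges()
    return _edge_frame(ids[np.asarray(edges_u)], ids[np.asarray(edges_v)])


def _clique_edges(ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.sort(ids)
    iu, iv = np.triu_indices(len(ids), k=1)
    return ids[iu], ids[iv]


def _affiliation_layer(
    groups: Iterable[np.ndarray],
    rng: np.random.Generator,
    *,
    full_connect_max: int = FULL_CONNECT_MAX,
    expected_degree_fn: Callable[[float], float] = expected_degree,
) -> pd.DataFrame:
    frames: list[pd.DataFrame] = []
    clique_u: list[np.ndarray] = []
    clique_v: list[np.ndarray] = []
    for ids in groups:
        ids = np.asarray(ids, dtype=np.int64)
        if len(ids) < 2:
            continue
        if len(ids) <= full_connect_max:
            cu, cv = _clique_edges(ids)
            clique_u.append(cu)
            clique_v.append(cv)
        else:
            frames.append(sample_group_edges(ids, rng, expected_degree_fn))
    if clique_u:
        frames.append(_edge_frame(np.concatenate(clique_u), np.concatenate(clique_v)))
    if not frames:
        return _empty_edges()
    df = pd.concat(frames, ignore_index=True)
    return df.drop_duplicates(["u", "v"]).sort_values(
        ["u", "v"], kind="mergesort"
    ).reset_index(drop=True)


def build_school(
    registry: pd.DataFrame,
    analysis_year: int,
    rng: np.random.Generator,
    *,
    full_connect_max: int = FULL_CONNECT_MAX,
    expected_degree_fn: Callable[[float], float] = expected_degree,
    field_split: int = SCHOOL_FIELD_SPLIT,
    group_cap: int = SCHOOL_GROUP_CAP,
) -> pd.DataFrame:
    """School edges (layer S).

    Groups share (education level, municipality, graduation year); groups
    above ``field_split`` members are split by field of study; groups still
    above ``group_cap`` emit no edges.
    """
    snap = analysis_year_frame(registry, analysis_year)
    snap = snap[snap["graduation_year"].notna()]
    groups: list[np.ndarray] = []
    for _, grp in snap.groupby(
        ["education_level", "municipality", "graduation_year"], sort=True
    ):
        if len(grp) > field_split:
            for _, sub in grp.groupby("field_of_study", sort=True, dropna=False):
                if len(sub) <= group_cap:
                    groups.append(sub["person_id"].to_numpy())
        elif len(grp) >= 2:
            groups.append(grp["person_id"].to_numpy())
    return _affiliation_layer(
        groups, rng, full_connect_max=full_connect_max,
        expected_degree_fn=expected_degree_fn,
    )


def build_neighbors(
    registry: pd.DataFrame,
    analysis_year: int,
    rng: np.random.Generator,
    *,
    full_connect_max: int = FULL_CONNECT_MAX,
    expected_degree_fn: Callable[[float], float] = expected_degree,
) -> pd.DataFrame:
    """Neighbor edges (layer N): persons sharing a property identifier."""
    snap = analysis_year_frame(registry, analysis_year)
    snap = snap[snap["property_id"].notna()]
    groups = [
        grp["person_id"].to_numpy()
        for _, grp in snap.groupby("property_id", sort=True)
        if len(grp) >= 2
    ]
    return _affiliation_layer(
        groups, rng, full_connect_max=full_connect_max,
        expected_degree_fn=expected_degree_fn,
    )


def build_work(
    registry: pd.DataFrame,
    analysis_year: int,
    rng: np.random.Generator,
    *,
    full_connect_max: int = FULL_CONNECT_MAX,
    expected_degree_fn: Callable[[float], float] = expected_degree,
    work_split: int = WORK_SPLIT,
) -> pd.DataFrame:
    """Work edges (layer W) from the analysis-year main employment.

    Companies below ``work_split`` employees are one group each; larger
    companies are subdivided by workplace.
    """
    snap = analysis_year_frame(registry, analysis_year)
    snap = snap[snap["company_id"].notna()]
    groups: list[np.ndarray] = []
    for _, grp in snap.groupby("company_id", sort=True):
        if len(grp) < 2:
            continue
        if len(grp) < work_split:
            groups.append(grp["person_id"].to_numpy())
        else:
            for _, sub in grp.groupby("workplace_id", sort=True, dropna=False):
                if len(sub) >= 2:
                    groups.append(sub["person_id"].to_numpy())
    return _affiliation_layer(
        groups, rng, full_connect_max=full_connect_max,
        expected_degree_fn=expected_degree_fn,
    )


def build_all_layers(
    registry: pd.DataFrame,
    analysis_year: int,
    seed: int | np.random.SeedSequence = 0,
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """Build all six layers; affiliation layers draw from independent
    seeded streams so each layer is individually reproducible."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_school, s_nbr, s_work = ss.spawn(3)
    close = build_close_family(registry, analysis_year)
    layers = {
        "C": close.drop(columns=[c for c in ("parent", "child") if c in close.columns]),
        "E": build_extended_family(close),
        "H": build_household(registry, analysis_year),
        "S": build_school(registry, analysis_year, np.random.default_rng(s_school), **kwargs),
        "N": build_neighbors(registry, analysis_year, np.random.default_rng(s_nbr), **kwargs),
        "W": build_work(registry, analysis_year, np.random.default_rng(s_work), **kwargs),
    }
    return layers
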