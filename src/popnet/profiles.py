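"""Sociodemographically stratified network-position profiles by age.

For bands of income, education or urbanization, the per-(band, age) cells
report mean total degree, mean excess closure (over vertices where it is
defined) and mean sampled closeness (over the closeness sample).  Cells
below a disclosure floor are suppressed — a register-data hygiene habit
that is harmless on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import MultilayerNetwork

__all__ = ["StratifiedProfile", "STRATIFIERS", "person_attributes", "stratified_profile"]

logger = logging.getLogger(__name__)

STRATIFIERS = {
    "income": "income_band",
    "education": "education_level",
    "urbanization": "urbanization_level",
}

#: cells with fewer persons than this are suppressed
DISCLOSURE_FLOOR = 10


@dataclass
class StratifiedProfile:
    stratifier: str
    bands: tuple
    table: pd.DataFrame  # columns: band, age, mean_degree, mean_excess,
    #                      mean_closeness, closeness_se, n, n_excess, n_closeness


def person_attributes(snapshot: pd.DataFrame, analysis_year: int) -> pd.DataFrame:
    """Per-person attribute frame (age plus the stratifier bands) from an
    analysis-year register snapshot."""
    out = pd.DataFrame(
        {
            "person_id": snapshot["person_id"],
            "age": analysis_year - snapshot["birth_year"],
            "income_band": snapshot["income_band"],
            "education_level": snapshot["education_level"],
            "urbanization_level": snapshot["urbanization_level"],
        }
    )
    return out.set_index("person_id")


def stratified_profile(
    network: MultilayerNetwork,
    attributes: pd.DataFrame,
    stratifier: str,
    *,
    excess: np.ndarray | pd.Series | None = None,
    closeness: pd.Series | None = None,
    bands: dict | None = None,
    floor: int = DISCLOSURE_FLOOR,
) -> StratifiedProfile:
    """Per-(band, age) means of total degree, excess closure and sampled
    closeness.

    ``attributes`` is indexed by person id with an ``age`` column and the
    stratifier column (see :data:`STRATIFIERS`).  ``bands`` optionally
    remaps raw attribute values to coarser labels.  Closeness cells use
    only the sampled vertices; their standard error is reported.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; expected one of {sorted(STRATIFIERS)}")
    col = STRATIFIERS[stratifier]
    if col not in attributes.columns or "age" not in attributes.columns:
        raise ValueError(f"attributes must carry 'age' and {col!r}")
    missing = [v for v in network.vertices if v not in attributes.index]
    if missing:
        raise ValueError(f"{len(missing)} vertices lack attributes, e.g. {missing[:3]}")

    df = attributes.loc[network.vertices, ["age", col]].copy()
    df["band"] = df[col].map(bands) if bands is not None else df[col]
    df["degree"] = network.total_degrees()
    if excess is not None:
        df["c_excess"] = np.asarray(excess, dtype=float)
    else:
        from .closure import excess_closure

        df["c_excess"] = excess_closure(network)
    if closeness is not None:
        df["closeness"] = closeness.reindex(df.index)
    else:
        df["closeness"] = np.nan

    rows = []
    for (band, age), grp in df.groupby(["band", "age"], sort=True):
        if len(grp) < floor:
            continue
        ce = grp["c_excess"].dropna()
        cl = grp["closeness"].dropna()
        rows.append(
            {
                "band": band,
                "age": int(age),
                "mean_degree": grp["degree"].mean(),
                "mean_excess": ce.mean() if len(ce) else np.nan,
                "mean_closeness": cl.mean() if len(cl) else np.nan,
                "closeness_se": cl.std(ddof=1) / np.sqrt(len(cl)) if len(cl) > 1 else np.nan,
                "n": len(grp),
                "n_excess": int(len(ce)),
                "n_closeness": int(len(cl)),
            }
        )
    table = pd.DataFrame(rows)
    observed = tuple(sorted(df["band"].dropna().unique().tolist()))
    for b in observed:
        if len(table) and b not in set(table["band"]):
            logger.warning("band %r fully suppressed (all cells below floor)", b)
    return StratifiedProfile(stratifier=stratifier, bands=observed, table=table)
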