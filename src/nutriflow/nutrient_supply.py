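"""Taxon nutrient profiles and conversion of flow weights to person-equivalents.

Nutrient composition comes from noisy multi-study observations (one row per
study x taxon x nutrient, concentration per 100 g).  Only raw muscle-tissue
observations are used; within each taxon x nutrient group, values outside
[Q1 - 3*IQR, Q3 + 3*IQR] are discarded (quartiles by linear interpolation;
groups of fewer than 4 observations are left untouched).  A taxon with no
species-level value for a nutrient inherits the mean over all observations
under the first ancestor (genus, family, ..., phylum) that has any.

Supply accounting: edible weight = live weight x edible fraction; nutrient
mass = edible weight x concentration; person-equivalents = nutrient mass /
annual RDA (daily RDA for women aged 14-50 x 365).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import (
    DAYS_PER_YEAR,
    NUTRIENT_UNITS,
    NUTRIENTS,
    PORTIONS_PER_TONNE,
    UNIT_FACTORS,
)
from .types import NutrientProfile, Taxonomy

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = ("taxon", "nutrient", "part", "preparation", "value", "unit")

#: Minimum group size before the outlier rule is applied.
MIN_OUTLIER_GROUP = 4
IQR_MULTIPLIER = 3.0


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read nutrient observations and convert to canonical units.

    Expected columns: taxon, nutrient, part, preparation, value, unit.
    The returned frame has a ``concentration`` column in each nutrient's
    canonical unit (mg or ug per 100 g).
    """
    frame = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"observation table {path} is missing columns: {sorted(missing)}")
    bad_nutrient = ~frame["nutrient"].isin(NUTRIENTS)
    if bad_nutrient.any():
        raise ValueError(
            f"unknown nutrients: {sorted(frame.loc[bad_nutrient, 'nutrient'].unique())}"
        )
    if (pd.to_numeric(frame["value"], errors="coerce") < 0).any():
        raise ValueError("nutrient concentrations must be >= 0")

    canonical = frame["nutrient"].map(NUTRIENT_UNITS)
    factors = [
        UNIT_FACTORS[(u, c)] for u, c in zip(frame["unit"], canonical, strict=True)
    ]
    n_converted = sum(f != 1.0 for f in factors)
    if n_converted:
        logger.info("converted %d observations to canonical units", n_converted)
    out = frame.copy()
    out["concentration"] = out["value"].astype(float) * np.asarray(factors)
    out["unit"] = canonical
    return out


def filter_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Retain only raw muscle-tissue observations.

    Mixing preparation types or body parts would conflate retention factors;
    raw muscle is both the modal stratum in composition databases and the
    tissue the edible-weight conversion refers to.
    """
    mask = (obs["preparation"] == "raw") & (obs["part"] == "muscle_tissue")
    return obs.loc[mask].reset_index(drop=True)


def remove_outliers(
    obs: pd.DataFrame, group_cols: tuple[str, str] = ("taxon", "nutrient")
) -> pd.DataFrame:
    """Drop concentrations outside [Q1 - 3*IQR, Q3 + 3*IQR] per group.

    Quartiles use linear interpolation.  Groups with fewer than
    ``MIN_OUTLIER_GROUP`` observations pass through unchanged (the IQR of
    2-3 points is too unstable to screen on).  The screen is applied to a
    fixed point within each group: removing an extreme value shifts the
    quartiles, and re-screening until nothing moves makes the filter
    idempotent regardless of group size.
    """

    def _keep(group: pd.DataFrame) -> pd.DataFrame:
        while len(group) >= MIN_OUTLIER_GROUP:
            values = group["concentration"].to_numpy(dtype=float)
            q1, q3 = np.percentile(values, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - IQR_MULTIPLIER * iqr, q3 + IQR_MULTIPLIER * iqr
            inside = (values >= lo) & (values <= hi)
            if inside.all():
                break
            group = group.loc[inside]
        return group

    kept = (
        obs.groupby(list(group_cols), group_keys=False, sort=False)[obs.columns]
        .apply(_keep)
        .reset_index(drop=True)
    )
    return kept


def build_profile(
    taxon: str, obs: pd.DataFrame, taxonomy: Taxonomy
) -> NutrientProfile:
    """Build the nutrient profile of one taxon with taxonomic fallback.

    Per nutrient: the mean of the taxon's own observations if any exist;
    otherwise walk the lineage upward and pool all observations attached to
    any taxon under the first ancestor that has data.  ``match_rank``
    records where the walk stopped.  Nutrients with no data up to phylum
    are simply absent (they contribute zero supply downstream).
    """
    record = taxonomy.get(taxon)  # KeyError -> fatal, per contract
    by_nutrient = {n: g for n, g in obs.groupby("nutrient", sort=False)}

    values: dict[str, float] = {}
    match_rank: dict[str, str] = {}
    n_obs: dict[str, int] = {}
    ranks = record.ancestor_ranks()
    for nutrient in NUTRIENTS:
        group = by_nutrient.get(nutrient)
        if group is None:
            continue
        for ancestor, rank in zip(record.lineage, ranks, strict=True):
            pool = taxonomy.descendants(ancestor)
            hits = group.loc[group["taxon"].isin(pool), "concentration"]
            if len(hits):
                values[nutrient] = float(hits.mean())
                match_rank[nutrient] = rank
                n_obs[nutrient] = int(len(hits))
                break
    return NutrientProfile(taxon=taxon, values=values, match_rank=match_rank, n_obs=n_obs)


def build_profiles(
    taxa: Iterable[str], obs: pd.DataFrame, taxonomy: Taxonomy
) -> pd.DataFrame:
    """Tidy profile table (taxon, nutrient, concentration, match_rank, n_obs)
    for every taxon in ``taxa``."""
    rows = []
    for taxon in taxa:
        profile = build_profile(taxon, obs, taxonomy)
        for nutrient, value in profile.values.items():
            rows.append(
                {
                    "taxon": taxon,
                    "nutrient": nutrient,
                    "concentration": value,
                    "match_rank": profile.match_rank[nutrient],
                    "n_obs": profile.n_obs[nutrient],
                }
            )
    return pd.DataFrame(rows, columns=["taxon", "nutrient", "concentration", "match_rank", "n_obs"])


def impute_edible_fraction(
    taxon: str, fractions: Mapping[str, float], taxonomy: Taxonomy
) -> float:
    """Edible (muscle) fraction of live weight for a taxon.

    Uses the species-group value if the taxon maps to a group; otherwise
    the mean over the distinct groups mapped by taxa under the nearest
    ancestor that has any mapped members.

    Raises
    ------
    ValueError
        If no ancestor level resolves (lists the lineage in the message).
    """
    record = taxonomy.get(taxon)
    if record.edible_group is not None and record.edible_group in fractions:
        return float(fractions[record.edible_group])
    for ancestor in record.lineage:
        groups = {
            taxonomy.get(name).edible_group
            for name in taxonomy.descendants(ancestor)
            if taxonomy.get(name).edible_group in fractions
        }
        groups.discard(None)
        if groups:
            return float(np.mean([fractions[g] for g in sorted(groups)]))
    raise ValueError(
        f"no edible fraction resolvable for {taxon!r}; lineage {list(record.lineage)}"
    )


def read_edible_fractions(path: str | Path) -> dict[str, float]:
    """Read the species-group -> edible-fraction table (fractions in (0, 1])."""
    frame = pd.read_csv(path)
    if not {"group", "fraction"} <= set(frame.columns):
        raise ValueError(f"edible-fraction table {path} needs columns group, fraction")
    if ((frame["fraction"] <= 0) | (frame["fraction"] > 1)).any():
        raise ValueError("edible fractions must lie in (0, 1]")
    return dict(zip(frame["group"], frame["fraction"].astype(float)))


def read_rda_table(path: str | Path) -> pd.DataFrame:
    """Read the RDA table (nutrient, unit, daily_rda) and annualize it.

    Units must match each nutrient's canonical unit; a mismatch is fatal
    because person-equivalents would silently be off by x1000.
    """
    frame = pd.read_csv(path)
    if not {"nutrient", "unit", "daily_rda"} <= set(frame.columns):
        raise ValueError(f"RDA table {path} needs columns nutrient, unit, daily_rda")
    if (frame["daily_rda"] <= 0).any():
        raise ValueError("daily_rda must be > 0")
    for row in frame.itertuples(index=False):
        if NUTRIENT_UNITS.get(row.nutrient) != row.unit:
            raise ValueError(
                f"RDA unit {row.unit!r} for {row.nutrient!r} does not match "
                f"canonical unit {NUTRIENT_UNITS.get(row.nutrient)!r}"
            )
    out = frame.copy()
    out["annual_rda"] = out["daily_rda"].astype(float) * DAYS_PER_YEAR
    return out


def compute_supply(
    flows: pd.DataFrame,
    profiles: pd.DataFrame,
    fractions_by_taxon: Mapping[str, float],
    rda: pd.DataFrame,
) -> pd.DataFrame:
    """Convert flow live weights into nutrient mass and person-equivalents.

    Returns a tidy table: one row per flow x nutrient with columns
    ``edible_weight`` (tonnes), ``nutrient_mass`` (canonical unit) and
    ``person_equivalents``.  Nutrients missing from a taxon's profile are
    absent (zero contribution).  Supply is linear in live weight and
    additive over any partition of the flows.
    """
    flows = flows.copy()
    flows["edible_fraction"] = flows["taxon"].map(
        lambda t: float(fractions_by_taxon[t])
    )
    bad = (flows["edible_fraction"] <= 0) | (flows["edible_fraction"] > 1)
    if bad.any():
        raise ValueError("edible fractions must lie in (0, 1]")
    flows["edible_weight"] = flows["live_weight"] * flows["edible_fraction"]

    merged = flows.merge(
        profiles[["taxon", "nutrient", "concentration"]], on="taxon", how="inner"
    )
    merged = merged.merge(rda[["nutrient", "annual_rda"]], on="nutrient", how="left")
    if merged["annual_rda"].isna().any():
        missing = sorted(merged.loc[merged["annual_rda"].isna(), "nutrient"].unique())
        raise ValueError(f"no RDA for nutrients: {missing}")

    # concentration is per 100 g; one tonne holds PORTIONS_PER_TONNE portions
    merged["nutrient_mass"] = (
        merged["edible_weight"] * merged["concentration"] * PORTIONS_PER_TONNE
    )
    merged["person_equivalents"] = merged["nutrient_mass"] / merged["annual_rda"]
    return merged


def summarize_across_nutrients(
    values: pd.Series | pd.DataFrame,
    stat: str = "mean",
    weights: pd.Series | None = None,
) -> float:
    """Cross-nutrient summary of person-equivalents (mean or median).

    When ``weights`` (live-weight trade volumes) are supplied with
    ``stat='mean'``, the result is the trade-volume-weighted mean.
    """
    series = values if isinstance(values, pd.Series) else values.squeeze()
    if len(series) == 0:
        raise ValueError("cannot summarize an empty nutrient set")
    if stat == "median":
        return float(series.median())
    if stat != "mean":
        raise ValueError(f"unknown statistic {stat!r}")
    if weights is None:
        return float(series.mean())
    w = weights.loc[series.index].astype(float)
    if w.sum() == 0:
        raise ValueError("weights sum to zero")
    return float(np.average(series.astype(float), weights=w))
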