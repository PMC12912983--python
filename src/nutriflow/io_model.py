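"""Reading, validation, filtering and year-averaging of bilateral trade flows.

The canonical flow table has one row per producer -> exporter -> importer
record of live-weight tonnes for a taxon/production-method/commodity, with
columns::

    year, producer, exporter, importer, taxon, method, commodity, live_weight

Domestic retention is encoded as a self-flow (producer = exporter =
importer).  Country codes are ISO3-style three-letter codes; codes not in a
supplied registry are retained but flagged, and excluded from country-level
statistics downstream.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .constants import COMMODITIES, METHODS
from .types import FilterReport, ParseResult

logger = logging.getLogger(__name__)

FLOW_COLUMNS: tuple[str, ...] = (
    "year",
    "producer",
    "exporter",
    "importer",
    "taxon",
    "method",
    "commodity",
    "live_weight",
)

_ISO3_RE = re.compile(r"^[A-Z]{3}$")


def read_trade_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    known_codes: Iterable[str] | None = None,
) -> ParseResult:
    """Read a trade-flow CSV into the canonical flow table.

    Parameters
    ----------
    path:
        CSV with a header row.
    schema:
        Optional map from canonical column name to the column name used in
        the file (columns not listed keep their canonical name).
    known_codes:
        Registry of valid country codes (typically the codes of the country
        table).  Codes of the right shape but outside the registry are
        retained with ``code_flagged=True`` and counted in
        ``ParseResult.unknown_codes``; malformed codes are flagged the same
        way.  A missing producer is legal at this stage (removed later by
        :func:`apply_exclusion_filters`).

    Raises
    ------
    ValueError
        If a required column is absent (fatal; nothing is parsed).
    """
    raw = pd.read_csv(path, dtype={"year": "Int64"})
    rename = {v: k for k, v in (schema or {}).items()}
    raw = raw.rename(columns=rename)

    missing = [c for c in FLOW_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"trade table {path} is missing required columns: {missing}")

    rejected: list[str] = []
    unknown: dict[str, int] = {}

    frame = raw.loc[:, list(FLOW_COLUMNS)].copy()
    frame["live_weight"] = pd.to_numeric(frame["live_weight"], errors="coerce")

    bad_weight = frame["live_weight"].isna() | (frame["live_weight"] < 0)
    for idx in frame.index[bad_weight]:
        rejected.append(f"row {idx}: invalid live_weight {raw.at[idx, 'live_weight']!r}")
    frame = frame.loc[~bad_weight]

    bad_method = ~frame["method"].isin(METHODS)
    for idx in frame.index[bad_method]:
        rejected.append(f"row {idx}: unknown method {frame.at[idx, 'method']!r}")
    frame = frame.loc[~bad_method]

    bad_commodity = ~frame["commodity"].isin(COMMODITIES)
    for idx in frame.index[bad_commodity]:
        rejected.append(f"row {idx}: unknown commodity {frame.at[idx, 'commodity']!r}")
    frame = frame.loc[~bad_commodity]

    registry = set(known_codes) if known_codes is not None else None
    flagged = pd.Series(False, index=frame.index)
    for col in ("producer", "exporter", "importer"):
        codes = frame[col].astype("string")
        for idx, code in codes.items():
            if pd.isna(code) or code == "":
                continue  # absent producer handled by the exclusion filters
            ok_shape = bool(_ISO3_RE.match(code))
            ok_known = registry is None or code in registry
            if not (ok_shape and ok_known):
                flagged.at[idx] = True
                unknown[code] = unknown.get(code, 0) + 1
    frame["code_flagged"] = flagged
    frame["producer"] = frame["producer"].astype("string")
    frame = frame.reset_index(drop=True)

    if rejected:
        logger.warning("rejected %d rows while reading %s", len(rejected), path)
    return ParseResult(flows=frame, rejected=rejected, unknown_codes=unknown)


def write_flows(flows: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical flow table as CSV (round-trips with read)."""
    flows.to_csv(path, index=False, float_format="%.10g")


def apply_exclusion_filters(
    flows: pd.DataFrame,
    plant_algae_taxa: Iterable[str] = (),
) -> tuple[pd.DataFrame, list[FilterReport]]:
    """Apply the three record-level exclusion rules.

    (a) fishmeal sourced from aquaculture (mostly by-products, which would
        double-count farmed production);
    (b) fish-oil commodities and plant/algae taxa (out of the edible-weight
        accounting);
    (c) flows with no producing country (unexplained exports).

    Returns the surviving flows and one :class:`FilterReport` per rule with
    the dropped live-weight fraction relative to the input total.  The
    operation is idempotent.
    """
    total_weight = float(flows["live_weight"].sum())
    plant_algae = set(plant_algae_taxa)
    reports: list[FilterReport] = []
    kept = flows

    masks = {
        "aquaculture_fishmeal": (kept["commodity"] == "fishmeal")
        & (kept["method"] == "aquaculture"),
        "fish_oil_plants_algae": (kept["commodity"] == "fish_oil")
        | kept["taxon"].isin(plant_algae),
        "missing_producer": kept["producer"].isna() | (kept["producer"] == ""),
    }
    for rule, mask in masks.items():
        dropped = kept.loc[mask]
        frac = float(dropped["live_weight"].sum()) / total_weight if total_weight else 0.0
        reports.append(
            FilterReport(
                rule=rule,
                records_dropped=int(mask.sum()),
                weight_dropped_fraction=frac,
            )
        )
        kept = kept.loc[~mask]

    return kept.reset_index(drop=True), reports


FLOW_KEY: tuple[str, ...] = (
    "producer",
    "exporter",
    "importer",
    "taxon",
    "method",
    "commodity",
)


def average_years(
    flows: pd.DataFrame, year_range: tuple[int, int]
) -> pd.DataFrame:
    """Average live weight over an inclusive year range.

    Flows are grouped on (producer, exporter, importer, taxon, method,
    commodity); the averaged weight is the sum over the years present
    divided by the number of years in the range, so years with no record
    count as zero production.  Flows outside the range are excluded with a
    logged count.  The output ``year`` column marks the range.
    """
    lo, hi = year_range
    if hi < lo:
        raise ValueError(f"empty year range {year_range}")
    n_years = hi - lo + 1

    in_range = flows["year"].between(lo, hi)
    n_out = int((~in_range).sum())
    if n_out:
        logger.info("average_years: excluded %d flows outside %s", n_out, year_range)
    subset = flows.loc[in_range]

    agg: dict[str, str] = {"live_weight": "sum"}
    if "code_flagged" in subset.columns:
        agg["code_flagged"] = "max"
    grouped = (
        subset.groupby(list(FLOW_KEY), dropna=False, sort=True)
        .agg(agg)
        .reset_index()
    )
    grouped["live_weight"] = grouped["live_weight"] / n_years
    grouped.insert(0, "year", f"{lo}-{hi}")
    return grouped


def split_retained_traded(
    flows: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition flows into domestically retained self-flows and traded flows.

    Retained means producer = exporter = importer; everything else is
    traded.  The two outputs partition the input exactly.
    """
    retained_mask = (flows["producer"] == flows["exporter"]) & (
        flows["exporter"] == flows["importer"]
    )
    retained = flows.loc[retained_mask].reset_index(drop=True)
    traded = flows.loc[~retained_mask].reset_index(drop=True)
    return retained, traded


def read_country_table(path: str | Path) -> pd.DataFrame:
    """Read the tidy country table (iso3, population, nutrient, prevalence).

    Prevalences are percentages in [0, 100]; population must be positive
    and constant per country.
    """
    frame = pd.read_csv(path)
    required = {"iso3", "population", "nutrient", "prevalence"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"country table {path} is missing columns: {sorted(missing)}")
    if (frame["population"] <= 0).any():
        raise ValueError("population must be > 0 for every country")
    bad = ~frame["prevalence"].between(0, 100)
    if bad.any():
        raise ValueError(
            f"prevalence outside [0, 100] for rows {list(frame.index[bad])}"
        )
    return frame
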