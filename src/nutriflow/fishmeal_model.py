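"""Bottom-up fishmeal demand of aquaculture and allocation of fishmeal flows.

The demand model is FM = sum_s AC_s * FCR_s * P_FMFO_s (product tonnes),
with wild-fish live-weight equivalents obtained via the constant
live-weight conversion factor LWC_FM = 2.98.  AC_s is the aquaculture live
weight of species group s, FCR its feed conversion ratio and P_FMFO the
proportion of fishmeal plus fish oil in its feed (non-fed groups such as
bivalves have P_FMFO = 0).

Feed parameters are tabulated for 12 feed taxa while production is grouped
by ISSCAAP statistical groups; the two are bridged by the ordered matching
rules implemented in :func:`match_isscaap_to_fcr`.

Allocation assumes a country sources the fishmeal for every farmed taxon in
proportion to its overall fishmeal supply mix (partners and constituent
wild species), scaled to that taxon's demand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .constants import LWC_FM

logger = logging.getLogger(__name__)


def _tokens(label: str) -> set[str]:
    return {t for t in re.split(r"[^a-z]+", label.lower()) if t}


def _token_in_label(token: str, label_tokens: set[str]) -> bool:
    """Match a feed-taxon token against a group label, tolerating plural forms."""
    candidates = {token, token + "s", token + "es"}
    if token.endswith("s"):
        candidates.add(token[:-1])
    return bool(candidates & label_tokens)


def match_isscaap_to_fcr(
    isscaap: pd.DataFrame, fcr: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Bridge ISSCAAP production groups to feed-parameter taxa.

    Parameters
    ----------
    isscaap:
        Columns ``group`` (label) and ``members`` (';'-joined species names).
    fcr:
        Columns ``taxon_group``, ``members`` (';'-joined, may be empty),
        ``fcr``, ``p_fmfo``.

    Rules are applied in order of specificity and the first rule that
    yields any match wins (a group is never matched to a broader taxon
    when a more specific one already matched):

    i.   the feed taxon is mentioned explicitly in the ISSCAAP group label;
    ii.  the feed taxon's member species all fit inside the broader ISSCAAP
         group;
    iii. the ISSCAAP group's members all fit inside the broader feed taxon.

    Many-to-many matches are allowed; a group matching several feed taxa
    receives the mean of their FCR and P_FMFO values.

    Returns the mapping table (isscaap_group, fcr, p_fmfo, matched_taxa,
    rule) and the list of unmatched group labels (excluded from feed
    demand, with a warning).
    """
    fcr_rows = []
    for row in fcr.itertuples(index=False):
        members = set()
        raw = getattr(row, "members", "")
        if isinstance(raw, str) and raw:
            members = {m.strip() for m in raw.split(";") if m.strip()}
        fcr_rows.append(
            {
                "taxon_group": row.taxon_group,
                "tokens": _tokens(str(row.taxon_group)),
                "members": members,
                "fcr": float(row.fcr),
                "p_fmfo": float(row.p_fmfo),
            }
        )

    mapping_rows = []
    unmatched: list[str] = []
    for row in isscaap.itertuples(index=False):
        label = str(row.group)
        label_tokens = _tokens(label)
        group_members = {
            m.strip() for m in str(getattr(row, "members", "") or "").split(";") if m.strip()
        }
        matched: list[dict] = []
        rule_used = None
        # rule (i): explicit mention in the group label
        hits = [
            f
            for f in fcr_rows
            if all(_token_in_label(t, label_tokens) for t in f["tokens"])
        ]
        if hits:
            matched, rule_used = hits, "explicit_mention"
        if not matched and group_members:
            # rule (ii): feed taxon fits inside the broader ISSCAAP group
            hits = [
                f
                for f in fcr_rows
                if f["members"] and f["members"] <= group_members
            ]
            if hits:
                matched, rule_used = hits, "fcr_within_group"
        if not matched and group_members:
            # rule (iii): ISSCAAP group fits inside the broader feed taxon
            hits = [
                f
                for f in fcr_rows
                if f["members"] and group_members <= f["members"]
            ]
            if hits:
                matched, rule_used = hits, "group_within_fcr"
        if not matched:
            unmatched.append(label)
            continue
        mapping_rows.append(
            {
                "isscaap_group": label,
                "fcr": sum(f["fcr"] for f in matched) / len(matched),
                "p_fmfo": sum(f["p_fmfo"] for f in matched) / len(matched),
                "matched_taxa": ";".join(sorted(f["taxon_group"] for f in matched)),
                "rule": rule_used,
            }
        )
    if unmatched:
        logger.warning(
            "no feed parameters for %d ISSCAAP groups (zero assumed): %s",
            len(unmatched),
            unmatched,
        )
    return (
        pd.DataFrame(
            mapping_rows,
            columns=["isscaap_group", "fcr", "p_fmfo", "matched_taxa", "rule"],
        ),
        unmatched,
    )


def feed_demand(production: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Per-country, per-group fishmeal demand from aquaculture production.

    ``production`` has columns country, isscaap_group, live_weight (tonnes
    of farmed output).  Output columns: country, isscaap_group,
    fishmeal_product (tonnes of product) and live_weight_equiv (wild-fish
    live weight = product x 2.98).  Groups absent from the mapping
    contribute zero demand and are dropped.
    """
    if (production["live_weight"] < 0).any():
        raise ValueError("production live weights must be >= 0")
    merged = production.merge(
        mapping[["isscaap_group", "fcr", "p_fmfo"]], on="isscaap_group", how="inner"
    )
    out = merged.copy()
    out["fishmeal_product"] = out["live_weight"] * out["fcr"] * out["p_fmfo"]
    out["live_weight_equiv"] = out["fishmeal_product"] * LWC_FM
    return out[
        ["country", "isscaap_group", "fishmeal_product", "live_weight_equiv"]
    ].reset_index(drop=True)


@dataclass
class AllocationResult:
    """Fishmeal demand allocated over each country's fishmeal supply mix.

    ``allocations`` columns: country, isscaap_group, source_country,
    fishmeal_species, tonnes (live-weight equivalents).  Per country x
    group the allocated tonnes sum to that cell's demand; cells with
    demand but no recorded fishmeal supply appear in ``unsourced`` with the
    demand left unallocated.
    """

    allocations: pd.DataFrame
    unsourced: pd.DataFrame = field(default_factory=pd.DataFrame)


def allocate_fishmeal_flows(
    demand: pd.DataFrame,
    fishmeal_flows: pd.DataFrame,
    include_domestic: bool = True,
) -> AllocationResult:
    """Distribute each country's feed demand over its fishmeal supply mix.

    ``fishmeal_flows`` are fishmeal-commodity flows (live-weight tonnes);
    a country's supply is everything flowing to it as importer —
    including its own retained production when ``include_domestic`` (a
    country feeding its own fishmeal should not be flagged unsourced).
    Shares are computed on live-weight-equivalent tonnes; with a constant
    conversion factor they equal product-tonne shares.
    """
    supply = fishmeal_flows.loc[fishmeal_flows["commodity"] == "fishmeal"]
    if not include_domestic:
        supply = supply.loc[supply["exporter"] != supply["importer"]]
    totals = supply.groupby("importer")["live_weight"].sum()

    alloc_rows = []
    unsourced_rows = []
    for row in demand.itertuples(index=False):
        need = float(row.live_weight_equiv)
        total = float(totals.get(row.country, 0.0))
        if need > 0 and total <= 0:
            unsourced_rows.append(
                {
                    "country": row.country,
                    "isscaap_group": row.isscaap_group,
                    "live_weight_equiv": need,
                }
            )
            continue
        if need == 0:
            continue
        mix = supply.loc[supply["importer"] == row.country]
        cells = mix.groupby(["producer", "taxon"])["live_weight"].sum() / total
        for (source, species), share in cells.items():
            alloc_rows.append(
                {
                    "country": row.country,
                    "isscaap_group": row.isscaap_group,
                    "source_country": source,
                    "fishmeal_species": species,
                    "tonnes": need * float(share),
                }
            )
    allocations = pd.DataFrame(
        alloc_rows,
        columns=["country", "isscaap_group", "source_country", "fishmeal_species", "tonnes"],
    )
    unsourced = pd.DataFrame(
        unsourced_rows, columns=["country", "isscaap_group", "live_weight_equiv"]
    )
    if len(unsourced):
        logger.warning("%d demand cells have no fishmeal supply", len(unsourced))
    return AllocationResult(allocations=allocations, unsourced=unsourced)


def trimmings_adjustment(
    frame: pd.DataFrame, trimmings_fraction: float, columns: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Scale fishmeal quantities by (1 - trimmings_fraction).

    A fraction of fishmeal originates from processing trimmings rather than
    whole wild fish; scaling removes that share from reduction-fishery
    accounting.  The baseline is fraction 0; the reported sensitivity upper
    bound is 0.34.  Applies to every recognised quantity column present
    (or an explicit column list) and is linear, so it commutes with the
    rest of the accounting.
    """
    if not 0.0 <= trimmings_fraction <= 1.0:
        raise ValueError(f"trimmings fraction {trimmings_fraction} outside [0, 1]")
    default_cols = (
        "live_weight",
        "edible_weight",
        "fishmeal_product",
        "live_weight_equiv",
        "tonnes",
        "nutrient_mass",
        "person_equivalents",
    )
    cols = [c for c in (columns or default_cols) if c in frame.columns]
    out = frame.copy()
    out[cols] = out[cols] * (1.0 - trimmings_fraction)
    return out
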