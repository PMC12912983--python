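"""Vulnerability bins and equity classification of traded nutrient flows.

Country nutritional vulnerability is the prevalence of inadequate intake of
a nutrient, binned into five categories::

    very_low <= 5 < low <= 10 < medium <= 25 < high <= 50 < very_high

(boundaries belong to the lower bin).  A country is "nutritionally
vulnerable" when its prevalence exceeds a threshold (default 25%, i.e. the
high/very-high bins); the threshold is a parameter so the sensitivity sweep
can vary it.

A traded flow is labelled by comparing source and destination prevalence:
flows from a MORE vulnerable source to a LESS vulnerable destination are
inequitable (nutrients leaving the places that need them most), the
opposite direction is equitable, and ties are "same".  Two rules are
provided: categorical (compare bins) and absolute (compare prevalences
with a +/- 5 percentage-point indifference band).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES: tuple[str, ...] = ("very_low", "low", "medium", "high", "very_high")
#: Upper bounds of the first four bins (inclusive).
_BIN_UPPER: tuple[float, ...] = (5.0, 10.0, 25.0, 50.0)

VULNERABLE_THRESHOLD_DEFAULT = 25.0
ABSOLUTE_BAND_DEFAULT = 5.0


def vulnerability_category(prevalence: float) -> str:
    """Bin a prevalence (%) into one of the five vulnerability categories."""
    if not 0.0 <= prevalence <= 100.0:
        raise ValueError(f"prevalence {prevalence} outside [0, 100]")
    for label, upper in zip(CATEGORIES, _BIN_UPPER):
        if prevalence <= upper:
            return label
    return "very_high"


def vulnerability_categories(prevalence: pd.Series | np.ndarray) -> np.ndarray:
    """Vectorised :func:`vulnerability_category`."""
    values = np.asarray(prevalence, dtype=float)
    if ((values < 0) | (values > 100)).any():
        raise ValueError("prevalence outside [0, 100]")
    idx = np.searchsorted(np.asarray(_BIN_UPPER), values, side="left")
    return np.asarray(CATEGORIES, dtype=object)[idx]


def is_vulnerable(
    prevalence: float | np.ndarray, threshold: float = VULNERABLE_THRESHOLD_DEFAULT
):
    """True where prevalence strictly exceeds the vulnerability threshold."""
    result = np.asarray(prevalence, dtype=float) > threshold
    return bool(result) if result.ndim == 0 else result


@dataclass(frozen=True)
class EquityLabel:
    """Classification of one flow for one nutrient."""

    label: str  # equitable | same | inequitable
    direction: str  # higher_to_lower | same | lower_to_higher
    method: str  # categorical | absolute
    i_s: float  # source prevalence (%)
    i_d: float  # destination prevalence (%)


def classify_flow_categorical(i_s: float, i_d: float) -> EquityLabel:
    """Compare source and destination vulnerability bins.

    Same bin -> "same"; source in a more vulnerable bin -> inequitable
    (direction higher_to_lower); source less vulnerable -> equitable.
    """
    bin_s = CATEGORIES.index(vulnerability_category(i_s))
    bin_d = CATEGORIES.index(vulnerability_category(i_d))
    if bin_s == bin_d:
        return EquityLabel("same", "same", "categorical", i_s, i_d)
    if bin_s > bin_d:
        return EquityLabel("inequitable", "higher_to_lower", "categorical", i_s, i_d)
    return EquityLabel("equitable", "lower_to_higher", "categorical", i_s, i_d)


def classify_flow_absolute(
    i_s: float, i_d: float, band: float = ABSOLUTE_BAND_DEFAULT
) -> EquityLabel:
    """Compare raw prevalences with an indifference band (percentage points).

    |I_D - I_S| <= band -> same; I_S - I_D > band -> inequitable;
    I_D - I_S > band -> equitable.  Antisymmetric: swapping source and
    destination swaps equitable and inequitable and preserves "same".
    """
    if band < 0:
        raise ValueError(f"band must be >= 0, got {band}")
    delta = i_s - i_d
    if abs(delta) <= band:
        return EquityLabel("same", "same", "absolute", i_s, i_d)
    if delta > band:
        return EquityLabel("inequitable", "higher_to_lower", "absolute", i_s, i_d)
    return EquityLabel("equitable", "lower_to_higher", "absolute", i_s, i_d)


def classify_frame(
    i_s: pd.Series | np.ndarray,
    i_d: pd.Series | np.ndarray,
    method: str = "categorical",
    band: float = ABSOLUTE_BAND_DEFAULT,
) -> np.ndarray:
    """Vectorised classification; returns an array of labels."""
    s = np.asarray(i_s, dtype=float)
    d = np.asarray(i_d, dtype=float)
    if method == "categorical":
        if ((s < 0) | (s > 100)).any() or ((d < 0) | (d > 100)).any():
            raise ValueError("prevalence outside [0, 100]")
        upper = np.asarray(_BIN_UPPER)
        bin_s = np.searchsorted(upper, s, side="left")
        bin_d = np.searchsorted(upper, d, side="left")
        out = np.where(
            bin_s == bin_d, "same", np.where(bin_s > bin_d, "inequitable", "equitable")
        )
    elif method == "absolute":
        if band < 0:
            raise ValueError(f"band must be >= 0, got {band}")
        delta = s - d
        out = np.where(
            np.abs(delta) <= band,
            "same",
            np.where(delta > band, "inequitable", "equitable"),
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return out.astype(object)


def label_flows(
    supply: pd.DataFrame,
    countries: pd.DataFrame,
    method: str = "categorical",
    band: float = ABSOLUTE_BAND_DEFAULT,
    source_col: str = "producer",
    dest_col: str = "importer",
) -> pd.DataFrame:
    """Label each flow x nutrient row of a tidy supply table.

    ``countries`` is the tidy country table (iso3, nutrient, prevalence,
    population).  Rows whose source or destination lacks a prevalence for
    the nutrient are excluded from equity statistics with a logged count.
    """
    prev = countries.rename(columns={"iso3": "_c", "prevalence": "_p"})[
        ["_c", "nutrient", "_p"]
    ]
    out = supply.merge(
        prev.rename(columns={"_c": source_col, "_p": "i_s"}),
        on=[source_col, "nutrient"],
        how="left",
    ).merge(
        prev.rename(columns={"_c": dest_col, "_p": "i_d"}),
        on=[dest_col, "nutrient"],
        how="left",
    )
    missing = out["i_s"].isna() | out["i_d"].isna()
    if missing.any():
        logger.info(
            "label_flows: %d rows excluded for missing prevalence", int(missing.sum())
        )
    out = out.loc[~missing].reset_index(drop=True)
    out["label"] = classify_frame(out["i_s"], out["i_d"], method=method, band=band)
    out["method"] = method
    return out


def equity_shares(
    labeled: pd.DataFrame, weight_col: str = "person_equivalents"
) -> dict[str, float]:
    """Three-way weighted split (%) over equitable / same / inequitable.

    The shares sum to 100.  Raises on zero total weight (an empty traded
    set has no defined share).
    """
    total = float(labeled[weight_col].sum())
    if total <= 0:
        raise ValueError("total weight is zero; equity share undefined")
    shares = {}
    for label in ("equitable", "same", "inequitable"):
        shares[label] = (
            float(labeled.loc[labeled["label"] == label, weight_col].sum()) / total * 100.0
        )
    return shares


def inequitable_share(
    labeled: pd.DataFrame, weight_col: str = "person_equivalents"
) -> float:
    """Weighted percentage of traded quantity labelled inequitable."""
    return equity_shares(labeled, weight_col)["inequitable"]


def vulnerable_source_share(
    supply: pd.DataFrame,
    countries: pd.DataFrame,
    threshold: float = VULNERABLE_THRESHOLD_DEFAULT,
    weight_col: str = "person_equivalents",
    source_col: str = "producer",
) -> float:
    """Percent of traded supply whose source country is vulnerable.

    Vulnerability is per nutrient (prevalence > threshold).  Rows with no
    source prevalence are excluded.
    """
    prev = countries[["iso3", "nutrient", "prevalence"]].rename(
        columns={"iso3": source_col}
    )
    merged = supply.merge(prev, on=[source_col, "nutrient"], how="left")
    merged = merged.loc[~merged["prevalence"].isna()]
    total = float(merged[weight_col].sum())
    if total <= 0:
        raise ValueError("total weight is zero; vulnerable-source share undefined")
    vulnerable = merged.loc[merged["prevalence"] > threshold, weight_col].sum()
    return float(vulnerable) / total * 100.0


def vulnerable_source_sweep(
    supply: pd.DataFrame,
    countries: pd.DataFrame,
    thresholds: tuple[float, ...] = (10.0, 25.0, 50.0),
    weight_col: str = "person_equivalents",
    source_col: str = "producer",
) -> pd.DataFrame:
    """Sensitivity of the vulnerable-source share to the threshold."""
    rows = [
        {
            "threshold": t,
            "share": vulnerable_source_share(
                supply, countries, threshold=t, weight_col=weight_col, source_col=source_col
            ),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows)


def build_supply_chains(
    fishmeal_edges: pd.DataFrame,
    farmed_edges: pd.DataFrame,
    countries: pd.DataFrame,
    nutrient: str | None = None,
    method: str = "categorical",
    band: float = ABSOLUTE_BAND_DEFAULT,
) -> pd.DataFrame:
    """Three-stage edge list for Sankey-style rendering.

    Stage "fishmeal_to_aquaculture" edges come from the allocation result
    (columns source_country, country, tonnes [, nutrient]); stage
    "aquaculture_to_consumer" edges from traded farmed-fish supply
    (producer, importer, quantity column [, nutrient]).  Every edge is
    labelled with the equity class of its endpoints, so the renderer can
    colour links without re-deriving the classification.
    """
    rows = []
    prev = countries.set_index(["iso3", "nutrient"])["prevalence"]

    def _emit(stage, src, dst, qty, nut):
        key_s, key_d = (src, nut), (dst, nut)
        if key_s not in prev.index or key_d not in prev.index:
            return
        i_s, i_d = float(prev[key_s]), float(prev[key_d])
        lab = (
            classify_flow_categorical(i_s, i_d)
            if method == "categorical"
            else classify_flow_absolute(i_s, i_d, band)
        )
        rows.append(
            {
                "stage": stage,
                "source": src,
                "target": dst,
                "nutrient": nut,
                "quantity": qty,
                "label": lab.label,
                "direction": lab.direction,
            }
        )

    fm = fishmeal_edges
    if nutrient is not None and "nutrient" in fm.columns:
        fm = fm.loc[fm["nutrient"] == nutrient]
    qty_col = "tonnes" if "tonnes" in fm.columns else "quantity"
    group_cols = ["source_country", "country"] + (
        ["nutrient"] if "nutrient" in fm.columns else []
    )
    for key, grp in fm.groupby(group_cols):
        key = (key,) if not isinstance(key, tuple) else key
        nut = key[2] if len(key) > 2 else nutrient
        if nut is None:
            continue
        _emit("fishmeal_to_aquaculture", key[0], key[1], float(grp[qty_col].sum()), nut)

    ff = farmed_edges
    if nutrient is not None and "nutrient" in ff.columns:
        ff = ff.loc[ff["nutrient"] == nutrient]
    qty_col = (
        "person_equivalents" if "person_equivalents" in ff.columns else "live_weight"
    )
    group_cols = ["producer", "importer"] + (["nutrient"] if "nutrient" in ff.columns else [])
    for key, grp in ff.groupby(group_cols):
        key = (key,) if not isinstance(key, tuple) else key
        nut = key[2] if len(key) > 2 else nutrient
        if nut is None:
            continue
        _emit("aquaculture_to_consumer", key[0], key[1], float(grp[qty_col].sum()), nut)

    return pd.DataFrame(
        rows,
        columns=["stage", "source", "target", "nutrient", "quantity", "label", "direction"],
    )
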