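"""Net nutrient positions and retention/repurposing counterfactuals.

Net position: per country and nutrient, person-equivalents imported minus
exported (exports include both fishmeal and farmed-fish exports); the
cross-nutrient summary is the median.

Scenarios (all evaluated through population-capped newly-met needs):

* ``repurpose_fishmeal_exports`` — the wild fish behind a country's
  fishmeal exports is eaten at home instead (optionally scaled down by the
  trimmings fraction, since trimmings-derived fishmeal embodies no extra
  whole fish);
* ``retain_farmed_exports`` — farmed-fish exports stay with the exporter;
* ``actual_farmed_imports`` — the nutrients a country actually imports in
  farmed fish.

Newly-met needs cap each nutrient at the nutritionally vulnerable
population (population x prevalence of inadequate intake): supply beyond
the people who lack the nutrient meets no new need.  Capping is applied
per nutrient before averaging across nutrients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import NUTRIENTS

logger = logging.getLogger(__name__)

SCENARIOS: tuple[str, ...] = (
    "repurpose_fishmeal_exports",
    "retain_farmed_exports",
    "actual_farmed_imports",
)

ROLES: tuple[str, ...] = ("import", "fishmeal_export", "farmed_export")


def net_position(supplies: pd.DataFrame) -> pd.DataFrame:
    """Per-country net person-equivalents (imports minus all exports).

    ``supplies`` is tidy with columns country, role (one of ``ROLES``),
    nutrient, person_equivalents.  Returns one row per country x nutrient
    plus a ``net_median`` column repeating the country's cross-nutrient
    median.  Additive over flows; reversing every flow flips the sign.
    """
    bad = ~supplies["role"].isin(ROLES)
    if bad.any():
        raise ValueError(
            f"unknown roles: {sorted(supplies.loc[bad, 'role'].unique())}"
        )
    signed = supplies.copy()
    signed["signed_pe"] = np.where(
        signed["role"] == "import",
        signed["person_equivalents"],
        -signed["person_equivalents"],
    )
    net = (
        signed.groupby(["country", "nutrient"], sort=True)["signed_pe"]
        .sum()
        .rename("net_pe")
        .reset_index()
    )
    # countries may lack rows for some nutrients; absent nutrient = 0 net
    medians = (
        net.pivot(index="country", columns="nutrient", values="net_pe")
        .reindex(columns=list(NUTRIENTS))
        .fillna(0.0)
        .median(axis=1)
        .rename("net_median")
    )
    return net.merge(medians, on="country")


@dataclass
class ScenarioResult:
    """Newly-met needs of one country under one scenario."""

    country: str
    scenario: str
    newly_met: dict[str, float]  # per nutrient, persons (capped)
    mean_newly_met: float  # mean over the 14 nutrients
    fraction_of_population: float
    fraction_of_vulnerable: float  # mean per-nutrient fraction, capped at 1


def newly_met_needs(
    country: str,
    person_equivalents: dict[str, float] | pd.Series,
    countries: pd.DataFrame,
    scenario: str = "",
) -> ScenarioResult:
    """Cap supply at the vulnerable population and average across nutrients.

    Per nutrient: newly_met = min(pe, population x prevalence / 100).
    Nutrients with no supply count as zero when averaging, so the mean is
    always over the full 14-nutrient set.
    """
    rows = countries.loc[countries["iso3"] == country]
    if rows.empty:
        raise ValueError(f"unknown country {country!r}")
    population = float(rows["population"].iloc[0])
    if population <= 0:
        raise ValueError(f"population of {country!r} must be > 0")
    prevalence = dict(zip(rows["nutrient"], rows["prevalence"].astype(float)))

    pe = dict(person_equivalents)
    newly: dict[str, float] = {}
    vuln_fractions = []
    for nutrient in NUTRIENTS:
        supply = float(pe.get(nutrient, 0.0))
        vuln_pop = population * prevalence.get(nutrient, 0.0) / 100.0
        met = min(supply, vuln_pop)
        newly[nutrient] = met
        vuln_fractions.append(min(met / vuln_pop, 1.0) if vuln_pop > 0 else 0.0)
    mean_met = float(np.mean(list(newly.values())))
    return ScenarioResult(
        country=country,
        scenario=scenario,
        newly_met=newly,
        mean_newly_met=mean_met,
        fraction_of_population=mean_met / population,
        fraction_of_vulnerable=float(np.mean(vuln_fractions)),
    )


def _pe_by_country(supply: pd.DataFrame, country_col: str) -> pd.DataFrame:
    return (
        supply.groupby([country_col, "nutrient"], sort=True)["person_equivalents"]
        .sum()
        .reset_index()
        .rename(columns={country_col: "country"})
    )


def run_scenarios(
    fishmeal_export_supply: pd.DataFrame,
    farmed_traded_supply: pd.DataFrame,
    countries: pd.DataFrame,
    trimmings_fraction: float = 0.0,
) -> pd.DataFrame:
    """Evaluate the three counterfactuals for every country involved.

    ``fishmeal_export_supply`` is the tidy nutrient supply of traded
    fishmeal flows (live-weight equivalents of the wild fish, treated as
    edible at home); ``farmed_traded_supply`` the tidy supply of traded
    farmed-fish flows.  Trimmings scaling applies only to the fishmeal
    scenario.  Returns a tidy table: country, scenario, nutrient, supply
    person-equivalents, newly_met, plus per-country aggregates.
    """
    if not 0.0 <= trimmings_fraction <= 1.0:
        raise ValueError(f"trimmings fraction {trimmings_fraction} outside [0, 1]")

    tables = {
        "repurpose_fishmeal_exports": _pe_by_country(fishmeal_export_supply, "producer"),
        "retain_farmed_exports": _pe_by_country(farmed_traded_supply, "producer"),
        "actual_farmed_imports": _pe_by_country(farmed_traded_supply, "importer"),
    }
    tables["repurpose_fishmeal_exports"] = tables["repurpose_fishmeal_exports"].assign(
        person_equivalents=lambda d: d["person_equivalents"] * (1.0 - trimmings_fraction)
    )

    known = set(countries["iso3"])
    rows = []
    for scenario, table in tables.items():
        for country, grp in table.groupby("country"):
            if country not in known:
                logger.info("run_scenarios: skipping unknown country %s", country)
                continue
            pe = dict(zip(grp["nutrient"], grp["person_equivalents"]))
            result = newly_met_needs(country, pe, countries, scenario=scenario)
            for nutrient in NUTRIENTS:
                rows.append(
                    {
                        "country": country,
                        "scenario": scenario,
                        "nutrient": nutrient,
                        "person_equivalents": float(pe.get(nutrient, 0.0)),
                        "newly_met": result.newly_met[nutrient],
                        "mean_newly_met": result.mean_newly_met,
                        "fraction_of_population": result.fraction_of_population,
                        "fraction_of_vulnerable": result.fraction_of_vulnerable,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "country",
            "scenario",
            "nutrient",
            "person_equivalents",
            "newly_met",
            "mean_newly_met",
            "fraction_of_population",
            "fraction_of_vulnerable",
        ],
    )


def threshold_counts(
    results: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.03, 0.05, 0.10),
    elimination_fraction: float = 0.95,
) -> pd.DataFrame:
    """Countries per scenario clearing each newly-met population threshold.

    Counts countries whose newly-met fraction of TOTAL population exceeds
    each threshold, plus a "near elimination" count: countries meeting at
    least ``elimination_fraction`` of their vulnerable population.
    Counts are monotone non-increasing in the threshold.
    """
    per_country = results.drop_duplicates(["country", "scenario"])[
        ["country", "scenario", "fraction_of_population", "fraction_of_vulnerable"]
    ]
    rows = []
    for scenario, grp in per_country.groupby("scenario"):
        entry = {"scenario": scenario}
        for t in thresholds:
            entry[f"gt_{int(round(t * 100))}pct"] = int(
                (grp["fraction_of_population"] > t).sum()
            )
        entry["near_elimination"] = int(
            (grp["fraction_of_vulnerable"] >= elimination_fraction).sum()
        )
        rows.append(entry)
    return pd.DataFrame(rows)
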