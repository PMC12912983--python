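"""End-to-end orchestration: ingest -> supply -> fishmeal -> equity -> scenarios.

A single :class:`PipelineConfig` governs every stage; :func:`run_all`
executes them in order, writes every intermediate table under the output
directory, and records a machine-readable manifest (config hash, package
and library versions, seed, filter reports).  Identical config and inputs
produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import equity as eq
from . import fishmeal_model as fm
from . import io_model, nutrient_supply, scenarios as sc
from .types import FilterReport, Taxonomy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_dir: str
    out_dir: str
    year_range: tuple[int, int] = (2015, 2019)
    trimmings_fraction: float = 0.0
    equity_method: str = "categorical"
    band: float = 5.0
    vulnerability_threshold: float = 25.0
    weight_basis: str = "person_equivalents"
    include_domestic_fishmeal: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.equity_method not in ("categorical", "absolute"):
            raise ValueError(f"unknown equity method {self.equity_method!r}")
        if not 0.0 <= self.trimmings_fraction <= 1.0:
            raise ValueError("trimmings_fraction outside [0, 1]")
        self.year_range = tuple(self.year_range)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["year_range"] = list(self.year_range)
        return data


@dataclass
class IngestResult:
    flows: pd.DataFrame  # averaged, filtered canonical flows
    retained: pd.DataFrame
    traded: pd.DataFrame
    countries: pd.DataFrame
    taxonomy: Taxonomy
    taxa: pd.DataFrame
    observations: pd.DataFrame
    fcr: pd.DataFrame
    isscaap: pd.DataFrame
    fractions: dict[str, float]
    rda: pd.DataFrame
    filter_reports: list[FilterReport]
    parse_diagnostics: dict


@dataclass
class PipelineResult:
    config: PipelineConfig
    ingest: IngestResult
    profiles: pd.DataFrame
    supply: pd.DataFrame  # tidy, all flows
    retention: pd.DataFrame
    feed_mapping: pd.DataFrame
    feed_demand: pd.DataFrame
    allocation: fm.AllocationResult
    labeled: pd.DataFrame
    equity_summary: dict
    chains: pd.DataFrame
    scenario_results: pd.DataFrame
    scenario_counts: pd.DataFrame
    net_positions: pd.DataFrame
    summary: dict = field(default_factory=dict)


def ingest(config: PipelineConfig) -> IngestResult:
    """Read and harmonize every input table; filter and average the flows."""
    root = Path(config.input_dir)
    countries = io_model.read_country_table(root / "countries.csv")
    plant_algae_path = root / "plant_algae.json"
    plant_algae = (
        json.loads(plant_algae_path.read_text()) if plant_algae_path.exists() else []
    )
    parsed = io_model.read_trade_table(
        root / "trade_flows.csv", known_codes=countries["iso3"].unique()
    )
    filtered, reports = io_model.apply_exclusion_filters(
        parsed.flows, plant_algae_taxa=plant_algae
    )
    averaged = io_model.average_years(filtered, config.year_range)
    retained, traded = io_model.split_retained_traded(averaged)

    taxa = pd.read_csv(root / "taxa.csv")
    taxonomy = Taxonomy.from_frame(taxa)
    observations = nutrient_supply.read_observations(root / "nutrient_observations.csv")
    fcr = pd.read_csv(root / "fcr.csv").fillna({"members": ""})
    isscaap = pd.read_csv(root / "isscaap.csv").fillna({"members": ""})
    fractions = nutrient_supply.read_edible_fractions(root / "edible_fractions.csv")
    rda = nutrient_supply.read_rda_table(root / "rda.csv")
    return IngestResult(
        flows=averaged,
        retained=retained,
        traded=traded,
        countries=countries,
        taxonomy=taxonomy,
        taxa=taxa,
        observations=observations,
        fcr=fcr,
        isscaap=isscaap,
        fractions=fractions,
        rda=rda,
        filter_reports=reports,
        parse_diagnostics={
            "rejected": parsed.rejected,
            "unknown_codes": parsed.unknown_codes,
        },
    )


def _clean_observations(ing: IngestResult) -> pd.DataFrame:
    obs = nutrient_supply.filter_observations(ing.observations)
    return nutrient_supply.remove_outliers(obs)


def supply_stage(ing: IngestResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profiles and tidy nutrient supply for every averaged flow."""
    clean = _clean_observations(ing)
    flow_taxa = sorted(ing.flows["taxon"].unique())
    profiles = nutrient_supply.build_profiles(flow_taxa, clean, ing.taxonomy)
    fractions_by_taxon = {
        t: nutrient_supply.impute_edible_fraction(t, ing.fractions, ing.taxonomy)
        for t in flow_taxa
    }
    supply = nutrient_supply.compute_supply(
        ing.flows, profiles, fractions_by_taxon, ing.rda
    )
    return profiles, supply


def retention_stage(supply: pd.DataFrame) -> pd.DataFrame:
    """Retained share per commodity, by edible weight and by nutrient supply."""
    flows = supply
    retained_mask = (flows["producer"] == flows["exporter"]) & (
        flows["exporter"] == flows["importer"]
    )
    rows = []
    for commodity, grp in flows.groupby("commodity"):
        mask = retained_mask.loc[grp.index]
        # edible weight is repeated across the 14 nutrient rows of a flow;
        # the ratio is unaffected by the repetition
        weight_total = float(grp["edible_weight"].sum())
        live_total = float(grp["live_weight"].sum())
        pe_total = float(grp["person_equivalents"].sum())
        rows.append(
            {
                "commodity": commodity,
                "retained_live_share": (
                    float(grp.loc[mask, "live_weight"].sum()) / live_total
                    if live_total
                    else np.nan
                ),
                "retained_weight_share": (
                    float(grp.loc[mask, "edible_weight"].sum()) / weight_total
                    if weight_total
                    else np.nan
                ),
                "retained_nutrient_share": (
                    float(grp.loc[mask, "person_equivalents"].sum()) / pe_total
                    if pe_total
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def fishmeal_stage(
    ing: IngestResult, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, fm.AllocationResult]:
    """Feed demand of aquaculture production and fishmeal-flow allocation."""
    mapping, _ = fm.match_isscaap_to_fcr(ing.isscaap, ing.fcr)
    group_of = dict(zip(ing.taxa["name"], ing.taxa["isscaap_group"]))
    aqua = ing.flows.loc[
        (ing.flows["method"] == "aquaculture")
        & (ing.flows["commodity"] == "food_product")
    ].copy()
    aqua["isscaap_group"] = aqua["taxon"].map(group_of)
    production = (
        aqua.groupby(["producer", "isscaap_group"], dropna=True)["live_weight"]
        .sum()
        .reset_index()
        .rename(columns={"producer": "country"})
    )
    demand = fm.feed_demand(production, mapping)
    fishmeal_flows = ing.flows.loc[ing.flows["commodity"] == "fishmeal"]
    allocation = fm.allocate_fishmeal_flows(
        demand, fishmeal_flows, include_domestic=config.include_domestic_fishmeal
    )
    return mapping, demand, allocation


def equity_stage(
    ing: IngestResult,
    supply: pd.DataFrame,
    allocation: fm.AllocationResult,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Label traded flows and compute the headline equity statistics."""
    traded_mask = ~(
        (supply["producer"] == supply["exporter"])
        & (supply["exporter"] == supply["importer"])
    )
    traded = supply.loc[traded_mask & ~supply["code_flagged"]]
    labeled = eq.label_flows(
        traded,
        ing.countries,
        method=config.equity_method,
        band=config.band,
    )
    summary: dict = {"method": config.equity_method, "by_commodity": {}}
    for commodity, grp in labeled.groupby("commodity"):
        entry = {
            "shares": eq.equity_shares(grp, weight_col=config.weight_basis),
            "vulnerable_source_share": eq.vulnerable_source_share(
                traded.loc[traded["commodity"] == commodity],
                ing.countries,
                threshold=config.vulnerability_threshold,
                weight_col=config.weight_basis,
            ),
        }
        summary["by_commodity"][commodity] = entry

    # Per-nutrient fishmeal-to-aquaculture edges: allocation tonnes are
    # wild-fish live-weight equivalents, converted through the fishmeal
    # species' own profiles.
    chains = pd.DataFrame()
    if len(allocation.allocations):
        pseudo = allocation.allocations.rename(
            columns={"fishmeal_species": "taxon", "tonnes": "live_weight"}
        )
        clean = _clean_observations(ing)
        taxa = sorted(pseudo["taxon"].unique())
        profiles = nutrient_supply.build_profiles(taxa, clean, ing.taxonomy)
        fractions = {
            t: nutrient_supply.impute_edible_fraction(t, ing.fractions, ing.taxonomy)
            for t in taxa
        }
        fm_supply = nutrient_supply.compute_supply(pseudo, profiles, fractions, ing.rda)
        fm_edges = (
            fm_supply.groupby(["source_country", "country", "nutrient"])[
                "person_equivalents"
            ]
            .sum()
            .reset_index()
            .rename(columns={"person_equivalents": "tonnes"})
        )
        farmed = traded.loc[traded["commodity"] == "food_product"]
        chains = eq.build_supply_chains(
            fm_edges,
            farmed,
            ing.countries,
            method=config.equity_method,
            band=config.band,
        )
    return labeled, summary, chains


def scenario_stage(
    ing: IngestResult, supply: pd.DataFrame, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counterfactual retention/repurposing scenarios and net positions."""
    traded_mask = ~(
        (supply["producer"] == supply["exporter"])
        & (supply["exporter"] == supply["importer"])
    )
    traded = supply.loc[traded_mask & ~supply["code_flagged"]]
    fm_traded = traded.loc[traded["commodity"] == "fishmeal"]
    farmed_traded = traded.loc[traded["commodity"] == "food_product"]
    results = sc.run_scenarios(
        fm_traded,
        farmed_traded,
        ing.countries,
        trimmings_fraction=config.trimmings_fraction,
    )
    counts = sc.threshold_counts(results)

    roles = []
    for role, frame, col in (
        ("import", farmed_traded, "importer"),
        ("farmed_export", farmed_traded, "producer"),
        ("fishmeal_export", fm_traded, "producer"),
    ):
        part = (
            frame.groupby([col, "nutrient"])["person_equivalents"]
            .sum()
            .reset_index()
            .rename(columns={col: "country"})
        )
        part["role"] = role
        roles.append(part)
    net = sc.net_position(pd.concat(roles, ignore_index=True))
    return results, counts, net


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage, write all outputs, and return the result bundle."""
    logging.basicConfig(level=config.log_level)
    stage = "ingest"
    try:
        ing = ingest(config)
        stage = "supply"
        profiles, supply = supply_stage(ing)
        retention = retention_stage(supply)
        stage = "fishmeal"
        mapping, demand, allocation = fishmeal_stage(ing, config)
        stage = "equity"
        labeled, equity_summary, chains = equity_stage(ing, supply, allocation, config)
        stage = "scenarios"
        results, counts, net = scenario_stage(ing, supply, config)
    except Exception as err:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    result = PipelineResult(
        config=config,
        ingest=ing,
        profiles=profiles,
        supply=supply,
        retention=retention,
        feed_mapping=mapping,
        feed_demand=demand,
        allocation=allocation,
        labeled=labeled,
        equity_summary=equity_summary,
        chains=chains,
        scenario_results=results,
        scenario_counts=counts,
        net_positions=net,
    )
    result.summary = _build_summary(result)
    _write_outputs(result)
    return result


def _build_summary(result: PipelineResult) -> dict:
    retention = {
        row.commodity: {
            "weight_share_pct": row.retained_weight_share * 100.0,
            "nutrient_share_pct": row.retained_nutrient_share * 100.0,
        }
        for row in result.retention.itertuples(index=False)
    }
    net = result.net_positions.drop_duplicates("country")[["country", "net_median"]]
    gainers = net.sort_values(["net_median", "country"], ascending=[False, True]).head(5)
    losers = net.sort_values(["net_median", "country"], ascending=[True, True]).head(5)
    return {
        "retention": retention,
        "equity": result.equity_summary,
        "top_net_gainers": dict(
            zip(gainers["country"], gainers["net_median"].round(3))
        ),
        "top_net_losers": dict(zip(losers["country"], losers["net_median"].round(3))),
        "scenario_threshold_counts": result.scenario_counts.to_dict("records"),
        "unsourced_demand_cells": int(len(result.allocation.unsourced)),
    }


def _write_outputs(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = {"index": False, "float_format": "%.10g"}
    result.ingest.flows.to_csv(out / "flows_clean.csv", **fmt)
    result.profiles.to_csv(out / "profiles.csv", **fmt)
    result.supply.to_csv(out / "supply.csv", **fmt)
    result.retention.to_csv(out / "retention.csv", **fmt)
    result.feed_demand.to_csv(out / "feed_demand.csv", **fmt)
    result.allocation.allocations.to_csv(out / "allocation.csv", **fmt)
    result.allocation.unsourced.to_csv(out / "allocation_unsourced.csv", **fmt)
    result.labeled.to_csv(out / "equity_labels.csv", **fmt)
    result.chains.to_csv(out / "supply_chains.csv", **fmt)
    result.scenario_results.to_csv(out / "scenarios.csv", **fmt)
    result.scenario_counts.to_csv(out / "scenario_counts.csv", **fmt)
    result.net_positions.to_csv(out / "net_positions.csv", **fmt)
    (out / "equity_summary.json").write_text(
        json.dumps(result.equity_summary, sort_keys=True, indent=1)
    )
    (out / "filter_reports.json").write_text(
        json.dumps(
            [dataclasses.asdict(r) for r in result.ingest.filter_reports], indent=1
        )
    )
    (out / "summary.json").write_text(
        json.dumps(result.summary, sort_keys=True, indent=1)
    )
    config_dict = result.config.to_dict()
    manifest = {
        "config": config_dict,
        "config_hash": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": result.config.seed,
        "versions": {
            "nutriflow": __version__,
            "pandas": pd.__version__,
            "numpy": np.__version__,
        },
        "filter_reports": [dataclasses.asdict(r) for r in result.ingest.filter_reports],
        "n_flows": int(len(result.ingest.flows)),
        "n_supply_rows": int(len(result.supply)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))


def report_summary(result: PipelineResult) -> str:
    """Human-readable headline statistics of a run."""
    lines = ["nutriflow run summary", "====================="]
    for commodity, entry in result.summary["retention"].items():
        lines.append(
            f"retention [{commodity}]: {entry['weight_share_pct']:.1f}% of edible weight, "
            f"{entry['nutrient_share_pct']:.1f}% of nutrients"
        )
    by_commodity = result.summary["equity"]["by_commodity"]
    if not by_commodity:
        lines.append("equity: undefined (no traded flows)")
    for commodity, entry in by_commodity.items():
        shares = entry["shares"]
        lines.append(
            f"equity [{commodity}] ({result.summary['equity']['method']}): "
            f"inequitable {shares['inequitable']:.1f}%, same {shares['same']:.1f}%, "
            f"equitable {shares['equitable']:.1f}%; "
            f"vulnerable-source {entry['vulnerable_source_share']:.1f}%"
        )
    lines.append(f"top net gainers (median pe): {result.summary['top_net_gainers']}")
    lines.append(f"top net losers (median pe): {result.summary['top_net_losers']}")
    for entry in result.summary["scenario_threshold_counts"]:
        lines.append(f"scenario counts: {entry}")
    return "\n".join(lines)
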