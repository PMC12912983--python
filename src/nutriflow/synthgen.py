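"""Synthetic worlds with the statistical structure the pipeline assumes.

A world is the full input bundle — yearly bilateral trade flows, noisy
multi-study nutrient observations over a taxonomic hierarchy, a country
vulnerability table spanning all five bins, feed-parameter and
edible-fraction tables, and the RDA table — plus a ``truth`` record of
quantities recomputed independently by brute force at generation time
(retention fractions, equity shares, vulnerable-source shares, net-position
signs), so pipeline output can be checked against planted ground truth.

The real databases these tables emulate are species-level bilateral trade
records and multi-study composition observations; the generator reproduces
their load-bearing features — a heavy-tailed exporter size distribution
(a handful of exporters dominating trade), dispersed importers, noisy
observations with planted outliers, and species lacking species-level
composition data (exercising the taxonomic fallback) — not their actual
marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import NUTRIENT_UNITS, NUTRIENTS
from .equity import classify_frame

YEARS_DEFAULT: tuple[int, int] = (2015, 2019)

#: Default daily RDAs for women aged 14-50, canonical units (mg or ug).
RDA_DEFAULTS: dict[str, float] = {
    "calcium": 1000.0,
    "folate": 400.0,
    "iodine": 150.0,
    "iron": 18.0,
    "magnesium": 320.0,
    "niacin": 14.0,
    "selenium": 55.0,
    "thiamin": 1.1,
    "vitamin_a": 700.0,
    "vitamin_b2": 1.1,
    "vitamin_b6": 1.3,
    "vitamin_b12": 2.4,
    "vitamin_e": 15.0,
    "zinc": 8.0,
}

#: Typical raw-muscle concentrations per 100 g used as generator scales.
CONCENTRATION_SCALES: dict[str, float] = {
    "calcium": 50.0,
    "folate": 15.0,
    "iodine": 30.0,
    "iron": 1.5,
    "magnesium": 30.0,
    "niacin": 3.0,
    "selenium": 40.0,
    "thiamin": 0.1,
    "vitamin_a": 30.0,
    "vitamin_b2": 0.15,
    "vitamin_b6": 0.3,
    "vitamin_b12": 3.0,
    "vitamin_e": 1.0,
    "zinc": 1.0,
}

#: The 12 feed taxa with feed conversion ratio and fishmeal+oil proportion.
FCR_DEFAULTS: tuple[tuple[str, float, float], ...] = (
    ("bivalves", 0.0, 0.0),
    ("carp", 1.7, 0.03),
    ("tilapia", 1.6, 0.05),
    ("salmon", 1.3, 0.25),
    ("trout", 1.4, 0.25),
    ("shrimp", 1.6, 0.18),
    ("milkfish", 2.0, 0.05),
    ("catfish", 1.5, 0.05),
    ("eel", 2.1, 0.35),
    ("marine fish", 1.9, 0.20),
    ("freshwater crustaceans", 1.8, 0.12),
    ("other fish", 1.7, 0.10),
)


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; the seed fixes every draw."""

    n_countries: int = 40
    n_species: int = 60
    n_groups: int = 22  # edible-fraction species groups
    seed: int = 0
    exporter_concentration: float = 2.0  # sigma of log-normal export volumes
    retention_rate_by_commodity: dict[str, float] = field(
        default_factory=lambda: {"food_product": 0.777, "fishmeal": 0.371}
    )
    vulnerability_spread: float = 1.0  # within-bin spread of prevalences
    outlier_rate: float = 0.03
    missingness: float = 0.2  # fraction of species with no species-level obs
    years: tuple[int, int] = YEARS_DEFAULT

    def __post_init__(self) -> None:
        for name in ("outlier_rate", "missingness"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for commodity, rate in self.retention_rate_by_commodity.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"retention rate for {commodity} outside [0, 1]")
        if self.n_countries < 4 or self.n_species < 1 or self.n_groups < 1:
            raise ValueError("degenerate world size")


@dataclass
class World:
    """A complete synthetic input bundle plus planted ground truth."""

    config: WorldConfig
    flows: pd.DataFrame  # yearly flow rows (CSV-level)
    taxa: pd.DataFrame
    observations: pd.DataFrame
    countries: pd.DataFrame
    fcr: pd.DataFrame
    isscaap: pd.DataFrame
    edible_fractions: pd.DataFrame
    rda: pd.DataFrame
    plant_algae: list[str]
    truth: dict
    year_range: tuple[int, int]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in (
            ("trade_flows", self.flows),
            ("taxa", self.taxa),
            ("nutrient_observations", self.observations),
            ("countries", self.countries),
            ("fcr", self.fcr),
            ("isscaap", self.isscaap),
            ("edible_fractions", self.edible_fractions),
            ("rda", self.rda),
        ):
            frame.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        (out / "plant_algae.json").write_text(json.dumps(self.plant_algae))
        (out / "truth.json").write_text(json.dumps(self.truth, sort_keys=True, indent=1))


def _country_codes(n: int) -> list[str]:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    codes = []
    for a in letters:
        for b in letters:
            for c in letters:
                codes.append(a + b + c)
                if len(codes) == n:
                    return codes
    raise ValueError("too many countries requested")


def _make_countries(cfg: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    codes = _country_codes(cfg.n_countries)
    population = np.round(10 ** rng.uniform(5.5, 8.5, size=cfg.n_countries))
    bounds = [(0.0, 5.0), (5.0, 10.0), (10.0, 25.0), (25.0, 50.0), (50.0, 100.0)]
    rows = []
    for nutrient in NUTRIENTS:
        order = rng.permutation(cfg.n_countries)
        for slot, idx in enumerate(order):
            lo, hi = bounds[slot % 5]
            width = (hi - lo) * min(cfg.vulnerability_spread, 1.0)
            mid = (lo + hi) / 2.0
            prev = rng.uniform(mid - width / 2.0, mid + width / 2.0)
            rows.append(
                {
                    "iso3": codes[idx],
                    "population": population[idx],
                    "nutrient": nutrient,
                    "prevalence": round(float(np.clip(prev, 0.0, 100.0)), 4),
                }
            )
    return pd.DataFrame(rows)


def _make_taxonomy(cfg: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_sp = cfg.n_species
    n_gen = max(4, n_sp // 3)
    n_fam = max(3, n_sp // 6)
    n_ord = max(2, n_fam // 2)
    n_cls = max(2, n_ord // 2)
    phyla = ["Chordata", "Mollusca"]
    classes = [f"Class{i:02d}" for i in range(n_cls)]
    orders = [f"Order{i:02d}" for i in range(n_ord)]
    families = [f"Family{i:02d}" for i in range(n_fam)]
    genera = [f"Genus{i:02d}" for i in range(n_gen)]

    cls_phy = {c: phyla[i % 2] for i, c in enumerate(classes)}
    ord_cls = {o: classes[rng.integers(n_cls)] for o in orders}
    fam_ord = {f: orders[rng.integers(n_ord)] for f in families}
    gen_fam = {g: families[rng.integers(n_fam)] for g in genera}

    rows = []
    species = [f"Species{i:03d}" for i in range(n_sp)]
    for i, sp in enumerate(species):
        g = genera[i % n_gen]
        f = gen_fam[g]
        o = fam_ord[f]
        c = ord_cls[o]
        p = cls_phy[c]
        rows.append(
            {"name": sp, "rank": "species", "lineage": ";".join([sp, g, f, o, c, p])}
        )
    seen: set[str] = set()
    for g in genera:
        f = gen_fam[g]
        o = fam_ord[f]
        c = ord_cls[o]
        rows.append(
            {
                "name": g,
                "rank": "genus",
                "lineage": ";".join([g, f, o, c, cls_phy[c]]),
            }
        )
    for f in families:
        o = fam_ord[f]
        c = ord_cls[o]
        rows.append(
            {"name": f, "rank": "family", "lineage": ";".join([f, o, c, cls_phy[c]])}
        )
    for o in orders:
        c = ord_cls[o]
        rows.append({"name": o, "rank": "order", "lineage": ";".join([o, c, cls_phy[c]])})
    for c in classes:
        rows.append({"name": c, "rank": "class", "lineage": ";".join([c, cls_phy[c]])})
    for p in phyla:
        if p not in seen:
            rows.append({"name": p, "rank": "phylum", "lineage": p})
            seen.add(p)
    frame = pd.DataFrame(rows)
    frame["isscaap_group"] = None
    frame["edible_group"] = None
    return frame


def _assign_groups(
    taxa: pd.DataFrame, cfg: WorldConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Assign ISSCAAP and edible groups; build the FCR and ISSCAAP tables."""
    species = taxa.loc[taxa["rank"] == "species", "name"].tolist()
    n_sp = len(species)

    # ISSCAAP-style group labels; most mention a feed taxon explicitly,
    # the bivalve and flatfish groups exercise the member-subset rules,
    # and the last group is deliberately unmatched.
    group_labels = [
        "carps, barbels and other cyprinids",
        "tilapias and other cichlids",
        "salmons, trouts, smelts",
        "shrimps, prawns",
        "milkfishes",
        "catfishes",
        "river eels",
        "oysters, mussels and clams",  # matched through members (bivalves)
        "flounders, halibuts, soles",  # subset of the marine fish feed taxon
        "miscellaneous aquatic invertebrates",  # no feed parameters
    ]
    assignment = [group_labels[i % len(group_labels)] for i in range(n_sp)]
    members: dict[str, list[str]] = {g: [] for g in group_labels}
    for sp, g in zip(species, assignment):
        members[g].append(sp)

    fcr_rows = []
    for name, fcr_value, p_fmfo in FCR_DEFAULTS:
        if name == "bivalves":
            mem = members["oysters, mussels and clams"]
        elif name == "marine fish":
            mem = members["flounders, halibuts, soles"] + ["SpeciesExtraMarine"]
        else:
            mem = []
        fcr_rows.append(
            {
                "taxon_group": name,
                "members": ";".join(mem),
                "fcr": fcr_value,
                "p_fmfo": p_fmfo,
            }
        )
    fcr = pd.DataFrame(fcr_rows)
    isscaap = pd.DataFrame(
        [{"group": g, "members": ";".join(m)} for g, m in members.items()]
    )

    edible_groups = [f"edible_group_{i:02d}" for i in range(cfg.n_groups)]
    fractions = pd.DataFrame(
        {
            "group": edible_groups,
            "fraction": np.round(rng.uniform(0.3, 0.6, size=cfg.n_groups), 4),
        }
    )

    taxa = taxa.copy().set_index("name")
    for i, sp in enumerate(species):
        taxa.at[sp, "isscaap_group"] = assignment[i]
        # ~10% of species lack an edible-group mapping (taxonomic fallback);
        # the first species of each phylum stays mapped so fallback resolves.
        if rng.random() < 0.1 and i >= 2:
            continue
        taxa.at[sp, "edible_group"] = edible_groups[i % cfg.n_groups]
    return taxa.reset_index(), fcr, isscaap, fractions


def _make_observations(
    taxa: pd.DataFrame, cfg: WorldConfig, rng: np.random.Generator
) -> pd.DataFrame:
    species = taxa.loc[taxa["rank"] == "species"]
    fam_of = {
        row.name: row.lineage.split(";")[2] for row in species.itertuples(index=False)
    }
    gen_of = {
        row.name: row.lineage.split(";")[1] for row in species.itertuples(index=False)
    }
    families = sorted(set(fam_of.values()))
    fam_mult = {
        f: {n: float(rng.lognormal(0.0, 0.4)) for n in NUTRIENTS} for f in families
    }
    missing = set(
        rng.choice(
            species["name"].to_numpy(),
            size=int(round(cfg.missingness * len(species))),
            replace=False,
        )
    )
    rows = []
    for sp in species["name"]:
        target = gen_of[sp] if sp in missing else sp
        for nutrient in NUTRIENTS:
            base = CONCENTRATION_SCALES[nutrient] * fam_mult[fam_of[sp]][nutrient]
            base *= float(rng.lognormal(0.0, 0.3))
            n_obs = int(rng.integers(2, 7))
            for _ in range(n_obs):
                value = base * float(rng.lognormal(0.0, 0.2))
                if rng.random() < cfg.outlier_rate:
                    value *= 8.0
                rows.append(
                    {
                        "taxon": target,
                        "nutrient": nutrient,
                        "part": "muscle_tissue",
                        "preparation": "raw",
                        "value": round(value, 6),
                        "unit": NUTRIENT_UNITS[nutrient],
                    }
                )
            # non-raw / non-muscle strata that the preparation filter drops
            if rng.random() < 0.3:
                rows.append(
                    {
                        "taxon": target,
                        "nutrient": nutrient,
                        "part": "viscera" if rng.random() < 0.5 else "muscle_tissue",
                        "preparation": "cooked",
                        "value": round(base * 2.0, 6),
                        "unit": NUTRIENT_UNITS[nutrient],
                    }
                )
    return pd.DataFrame(rows)


def _yearly_weights(
    base: float, years: tuple[int, int], rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Per-year weights whose mean over the range equals ``base`` exactly."""
    lo, hi = years
    span = list(range(lo, hi + 1))
    n = len(span)
    if n == 1:
        return [(lo, base)]
    jitters = rng.uniform(0.9, 1.1, size=n - 1)
    last = n - float(jitters.sum())
    weights = [base * j for j in jitters] + [base * last]
    return list(zip(span, weights))


def generate_world(config: WorldConfig) -> World:
    """Generate a complete input bundle with planted ground truth.

    The clean averaged flow set is constructed first and the truth record
    derived from it by brute-force loops; yearly rows are then expanded so
    that the five-year mean reproduces the clean set exactly, and junk rows
    (aquaculture-sourced fishmeal, fish oil, algae, producer-less exports)
    are appended for the exclusion filters to remove.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    countries = _make_countries(cfg, rng)
    codes = countries["iso3"].unique().tolist()
    taxa = _make_taxonomy(cfg, rng)
    taxa, fcr, isscaap, fractions = _assign_groups(taxa, cfg, rng)
    observations = _make_observations(taxa, cfg, rng)
    rda = pd.DataFrame(
        {
            "nutrient": list(NUTRIENTS),
            "unit": [NUTRIENT_UNITS[n] for n in NUTRIENTS],
            "daily_rda": [RDA_DEFAULTS[n] for n in NUTRIENTS],
        }
    )

    species = taxa.loc[taxa["rank"] == "species", "name"].tolist()
    # Species roles: most are farmed food species; a slice are wild
    # reduction-fishery species that become fishmeal.
    n_reduction = max(2, len(species) // 6)
    reduction = set(species[-n_reduction:])
    farmed = [s for s in species if s not in reduction]

    # Heavy-tailed producer sizes: producer chosen by a skewed distribution
    # and volumes log-normal, so a few exporters dominate trade.
    producer_weights = rng.dirichlet(np.full(len(codes), 0.3))
    base_rows = []
    for sp in farmed:
        producer = str(rng.choice(codes, p=producer_weights))
        volume = float(rng.lognormal(8.0, cfg.exporter_concentration))
        retention = float(
            np.clip(
                cfg.retention_rate_by_commodity["food_product"]
                + rng.uniform(-0.1, 0.1),
                0.0,
                1.0,
            )
        )
        retained = volume * retention
        if retained > 0:
            base_rows.append((producer, producer, producer, sp, "aquaculture", "food_product", retained))
        traded = volume - retained
        if traded > 0:
            k = int(rng.integers(2, 7))
            partners = [c for c in codes if c != producer]
            importers = rng.choice(partners, size=min(k, len(partners)), replace=False)
            shares = rng.dirichlet(np.full(len(importers), 0.5))
            for imp, share in zip(importers, shares):
                base_rows.append(
                    (producer, producer, str(imp), sp, "aquaculture", "food_product", traded * float(share))
                )
    aqua_producers = sorted({r[0] for r in base_rows})
    for sp in reduction:
        producer = str(rng.choice(codes, p=producer_weights))
        volume = float(rng.lognormal(8.5, cfg.exporter_concentration))
        retention = float(
            np.clip(
                cfg.retention_rate_by_commodity["fishmeal"] + rng.uniform(-0.1, 0.1),
                0.0,
                1.0,
            )
        )
        retained = volume * retention
        if retained > 0:
            base_rows.append((producer, producer, producer, sp, "capture", "fishmeal", retained))
        traded = volume - retained
        if traded > 0:
            k = int(rng.integers(2, 5))
            candidates = [c for c in aqua_producers if c != producer] or [
                c for c in codes if c != producer
            ]
            importers = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
            shares = rng.dirichlet(np.full(len(importers), 0.5))
            for imp, share in zip(importers, shares):
                base_rows.append(
                    (producer, producer, str(imp), sp, "capture", "fishmeal", traded * float(share))
                )

    base = pd.DataFrame(
        base_rows,
        columns=["producer", "exporter", "importer", "taxon", "method", "commodity", "live_weight"],
    )
    truth = _brute_force_truth(base, countries)

    # Expand to yearly rows whose range mean equals the base weights.
    yearly_rows = []
    for row in base.itertuples(index=False):
        for year, weight in _yearly_weights(row.live_weight, cfg.years, rng):
            yearly_rows.append(
                {
                    "year": year,
                    "producer": row.producer,
                    "exporter": row.exporter,
                    "importer": row.importer,
                    "taxon": row.taxon,
                    "method": row.method,
                    "commodity": row.commodity,
                    "live_weight": round(weight, 6),
                }
            )

    # Junk rows for the exclusion filters.
    plant_algae = ["Ulva_lactuca", "Saccharina_japonica"]
    algae_taxa = pd.DataFrame(
        {
            "name": plant_algae,
            "rank": ["species"] * 2,
            "lineage": [f"{p};AlgaeFamily;AlgaeOrder;AlgaeClass" for p in plant_algae],
            "isscaap_group": [None, None],
            "edible_group": [None, None],
        }
    )
    taxa = pd.concat([taxa, algae_taxa], ignore_index=True)
    lo = cfg.years[0]
    junk = [
        {"year": lo, "producer": codes[0], "exporter": codes[0], "importer": codes[1],
         "taxon": farmed[0], "method": "aquaculture", "commodity": "fishmeal",
         "live_weight": 500.0},
        {"year": lo, "producer": codes[2], "exporter": codes[2], "importer": codes[3],
         "taxon": sorted(reduction)[0], "method": "capture", "commodity": "fish_oil",
         "live_weight": 300.0},
        {"year": lo, "producer": codes[1], "exporter": codes[1], "importer": codes[2],
         "taxon": plant_algae[0], "method": "aquaculture", "commodity": "food_product",
         "live_weight": 200.0},
        {"year": lo, "producer": "", "exporter": codes[3], "importer": codes[4],
         "taxon": farmed[0], "method": "capture", "commodity": "food_product",
         "live_weight": 400.0},
    ]
    flows = pd.concat([pd.DataFrame(yearly_rows), pd.DataFrame(junk)], ignore_index=True)

    return World(
        config=cfg,
        flows=flows,
        taxa=taxa,
        observations=observations,
        countries=countries,
        fcr=fcr,
        isscaap=isscaap,
        edible_fractions=fractions,
        rda=rda,
        plant_algae=plant_algae,
        truth=truth,
        year_range=cfg.years,
    )


def _brute_force_truth(base: pd.DataFrame, countries: pd.DataFrame) -> dict:
    """Recompute the planted quantities with plain loops over the base flows.

    All shares are on a live-weight basis; equity and vulnerable-source
    shares are per nutrient because prevalence varies by nutrient.
    """
    prev: dict[tuple[str, str], float] = {
        (r.iso3, r.nutrient): float(r.prevalence) for r in countries.itertuples(index=False)
    }
    truth: dict = {"retention": {}, "inequitable_share": {}, "vulnerable_source_share": {}}
    for commodity in sorted(base["commodity"].unique()):
        sub = base.loc[base["commodity"] == commodity]
        total = float(sub["live_weight"].sum())
        retained = 0.0
        for row in sub.itertuples(index=False):
            if row.producer == row.exporter == row.importer:
                retained += row.live_weight
        truth["retention"][commodity] = retained / total if total else float("nan")

        traded = sub.loc[
            ~(
                (sub["producer"] == sub["exporter"])
                & (sub["exporter"] == sub["importer"])
            )
        ]
        ineq: dict[str, float] = {}
        vuln: dict[str, float] = {}
        for nutrient in NUTRIENTS:
            tot = ineq_w = vuln_w = 0.0
            for row in traded.itertuples(index=False):
                i_s = prev.get((row.producer, nutrient))
                i_d = prev.get((row.importer, nutrient))
                if i_s is None or i_d is None:
                    continue
                tot += row.live_weight
                label = classify_frame([i_s], [i_d], method="categorical")[0]
                if label == "inequitable":
                    ineq_w += row.live_weight
                if i_s > 25.0:
                    vuln_w += row.live_weight
            ineq[nutrient] = ineq_w / tot * 100.0 if tot else float("nan")
            vuln[nutrient] = vuln_w / tot * 100.0 if tot else float("nan")
        truth["inequitable_share"][commodity] = ineq
        truth["vulnerable_source_share"][commodity] = vuln

    # Net live-weight position: farmed imports minus farmed + fishmeal exports.
    net: dict[str, float] = {}
    for row in base.itertuples(index=False):
        if row.producer == row.exporter == row.importer:
            continue
        if row.commodity == "food_product":
            net[row.importer] = net.get(row.importer, 0.0) + row.live_weight
        net[row.producer] = net.get(row.producer, 0.0) - row.live_weight
    truth["net_sign"] = {c: int(np.sign(v)) for c, v in sorted(net.items())}
    return truth


def plant_equity_structure(
    config: WorldConfig, target_inequitable_share: float
) -> World:
    """World whose weighted inequitable share equals the target exactly.

    Two traded flows of one species carry weights ``target`` and
    ``100 - target``: the first from a very-high-prevalence source to a
    very-low one (inequitable under both rules), the second between two
    identical medium-bin countries ("same").  Nutrient concentrations and
    RDAs are uniform, so person-equivalent weighting coincides with
    live-weight weighting and the recovered share is exact under either
    basis.
    """
    t = float(target_inequitable_share)
    if not 0.0 <= t <= 100.0:
        raise ValueError(f"target share {t} outside [0, 100]")

    codes = ["SRA", "SRB", "SRC", "SRD"]
    prevalences = {"SRA": 60.0, "SRB": 2.0, "SRC": 15.0, "SRD": 15.0}
    countries = pd.DataFrame(
        [
            {"iso3": c, "population": 1_000_000, "nutrient": n, "prevalence": prevalences[c]}
            for c in codes
            for n in NUTRIENTS
        ]
    )
    sp = "Planted_species"
    taxa = pd.DataFrame(
        [
            {
                "name": sp,
                "rank": "species",
                "lineage": f"{sp};PlantedGenus;PlantedFamily;PlantedOrder;PlantedClass;Chordata",
                "isscaap_group": "planted group",
                "edible_group": "planted_edible",
            },
            {"name": "PlantedGenus", "rank": "genus",
             "lineage": "PlantedGenus;PlantedFamily;PlantedOrder;PlantedClass;Chordata",
             "isscaap_group": None, "edible_group": None},
        ]
    )
    observations = pd.DataFrame(
        [
            {"taxon": sp, "nutrient": n, "part": "muscle_tissue",
             "preparation": "raw", "value": 1.0, "unit": NUTRIENT_UNITS[n]}
            for n in NUTRIENTS
        ]
    )
    rda = pd.DataFrame(
        {"nutrient": list(NUTRIENTS), "unit": [NUTRIENT_UNITS[n] for n in NUTRIENTS],
         "daily_rda": [1.0] * len(NUTRIENTS)}
    )
    fractions = pd.DataFrame({"group": ["planted_edible"], "fraction": [0.5]})

    year = config.years[0]
    rows = []
    if t > 0:
        rows.append({"year": year, "producer": "SRA", "exporter": "SRA", "importer": "SRB",
                     "taxon": sp, "method": "aquaculture", "commodity": "food_product",
                     "live_weight": t})
    if t < 100:
        rows.append({"year": year, "producer": "SRC", "exporter": "SRC", "importer": "SRD",
                     "taxon": sp, "method": "aquaculture", "commodity": "food_product",
                     "live_weight": 100.0 - t})
    flows = pd.DataFrame(rows)

    truth = {
        "retention": {"food_product": 0.0},
        "inequitable_share": {"food_product": {n: t for n in NUTRIENTS}},
        "vulnerable_source_share": {"food_product": {n: t for n in NUTRIENTS}},
        "net_sign": {},
    }
    fcr = pd.DataFrame(
        [{"taxon_group": name, "members": "", "fcr": f, "p_fmfo": p} for name, f, p in FCR_DEFAULTS]
    )
    isscaap = pd.DataFrame([{"group": "planted group", "members": sp}])
    return World(
        config=config,
        flows=flows,
        taxa=taxa,
        observations=observations,
        countries=countries,
        fcr=fcr,
        isscaap=isscaap,
        edible_fractions=fractions,
        rda=rda,
        plant_algae=[],
        truth=truth,
        year_range=(year, year),
    )
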