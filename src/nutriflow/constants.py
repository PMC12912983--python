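"""Shared constants: the nutrient set, canonical units, ranks, and conversion factors.

All nutrient concentrations are carried internally in a canonical unit per
nutrient (mg or ug per 100 g of edible weight); inputs in the other unit
family are converted on ingest.
"""

from __future__ import annotations

#: The 14 nutrients tracked by the pipeline (6 minerals, 8 vitamins).
NUTRIENTS: tuple[str, ...] = (
    "calcium",
    "folate",
    "iodine",
    "iron",
    "magnesium",
    "niacin",
    "selenium",
    "thiamin",
    "vitamin_a",
    "vitamin_b2",
    "vitamin_b6",
    "vitamin_b12",
    "vitamin_e",
    "zinc",
)

#: Canonical unit per nutrient ("mg" or "ug" per 100 g edible weight).
NUTRIENT_UNITS: dict[str, str] = {
    "calcium": "mg",
    "folate": "ug",
    "iodine": "ug",
    "iron": "mg",
    "magnesium": "mg",
    "niacin": "mg",
    "selenium": "ug",
    "thiamin": "mg",
    "vitamin_a": "ug",
    "vitamin_b2": "mg",
    "vitamin_b6": "mg",
    "vitamin_b12": "ug",
    "vitamin_e": "mg",
    "zinc": "mg",
}

#: Factors to convert between mg and ug.
UNIT_FACTORS: dict[tuple[str, str], float] = {
    ("mg", "mg"): 1.0,
    ("ug", "ug"): 1.0,
    ("mg", "ug"): 1000.0,
    ("ug", "mg"): 0.001,
}

#: Taxonomic ranks ordered from most to least specific.
RANKS: tuple[str, ...] = ("species", "genus", "family", "order", "class", "phylum")

#: Live-weight conversion factor for fishmeal: tonnes of wild-fish live
#: weight embodied in one tonne of fishmeal product.
LWC_FM: float = 2.98

DAYS_PER_YEAR: int = 365

#: Production methods and commodity classes recognised in trade records.
METHODS: tuple[str, ...] = ("aquaculture", "capture")
COMMODITIES: tuple[str, ...] = ("fishmeal", "food_product", "fish_oil")

#: Number of 100 g portions in one tonne (1 t = 1e6 g).
PORTIONS_PER_TONNE: float = 1e4
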