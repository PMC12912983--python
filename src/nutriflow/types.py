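"""Canonical in-memory data model: taxa, taxonomy index, and report records.

Tables (trade flows, nutrient observations, country vulnerability, feed
parameters) are carried as pandas DataFrames with documented column sets;
the record classes here cover the structured objects that do not fit a flat
table: a taxon with its lineage, the taxonomy index used for fallback
matching, and small report/result records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import RANKS


@dataclass(frozen=True)
class TaxonRecord:
    """A taxon with its upward lineage.

    ``lineage`` starts at the taxon itself and walks toward phylum; the rank
    of ``lineage[i]`` is ``RANKS[RANKS.index(rank) + i]``, so a genus-rank
    taxon has a lineage starting at genus.
    """

    name: str
    rank: str
    lineage: tuple[str, ...]
    isscaap_group: str | None = None
    edible_group: str | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS and self.rank != "group":
            raise ValueError(f"unknown rank {self.rank!r} for taxon {self.name!r}")
        if not self.lineage:
            raise ValueError(f"empty lineage for taxon {self.name!r}")
        if self.lineage[0] != self.name:
            raise ValueError(
                f"lineage of {self.name!r} must start at the taxon itself"
            )
        if self.rank in RANKS:
            n_above = len(RANKS) - RANKS.index(self.rank)
            if len(self.lineage) > n_above:
                raise ValueError(
                    f"lineage of {self.name!r} is longer than the ranks above {self.rank!r}"
                )

    def ancestor_ranks(self) -> tuple[str, ...]:
        """Ranks of each lineage entry, most specific first."""
        start = RANKS.index(self.rank) if self.rank in RANKS else 0
        return RANKS[start : start + len(self.lineage)]


class Taxonomy:
    """Index of TaxonRecords with ancestor/descendant lookup.

    Used for the taxonomic-fallback rules: when a species has no nutrient
    observation (or edible-fraction mapping) of its own, the pipeline walks
    the lineage upward and pools everything recorded under the first
    ancestor that has data.
    """

    def __init__(self, records: list[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        self._descendants: dict[str, set[str]] = {}
        for rec in records:
            if rec.name in self._records:
                raise ValueError(f"duplicate taxon {rec.name!r}")
            self._records[rec.name] = rec
        for rec in records:
            for ancestor in rec.lineage:
                self._descendants.setdefault(ancestor, set()).add(rec.name)

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def get(self, name: str) -> TaxonRecord:
        try:
            return self._records[name]
        except KeyError:
            raise KeyError(f"taxon {name!r} not present in taxonomy") from None

    def names(self) -> list[str]:
        return list(self._records)

    def descendants(self, ancestor: str) -> set[str]:
        """All taxa whose lineage passes through ``ancestor`` (incl. itself)."""
        return set(self._descendants.get(ancestor, set()))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Taxonomy":
        """Build from a table with columns name, rank, lineage (';'-joined),
        and optional isscaap_group / edible_group."""
        records = []
        for row in frame.itertuples(index=False):
            lineage = tuple(str(part).strip() for part in str(row.lineage).split(";"))
            isscaap = getattr(row, "isscaap_group", None)
            edible = getattr(row, "edible_group", None)
            records.append(
                TaxonRecord(
                    name=str(row.name),
                    rank=str(row.rank),
                    lineage=lineage,
                    isscaap_group=None if pd.isna(isscaap) else str(isscaap),
                    edible_group=None if pd.isna(edible) else str(edible),
                )
            )
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": rec.name,
                "rank": rec.rank,
                "lineage": ";".join(rec.lineage),
                "isscaap_group": rec.isscaap_group,
                "edible_group": rec.edible_group,
            }
            for rec in self._records.values()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of one exclusion rule applied to the flow table."""

    rule: str
    records_dropped: int
    weight_dropped_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_dropped_fraction <= 1.0:
            raise ValueError("weight_dropped_fraction must lie in [0, 1]")


@dataclass
class ParseResult:
    """Result of reading a trade table: parsed flows plus diagnostics."""

    flows: pd.DataFrame
    rejected: list[str] = field(default_factory=list)
    unknown_codes: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class NutrientProfile:
    """Per-taxon mean nutrient concentrations (canonical unit per 100 g).

    ``match_rank`` records, per nutrient, the taxonomic rank at which the
    value was found; nutrients missing at every level are absent from all
    three maps.
    """

    taxon: str
    values: dict[str, float]
    match_rank: dict[str, str]
    n_obs: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.values) != set(self.match_rank) or set(self.values) != set(self.n_obs):
            raise ValueError("values, match_rank and n_obs must share keys")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("nutrient concentrations must be >= 0")
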