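"""Feed-parameter matching, the fishmeal demand formula, and allocation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutriflow import fishmeal_model as fm
from nutriflow.constants import LWC_FM


def _fcr(rows):
    return pd.DataFrame(rows, columns=["taxon_group", "members", "fcr", "p_fmfo"])


def _isscaap(rows):
    return pd.DataFrame(rows, columns=["group", "members"])


class TestMatching:
    def test_explicit_mention_in_label(self):
        mapping, unmatched = fm.match_isscaap_to_fcr(
            _isscaap([("salmons, trouts, smelts", "Salmo salar")]),
            _fcr([("salmon", "", 1.3, 0.25)]),
        )
        assert unmatched == []
        assert mapping.iloc[0]["rule"] == "explicit_mention"
        assert mapping.iloc[0]["fcr"] == 1.3

    def test_mean_over_multiple_matches(self):
        mapping, _ = fm.match_isscaap_to_fcr(
            _isscaap([("salmons, trouts, smelts", "")]),
            _fcr([("salmon", "", 1.2, 0.2), ("trout", "", 1.8, 0.3)]),
        )
        assert mapping.iloc[0]["fcr"] == pytest.approx(1.5)
        assert mapping.iloc[0]["p_fmfo"] == pytest.approx(0.25)

    def test_member_subset_rules(self):
        # feed taxon members inside the broader group -> rule (ii)
        mapping, _ = fm.match_isscaap_to_fcr(
            _isscaap([("oysters, mussels and clams", "Sp1;Sp2;Sp3")]),
            _fcr([("bivalves", "Sp1;Sp2", 0.0, 0.0)]),
        )
        assert mapping.iloc[0]["rule"] == "fcr_within_group"
        # group members inside the broader feed taxon -> rule (iii)
        mapping, _ = fm.match_isscaap_to_fcr(
            _isscaap([("flounders, halibuts, soles", "Sp1;Sp2")]),
            _fcr([("marine fish", "Sp1;Sp2;Sp3;Sp4", 1.9, 0.2)]),
        )
        assert mapping.iloc[0]["rule"] == "group_within_fcr"

    def test_specific_match_blocks_broader_candidate(self):
        mapping, _ = fm.match_isscaap_to_fcr(
            _isscaap([("salmons, trouts, smelts", "Sp1;Sp2")]),
            _fcr(
                [
                    ("salmon", "", 1.3, 0.25),
                    ("marine fish", "Sp1;Sp2;Sp3", 1.9, 0.2),  # broader, rule iii
                ]
            ),
        )
        assert mapping.iloc[0]["matched_taxa"] == "salmon"
        assert mapping.iloc[0]["fcr"] == 1.3

    def test_unmatched_group_recorded(self):
        mapping, unmatched = fm.match_isscaap_to_fcr(
            _isscaap([("miscellaneous aquatic invertebrates", "SpX")]),
            _fcr([("salmon", "", 1.3, 0.25)]),
        )
        assert unmatched == ["miscellaneous aquatic invertebrates"]
        assert mapping.empty


class TestFeedDemand:
    def _mapping(self, fcr=1.5, p=0.2):
        return pd.DataFrame(
            [{"isscaap_group": "g", "fcr": fcr, "p_fmfo": p, "matched_taxa": "x", "rule": "explicit_mention"}]
        )

    def _production(self, tonnes):
        return pd.DataFrame(
            [{"country": "CHN", "isscaap_group": "g", "live_weight": tonnes}]
        )

    def test_direct_formula(self):
        out = fm.feed_demand(self._production(1000.0), self._mapping())
        assert out["fishmeal_product"].iloc[0] == pytest.approx(300.0)
        assert out["live_weight_equiv"].iloc[0] == pytest.approx(894.0)

    def test_non_fed_taxa_zero_demand(self):
        out = fm.feed_demand(self._production(1000.0), self._mapping(fcr=0.0, p=0.0))
        assert out["fishmeal_product"].iloc[0] == 0.0

    def test_country_totals_sum(self):
        production = pd.DataFrame(
            [
                {"country": "CHN", "isscaap_group": "g", "live_weight": 1000.0},
                {"country": "CHN", "isscaap_group": "h", "live_weight": 2000.0},
            ]
        )
        mapping = pd.DataFrame(
            [
                {"isscaap_group": "g", "fcr": 1.5, "p_fmfo": 0.2, "matched_taxa": "", "rule": ""},
                {"isscaap_group": "h", "fcr": 1.0, "p_fmfo": 0.1, "matched_taxa": "", "rule": ""},
            ]
        )
        out = fm.feed_demand(production, mapping)
        assert out["fishmeal_product"].sum() == pytest.approx(300.0 + 200.0)

    def test_negative_production_fatal(self):
        with pytest.raises(ValueError):
            fm.feed_demand(self._production(-1.0), self._mapping())

    def test_linearity(self):
        one = fm.feed_demand(self._production(1.0), self._mapping())
        many = fm.feed_demand(self._production(137.5), self._mapping())
        assert many["live_weight_equiv"].iloc[0] == pytest.approx(
            137.5 * one["live_weight_equiv"].iloc[0]
        )


def _fishmeal_flows(rows):
    return pd.DataFrame(
        rows,
        columns=["producer", "exporter", "importer", "taxon", "commodity", "live_weight"],
    )


class TestAllocation:
    def test_proportional_shares(self):
        demand = pd.DataFrame(
            [{"country": "CHN", "isscaap_group": "g", "fishmeal_product": 0.0, "live_weight_equiv": 100.0}]
        )
        supply = _fishmeal_flows(
            [
                ("PER", "PER", "CHN", "SpA", "fishmeal", 70.0),
                ("CHL", "CHL", "CHN", "SpB", "fishmeal", 30.0),
            ]
        )
        result = fm.allocate_fishmeal_flows(demand, supply)
        alloc = result.allocations.set_index("source_country")["tonnes"]
        assert alloc["PER"] == pytest.approx(70.0)
        assert alloc["CHL"] == pytest.approx(30.0)

    def test_single_source_full_allocation(self):
        demand = pd.DataFrame(
            [{"country": "CHN", "isscaap_group": "g", "fishmeal_product": 0.0, "live_weight_equiv": 42.0}]
        )
        supply = _fishmeal_flows([("PER", "PER", "CHN", "SpA", "fishmeal", 7.0)])
        result = fm.allocate_fishmeal_flows(demand, supply)
        assert result.allocations["tonnes"].tolist() == [42.0]

    def test_unsourced_demand_flagged(self):
        demand = pd.DataFrame(
            [{"country": "ZZZ", "isscaap_group": "g", "fishmeal_product": 0.0, "live_weight_equiv": 5.0}]
        )
        result = fm.allocate_fishmeal_flows(demand, _fishmeal_flows([]))
        assert result.allocations.empty
        assert result.unsourced["live_weight_equiv"].tolist() == [5.0]

    def test_allocation_sums_match_demand_on_random_worlds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            countries = [f"C{i}" for i in range(4)]
            demand = pd.DataFrame(
                [
                    {
                        "country": c,
                        "isscaap_group": f"g{j}",
                        "fishmeal_product": 0.0,
                        "live_weight_equiv": float(rng.uniform(0, 100)),
                    }
                    for c in countries
                    for j in range(2)
                ]
            )
            supply = _fishmeal_flows(
                [
                    (f"S{k}", f"S{k}", c, f"Sp{k}", "fishmeal", float(rng.uniform(1, 50)))
                    for c in countries
                    for k in range(3)
                ]
            )
            result = fm.allocate_fishmeal_flows(demand, supply)
            got = result.allocations.groupby(["country", "isscaap_group"])["tonnes"].sum()
            want = demand.set_index(["country", "isscaap_group"])["live_weight_equiv"]
            for key, value in want.items():
                assert got.get(key, 0.0) == pytest.approx(value)


class TestTrimmings:
    def _frame(self, value):
        return pd.DataFrame([{"live_weight_equiv": value}])

    def test_exact_scaling(self):
        out = fm.trimmings_adjustment(self._frame(31.0), 0.34)
        assert out["live_weight_equiv"].iloc[0] == pytest.approx(20.46)

    def test_zero_fraction_identity(self):
        out = fm.trimmings_adjustment(self._frame(31.0), 0.0)
        assert out["live_weight_equiv"].iloc[0] == 31.0

    def test_composition_law(self):
        twice = fm.trimmings_adjustment(
            fm.trimmings_adjustment(self._frame(10.0), 0.2), 0.25
        )
        once = fm.trimmings_adjustment(self._frame(10.0), 1 - 0.8 * 0.75)
        assert twice["live_weight_equiv"].iloc[0] == pytest.approx(
            once["live_weight_equiv"].iloc[0]
        )

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            fm.trimmings_adjustment(self._frame(1.0), 1.5)

    def test_lwc_constant_links_units(self):
        demand = fm.feed_demand(
            pd.DataFrame([{"country": "A", "isscaap_group": "g", "live_weight": 10.0}]),
            pd.DataFrame([{"isscaap_group": "g", "fcr": 2.0, "p_fmfo": 0.5, "matched_taxa": "", "rule": ""}]),
        )
        assert demand["live_weight_equiv"].iloc[0] == pytest.approx(
            demand["fishmeal_product"].iloc[0] * LWC_FM
        )
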