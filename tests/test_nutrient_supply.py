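"""Observation cleaning, taxonomic-fallback profiles, and supply conversion."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriflow import nutrient_supply as ns
from nutriflow.constants import NUTRIENT_UNITS, NUTRIENTS


def _obs(rows):
    return pd.DataFrame(
        rows, columns=["taxon", "nutrient", "part", "preparation", "concentration"]
    )


class TestFilterObservations:
    @pytest.mark.parametrize(
        "part,preparation,kept",
        [
            ("muscle_tissue", "raw", True),
            ("muscle_tissue", "cooked", False),
            ("viscera", "raw", False),
        ],
    )
    def test_raw_muscle_only(self, part, preparation, kept):
        frame = _obs([("Sp", "iron", part, preparation, 1.0)])
        assert len(ns.filter_observations(frame)) == (1 if kept else 0)

    def test_mixed_fixture_count(self):
        rows = [
            ("Sp", "iron", "muscle_tissue", "raw", 1.0),
            ("Sp", "iron", "muscle_tissue", "raw", 2.0),
            ("Sp", "iron", "muscle_tissue", "cooked", 3.0),
            ("Sp", "iron", "viscera", "raw", 4.0),
            ("Sp", "iron", "viscera", "cooked", 5.0),
            ("Sp", "iron", "whole", "dried", 6.0),
        ]
        assert len(ns.filter_observations(_obs(rows))) == 2


class TestRemoveOutliers:
    def test_extreme_value_removed(self):
        # Q1=2, Q3=4 by linear interpolation; bounds [2-6, 4+6] exclude 100
        rows = [("Sp", "iron", "muscle_tissue", "raw", v) for v in (1, 2, 3, 4, 100)]
        out = ns.remove_outliers(_obs(rows))
        assert sorted(out["concentration"]) == [1, 2, 3, 4]

    def test_constant_group_unchanged(self):
        rows = [("Sp", "iron", "muscle_tissue", "raw", 5.0)] * 6
        assert len(ns.remove_outliers(_obs(rows))) == 6

    def test_small_group_passes_through(self):
        rows = [("Sp", "iron", "muscle_tissue", "raw", v) for v in (1, 2, 1000)]
        assert len(ns.remove_outliers(_obs(rows))) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_on_generated_observation_tables(self, seed):
        """A second pass removes nothing on generated observation tables
        (tight multiplicative noise plus rare far outliers)."""
        from nutriflow import synthgen

        world = synthgen.generate_world(
            synthgen.WorldConfig(seed=seed, n_species=30, n_countries=10)
        )
        obs = world.observations.rename(columns={"value": "concentration"})
        obs = ns.filter_observations(obs)
        once = ns.remove_outliers(obs).reset_index(drop=True)
        twice = ns.remove_outliers(once).reset_index(drop=True)
        pd.testing.assert_frame_equal(once, twice)


class TestBuildProfile:
    def test_species_level_mean(self, small_taxonomy):
        obs = _obs(
            [
                ("Gadus morhua", "iron", "muscle_tissue", "raw", 2.0),
                ("Gadus morhua", "iron", "muscle_tissue", "raw", 4.0),
            ]
        )
        profile = ns.build_profile("Gadus morhua", obs, small_taxonomy)
        assert profile.values["iron"] == 3.0
        assert profile.match_rank["iron"] == "species"

    def test_genus_fallback(self, small_taxonomy):
        obs = _obs([("Gadus", "zinc", "muscle_tissue", "raw", 10.0)])
        profile = ns.build_profile("Gadus morhua", obs, small_taxonomy)
        assert profile.values["zinc"] == 10.0
        assert profile.match_rank["zinc"] == "genus"

    def test_sibling_species_pooled_at_genus(self, small_taxonomy):
        obs = _obs(
            [
                ("Gadus macrocephalus", "zinc", "muscle_tissue", "raw", 6.0),
                ("Gadus", "zinc", "muscle_tissue", "raw", 12.0),
            ]
        )
        profile = ns.build_profile("Gadus morhua", obs, small_taxonomy)
        assert profile.values["zinc"] == 9.0  # mean over everything under the genus
        assert profile.match_rank["zinc"] == "genus"

    def test_absent_everywhere_is_absent(self, small_taxonomy):
        obs = _obs([("Gadus morhua", "iron", "muscle_tissue", "raw", 2.0)])
        profile = ns.build_profile("Gadus morhua", obs, small_taxonomy)
        assert "selenium" not in profile.values

    def test_unknown_taxon_fatal(self, small_taxonomy):
        with pytest.raises(KeyError, match="not present"):
            ns.build_profile("Unknown fish", _obs([]), small_taxonomy)

    def test_match_rank_never_more_specific_than_data(self, small_taxonomy):
        # observations only at family level -> match_rank cannot be genus/species
        obs = _obs([("Gadidae", "iron", "muscle_tissue", "raw", 1.0)])
        profile = ns.build_profile("Gadus morhua", obs, small_taxonomy)
        assert profile.match_rank["iron"] == "family"


def _edible_taxonomy(morhua_group=None, macrocephalus_group=None):
    from nutriflow.types import TaxonRecord, Taxonomy

    chain = ("Gadus", "Gadidae", "Gadiformes", "Actinopteri", "Chordata")
    return Taxonomy(
        [
            TaxonRecord(
                "Gadus morhua", "species", ("Gadus morhua",) + chain,
                edible_group=morhua_group,
            ),
            TaxonRecord(
                "Gadus macrocephalus", "species", ("Gadus macrocephalus",) + chain,
                edible_group=macrocephalus_group,
            ),
            TaxonRecord("Gadus", "genus", chain),
        ]
    )


class TestEdibleFraction:
    def test_direct_lookup(self):
        taxonomy = _edible_taxonomy(morhua_group="whitefish")
        assert ns.impute_edible_fraction(
            "Gadus morhua", {"whitefish": 0.45}, taxonomy
        ) == pytest.approx(0.45)

    def test_sibling_group_mean(self):
        # unmapped species; two distinct groups mapped under its genus
        taxonomy = _edible_taxonomy(macrocephalus_group="a")
        taxonomy2 = _edible_taxonomy(macrocephalus_group="b")
        got = ns.impute_edible_fraction("Gadus morhua", {"a": 0.4, "b": 0.6}, taxonomy)
        assert got == pytest.approx(0.4)  # only group "a" resolvable here
        got2 = ns.impute_edible_fraction("Gadus morhua", {"a": 0.4, "b": 0.6}, taxonomy2)
        assert got2 == pytest.approx(0.6)

    def test_two_sibling_groups_average(self):
        from nutriflow.types import TaxonRecord, Taxonomy

        chain = ("GenusX", "FamX", "OrdX", "ClsX", "Chordata")
        taxonomy = Taxonomy(
            [
                TaxonRecord("Sp a", "species", ("Sp a",) + chain),
                TaxonRecord("Sp b", "species", ("Sp b",) + chain, edible_group="a"),
                TaxonRecord("Sp c", "species", ("Sp c",) + chain, edible_group="b"),
                TaxonRecord("GenusX", "genus", chain),
            ]
        )
        got = ns.impute_edible_fraction("Sp a", {"a": 0.4, "b": 0.6}, taxonomy)
        assert got == pytest.approx(0.5)

    def test_fully_unmapped_lineage_fatal(self):
        taxonomy = _edible_taxonomy()
        with pytest.raises(ValueError, match="lineage"):
            ns.impute_edible_fraction("Gadus morhua", {"x": 0.5}, taxonomy)


def _flow(live_weight, taxon="Gadus morhua"):
    return pd.DataFrame(
        [
            {
                "year": "2015-2019",
                "producer": "NOR",
                "exporter": "NOR",
                "importer": "USA",
                "taxon": taxon,
                "method": "aquaculture",
                "commodity": "food_product",
                "live_weight": live_weight,
            }
        ]
    )


def _profile(conc, nutrient="vitamin_b12"):
    return pd.DataFrame(
        [{"taxon": "Gadus morhua", "nutrient": nutrient, "concentration": conc}]
    )


def _rda(daily, nutrient="vitamin_b12"):
    return pd.DataFrame([{"nutrient": nutrient, "annual_rda": daily * 365}])


class TestComputeSupply:
    def test_edible_weight_is_live_times_fraction(self):
        out = ns.compute_supply(
            _flow(100.0), _profile(1.0), {"Gadus morhua": 0.5}, _rda(2.4)
        )
        assert out["edible_weight"].iloc[0] == pytest.approx(50.0)

    def test_person_equivalents_against_hand_computation(self):
        # 100 t live x 0.5 edible x 1752 ug/100 g = 8.76e8 ug of B12;
        # annual RDA = 2.4 ug x 365 = 876 ug -> exactly one million people
        out = ns.compute_supply(
            _flow(100.0), _profile(1752.0), {"Gadus morhua": 0.5}, _rda(2.4)
        )
        assert out["person_equivalents"].iloc[0] == pytest.approx(1_000_000.0)

    def test_zero_weight_gives_zero_supply(self):
        out = ns.compute_supply(
            _flow(0.0), _profile(1752.0), {"Gadus morhua": 0.5}, _rda(2.4)
        )
        assert out["person_equivalents"].iloc[0] == 0.0
        assert out["nutrient_mass"].iloc[0] == 0.0

    @given(st.floats(0, 1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_live_weight(self, k):
        base = ns.compute_supply(
            _flow(1.0), _profile(10.0), {"Gadus morhua": 0.5}, _rda(2.4)
        )
        scaled = ns.compute_supply(
            _flow(k), _profile(10.0), {"Gadus morhua": 0.5}, _rda(2.4)
        )
        assert scaled["person_equivalents"].iloc[0] == pytest.approx(
            k * base["person_equivalents"].iloc[0]
        )

    def test_additivity_over_flow_partition(self, world_run):
        _, result = world_run
        supply = result.supply
        pooled = supply.groupby("nutrient")["person_equivalents"].sum()
        parts = (
            supply.loc[supply["commodity"] == "fishmeal"]
            .groupby("nutrient")["person_equivalents"]
            .sum()
            .add(
                supply.loc[supply["commodity"] != "fishmeal"]
                .groupby("nutrient")["person_equivalents"]
                .sum(),
                fill_value=0.0,
            )
        )
        pd.testing.assert_series_equal(pooled, parts, check_names=False)

    def test_rda_unit_mismatch_fatal(self, tmp_path):
        path = tmp_path / "rda.csv"
        path.write_text("nutrient,unit,daily_rda\niron,ug,18\n")
        with pytest.raises(ValueError, match="canonical unit"):
            ns.read_rda_table(path)


class TestSummarize:
    def test_mean_and_median(self):
        values = pd.Series([2.0, 4.0, 9.0], index=["a", "b", "c"])
        assert ns.summarize_across_nutrients(values, "mean") == 5.0
        assert ns.summarize_across_nutrients(values, "median") == 4.0

    def test_equal_weights_match_unweighted(self):
        values = pd.Series([2.0, 4.0, 9.0], index=["a", "b", "c"])
        weights = pd.Series([3.0, 3.0, 3.0], index=["a", "b", "c"])
        assert ns.summarize_across_nutrients(values, "mean", weights) == 5.0

    def test_degenerate_weights_pick_one_value(self):
        values = pd.Series([2.0, 4.0, 9.0], index=["a", "b", "c"])
        weights = pd.Series([1.0, 0.0, 0.0], index=["a", "b", "c"])
        assert ns.summarize_across_nutrients(values, "mean", weights) == 2.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            ns.summarize_across_nutrients(pd.Series(dtype=float), "mean")


def test_unit_conversion_on_read(tmp_path):
    path = tmp_path / "obs.csv"
    path.write_text(
        "taxon,nutrient,part,preparation,value,unit\n"
        "Sp,iron,muscle_tissue,raw,1500,ug\n"  # canonical iron unit is mg
        "Sp,folate,muscle_tissue,raw,0.02,mg\n"  # canonical folate unit is ug
    )
    out = ns.read_observations(path)
    assert out.loc[out["nutrient"] == "iron", "concentration"].iloc[0] == pytest.approx(1.5)
    assert out.loc[out["nutrient"] == "folate", "concentration"].iloc[0] == pytest.approx(20.0)
    assert set(out["unit"]) == {NUTRIENT_UNITS["iron"], NUTRIENT_UNITS["folate"]}


def test_world_profiles_exercise_taxonomic_fallback(world_run):
    """Species generated without species-level data must match above species."""
    _, result = world_run
    ranks = set(result.profiles["match_rank"])
    assert "species" in ranks
    assert ranks - {"species"}, "no profile used the taxonomic fallback"
    assert set(result.profiles["nutrient"]) == set(NUTRIENTS)
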