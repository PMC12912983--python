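"""Shared fixtures: a deterministic synthetic world and a full pipeline run."""

from __future__ import annotations

import pytest

from nutriflow import pipeline as pl
from nutriflow import synthgen
from nutriflow.types import TaxonRecord, Taxonomy


@pytest.fixture(scope="session")
def world():
    return synthgen.generate_world(synthgen.WorldConfig(seed=42))


@pytest.fixture(scope="session")
def world_run(world, tmp_path_factory):
    """The seed-42 world written to disk and pushed through the pipeline."""
    root = tmp_path_factory.mktemp("world42")
    world.write(root / "in")
    config = pl.PipelineConfig(
        input_dir=str(root / "in"),
        out_dir=str(root / "out"),
        year_range=world.year_range,
    )
    return world, pl.run_all(config)


@pytest.fixture()
def small_taxonomy() -> Taxonomy:
    """Two species sharing a genus, one genus-rank record, full chains."""
    chain = ("Gadus", "Gadidae", "Gadiformes", "Actinopteri", "Chordata")
    return Taxonomy(
        [
            TaxonRecord("Gadus morhua", "species", ("Gadus morhua",) + chain),
            TaxonRecord("Gadus macrocephalus", "species", ("Gadus macrocephalus",) + chain),
            TaxonRecord("Gadus", "genus", chain),
            TaxonRecord("Gadidae", "family", chain[1:]),
            TaxonRecord("Gadiformes", "order", chain[2:]),
            TaxonRecord("Actinopteri", "class", chain[3:]),
            TaxonRecord("Chordata", "phylum", chain[4:]),
        ]
    )
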