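"""Shared fixtures: generated inputs only, nothing read from disk."""

from __future__ import annotations

import random

import pytest

from eescan.io_formats import SequenceRecord
from eescan.merging import MergeParams
from eescan.pipeline import PipelineConfig, run_pipeline
from eescan.simulate import (
    FixtureSet,
    generate_bait_proteins,
    generate_host_genome,
    generate_proteins,
    plant_insertions,
    reciprocal_fixture,
    standard_fixture,
)
from eescan.io_formats import write_fasta
from eescan.simulate import write_truth


def small_planted_fixture(seed: int = 5, mutation_rate: float = 0.0) -> FixtureSet:
    """A fast fixture: 2 x 30 kb contigs, 4 proteins, 2 intact + 2 fragmented events."""
    genome = generate_host_genome(2, (30_000, 30_000), gc_fraction=0.5, seed=seed)
    proteins, metadata = generate_proteins(4, (120, 180), seed=seed)
    baits = generate_bait_proteins(8, (120, 200), seed=seed)
    planted, truth = plant_insertions(
        genome,
        proteins,
        n_intact=2,
        n_fragmented=2,
        fragments_per_event=3,
        intra_event_gap_range=(40, 95),
        mutation_rate=mutation_rate,
        strand_mix=0.5,
        seed=seed,
        min_event_spacing=9_000,
        edge_margin=1_500,
    )
    return FixtureSet(genome=planted, proteins=proteins, metadata=metadata, baits=baits, truth=truth)


@pytest.fixture(scope="session")
def small_fixture() -> FixtureSet:
    return small_planted_fixture()


@pytest.fixture(scope="session")
def recip_fixture() -> FixtureSet:
    return reciprocal_fixture(seed=1)


def write_fixture_inputs(fx: FixtureSet, directory) -> dict:
    """Materialize a FixtureSet as the four pipeline input files plus truth."""
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": directory / "genome.fna",
        "database": directory / "proteins.faa",
        "baits": directory / "baits.faa",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.tsv",
    }
    write_fasta(fx.genome, paths["genome"])
    write_fasta(fx.proteins, paths["database"])
    write_fasta(fx.baits, paths["baits"])
    with open(paths["metadata"], "w") as handle:
        handle.write("accession\tspecies\tgenus\tfamily\tmolecule_type\tprotein_product\thost\n")
        for row in fx.metadata:
            handle.write(
                f"{row.accession}\t{row.species}\t{row.genus}\t{row.family}\t"
                f"{row.molecule_type}\t{row.protein_product}\t{row.host}\n"
            )
    write_truth(fx.truth, paths["truth"])
    return paths


@pytest.fixture(scope="session")
def standard_run(tmp_path_factory):
    """One full pipeline run on the standard planted fixture (shared, ~2 min)."""
    fx = standard_fixture(seed=1)
    base = tmp_path_factory.mktemp("standard_run")
    paths = write_fixture_inputs(fx, base / "inputs")
    config = PipelineConfig(
        genome=paths["genome"],
        database=paths["database"],
        metadata=paths["metadata"],
        baits=paths["baits"],
        output_dir=base / "out",
        merge=MergeParams(merge_level="family", limit_merge=10_000, range_junction=100),
    )
    result = run_pipeline(config)
    return {"fixture": fx, "config": config, "result": result, "paths": paths}


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(length))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(1234)


def make_record(seq_id: str, residues: str, description: str = "") -> SequenceRecord:
    return SequenceRecord(id=seq_id, residues=residues, description=description)
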