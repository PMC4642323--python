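"""Shared fixtures: one session-scoped synthetic dataset and its records."""

from __future__ import annotations

from pathlib import Path

import pytest

from nbsevol import pipeline
from nbsevol.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset(tmp_path_factory) -> tuple[Path, object]:
    """Default synthetic dataset (seed 11) plus its truth manifest."""
    outdir = tmp_path_factory.mktemp("dataset")
    manifest = simulate_dataset(SimulationConfig(seed=11), outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def dataset_config(dataset) -> pipeline.PipelineConfig:
    outdir, _ = dataset
    return pipeline.PipelineConfig(
        proteins=outdir / "proteins.faa",
        cds=outdir / "cds.fna",
        gff=outdir / "genes.gff3",
        genome=outdir / "genome.fna",
        domain_table=outdir / "domains.tsv",
        species_map=outdir / "species.tsv",
        outdir=outdir / "results",
    )


@pytest.fixture(scope="session")
def gene_records(dataset_config):
    records, gff = pipeline.load_genes(dataset_config)
    return records
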