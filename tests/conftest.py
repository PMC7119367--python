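"""Shared fixtures: small simulated genomes and the full-size benchmark.

The heavy objects (the ~1-Mb reference genome, its bait set and its
per-gene scores) are session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import pytest

import hgtscan as h
from hgtscan.simulate import (
    CassetteSpec,
    IslandSpec,
    SimulationSpec,
    make_reference_fixture,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-kb genome with two 50%-GC islands carrying an 8-gene cassette
    at copy similarities 1.0 / 0.9 — big enough for every stage, small
    enough for unit tests."""
    spec = SimulationSpec(
        seed=7,
        genome_bp=300_000,
        background_gc=0.60,
        islands=[
            IslandSpec(length_bp=60_000, gc=0.50, cassette_copy=0),
            IslandSpec(length_bp=70_000, gc=0.50, cassette_copy=1),
        ],
        cassette=CassetteSpec(n_groups=8, copies=2, similarity_targets=(1.0, 0.9)),
    )
    return simulate_genome(spec)


@pytest.fixture(scope="session")
def small_groups(small_sim):
    return h.build_bait_set(small_sim.region_proteomes())


@pytest.fixture(scope="session")
def ref_sim():
    """The frozen ~1-Mb benchmark genome (three islands, 26-gene cassette)."""
    return make_reference_fixture()


@pytest.fixture(scope="session")
def ref_groups(ref_sim):
    return h.build_bait_set(ref_sim.region_proteomes())


@pytest.fixture(scope="session")
def ref_scores(ref_sim, ref_groups):
    return h.score_genome_genes(ref_sim.genome, ref_groups)


def make_genome(sequences: dict[str, str], genes=()) -> h.AnnotatedGenome:
    """Hand-build an annotated genome from raw contig strings and gene tuples
    (gene_id, contig, start, end, strand)."""
    from hgtscan.io import build_proteome

    records = [h.GenomeRecord(id=k, sequence=v) for k, v in sequences.items()]
    anns = [
        h.GeneAnnotation(gene_id=g[0], contig=g[1], start=g[2], end=g[3], strand=g[4])
        for g in genes
    ]
    genome = h.AnnotatedGenome(records=records, genes=anns)
    build_proteome(genome)
    return genome
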