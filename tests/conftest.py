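"""Shared fixtures: a small simulated study reused across test modules."""

import pytest

from tagomics import (
    MLUI_MOTIF,
    NLAIII_MOTIF,
    build_mmsdk_library,
    find_sites,
)
from tagomics.simulate import SimConfig, simulate_counts, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        genome_length=400_000,
        n_chromosomes=2,
        n_mlu_sites=300,
        n_genes=60,
        n_cgis=30,
        n_pairs=3,
        baseline_rate_mean=50.0,
        n_spiked=20,
        spike_log2fc=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """Genome + truth + MMSDK library + count matrix for the small design."""
    genome, truth = simulate_genome(small_config)
    mlu = find_sites(genome, MLUI_MOTIF)
    nla = find_sites(genome, NLAIII_MOTIF)
    fragments, library = build_mmsdk_library(genome, mlu, nla)
    matrix, truth = simulate_counts(small_config, library, truth)
    return {
        "config": small_config,
        "genome": genome,
        "truth": truth,
        "mlu": mlu,
        "nla": nla,
        "fragments": fragments,
        "library": library,
        "matrix": matrix,
    }
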