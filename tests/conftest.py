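"""Shared fixtures: one mid-sized synthetic population, binned and mapped
once per session, reused by the binning/linkage/QTL tests."""

from __future__ import annotations

import numpy as np
import pytest

from skimqtl import binning, linkage, simulate


@pytest.fixture(scope="session")
def genome():
    return simulate.make_genome(
        n_chromosomes=2,
        chrom_length=50_000_000,
        snps_per_chromosome=600,
        recomb_rate=2.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def truth(genome):
    return simulate.simulate_ril(genome, n_lines=200, n_selfing_generations=8, seed=12)


@pytest.fixture(scope="session")
def skim(truth):
    return simulate.simulate_skim(
        truth, simulate.SkimModel(mean_depth=0.72, error_rate=0.005, seed=13)
    )


@pytest.fixture(scope="session")
def chrom_lengths(genome):
    return {c.name: c.length for c in genome.chromosomes}


@pytest.fixture(scope="session")
def segments(skim, chrom_lengths):
    return binning.call_segments(skim, chrom_lengths=chrom_lengths)


@pytest.fixture(scope="session")
def bins(segments, skim, chrom_lengths):
    return binning.consensus_bins(segments, skim, chrom_lengths=chrom_lengths)


@pytest.fixture(scope="session")
def bin_matrix(bins, segments):
    return binning.genotype_bins(bins, segments)


@pytest.fixture(scope="session")
def genetic_map(bin_matrix):
    return linkage.build_map(bin_matrix)


@pytest.fixture(scope="session")
def phenotypes(truth):
    spec = simulate.QtlSpec(
        traits=[
            simulate.TraitModel("planted", [("Ca1", 25_000_000, 1.0)], h2=0.6),
            simulate.TraitModel("null", [("Ca1", 25_000_000, 0.0)], h2=0.5),
        ]
    )
    return simulate.simulate_phenotypes(truth, spec, seed=14)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
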