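"""Shared fixtures: small synthetic studies generated at test time."""

from __future__ import annotations

import pandas as pd
import pytest

import barseqfit as bf


@pytest.fixture(scope="session")
def small_genome() -> bf.GenomeAnnotation:
    return bf.make_genome(n_genes=60, scaffold_length=120_000, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_genome) -> pd.DataFrame:
    return bf.make_pool(small_genome, n_mutants=1_500, intergenic_fraction=0.1, seed=12)


@pytest.fixture(scope="session")
def small_design() -> bf.SimDesign:
    return bf.SimDesign(
        conditions=("alone", "pairwise_1", "community"),
        timepoints=("day1", "day2"),
        replicates=2,
        depth=60_000,
        seed=13,
    )


@pytest.fixture(scope="session")
def small_run(small_genome, small_pool, small_design):
    """A small end-to-end run with planted conserved genes."""
    truth = bf.make_truth(
        small_genome, small_design, {"conserved": 0.1}, effect_size=-2.0, seed=14
    )
    counts = bf.simulate_counts(small_pool, truth, small_design, small_genome.scaffold_lengths)
    records = bf.run_fitness(counts, small_pool, bf.FitnessConfig(window=11))
    return truth, counts, records
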