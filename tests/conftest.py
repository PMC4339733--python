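"""Shared fixtures: small simulated datasets built at test time."""

from __future__ import annotations

import os

# many small-matrix operations; BLAS threading only adds overhead
for _v in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from kmerbin import SimulationSpec, simulate_metagenome


@pytest.fixture(scope="session")
def two_species_sim():
    """Small 2-species paired-end dataset (120 kb + 150 kb genomes,
    5x and 12x coverage, error-free) with ground truth."""
    specs = [
        SimulationSpec(genome_length=120_000, coverage=5.0, chain_seed=101),
        SimulationSpec(genome_length=150_000, coverage=12.0, chain_seed=202),
    ]
    return simulate_metagenome(specs, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
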