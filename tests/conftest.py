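"""Shared fixtures: small simulated datasets reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from arrayphylo.datatypes import GenotypeTable, IntensityTable
from arrayphylo.sim import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the package's default (ascertained, biased) conditions."""
    return simulate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast, small dataset for plumbing-level tests."""
    cfg = SimConfig(n_species=6, samples_per_species=8, n_candidate_snps=300, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_tables():
    """Hand-built 3-sample x 4-SNP genotype and intensity tables."""
    samples = ["s1", "s2", "s3"]
    snps = ["snp1", "snp2", "snp3", "snp4"]
    dosage = pd.DataFrame(
        [[0.0, 1.0, 2.0, np.nan], [1.0, 1.0, 0.0, 2.0], [2.0, 0.0, np.nan, 1.0]],
        index=samples,
        columns=snps,
    )
    gencall = pd.DataFrame(0.9, index=samples, columns=snps)
    x = pd.DataFrame(
        np.round(np.abs(np.random.default_rng(5).normal(1.0, 0.2, (3, 4))), 6),
        index=samples,
        columns=snps,
    )
    y = pd.DataFrame(
        np.round(np.abs(np.random.default_rng(6).normal(0.5, 0.2, (3, 4))), 6),
        index=samples,
        columns=snps,
    )
    return GenotypeTable(dosage, gencall), IntensityTable(x, y)
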