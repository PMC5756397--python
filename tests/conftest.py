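"""Shared fixtures: small genotype matrices and simulated studies."""

from __future__ import annotations

import numpy as np
import pytest

from ascbias.types import GenotypeMatrix, SnpRecord
from ascbias import synthetic_data as sd


def make_geno(dosages, populations=None, chrom="1", start_pos=100, spacing=100):
    """GenotypeMatrix from a plain (samples x snps) dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n_samples, n_snps = dosages.shape
    snps = [
        SnpRecord(f"s{j}", chrom, start_pos + j * spacing, "A", "G") for j in range(n_snps)
    ]
    populations = populations or ["popA"] * n_samples
    sample_ids = [f"ind{i}" for i in range(n_samples)]
    return GenotypeMatrix(snps, sample_ids, populations, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_study():
    """A reduced strong-LD study reused by several suites."""
    cfg = sd.load_scenario("strong_ld")
    cfg.n_loci = 1200
    return sd.simulate_scenario(cfg)
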