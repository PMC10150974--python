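"""Shared fixtures: small genotype matrices and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from gwaswd import GenotypeMatrix, SimulationConfig, simulate_cohort


def make_matrix(dosages, chrom=None, alleles=None, sex=None, phenotype=None,
                positions=None):
    """Build a GenotypeMatrix from a raw dosage array with sane defaults."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    chrom = chrom if chrom is not None else [1] * m
    alleles = alleles if alleles is not None else [("A", "G")] * m
    if positions is None:
        pos, counters = [], {}
        for c in chrom:
            counters[c] = counters.get(c, 0) + 1
            pos.append(counters[c] * 100)
    else:
        pos = positions
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "snp": [f"rs{j}" for j in range(m)],
            "cm": 0.0,
            "pos": pos,
            "a1": [a for a, _ in alleles],
            "a2": [b for _, b in alleles],
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i:03d}" for i in range(n)],
            "father": "0",
            "mother": "0",
            "sex": sex if sex is not None else [1] * n,
            "phenotype": phenotype if phenotype is not None else [1, 2] * (n // 2)
            + [1] * (n % 2),
        }
    )
    return GenotypeMatrix(d, variants, samples)


def random_matrix(rng, n, m, missing_rate=0.1):
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    d[rng.random((n, m)) < missing_rate] = -1
    return make_matrix(d)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 140-sample, 600-SNP cohort with one strong planted SNP."""
    cfg = SimulationConfig(
        n_cases=60, n_controls=80,
        n_snps_per_chrom={1: 200, 2: 200, 3: 200},
        causal_spec=[(50, 3.0), (250, 2.5)], seed=7,
    )
    return simulate_cohort(cfg)
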