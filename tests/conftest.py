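import numpy as np
import pandas as pd
import pytest

from gagwas.datatypes import GenotypeMatrix


def make_genotypes(calls, chrom=None, bp=None, founder=True):
    """Build a small GenotypeMatrix from a call array (helper for tests)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, p = calls.shape
    chrom = chrom if chrom is not None else ["1"] * p
    bp = bp if bp is not None else [1 + 1000 * j for j in range(p)]
    snp_map = pd.DataFrame(
        {
            "snp": [f"s{j}" for j in range(p)],
            "chrom": chrom,
            "bp": bp,
            "a1": "A",
            "a2": "B",
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"I{i}" for i in range(n)], "founder": founder}
    )
    return GenotypeMatrix(calls, snp_map, samples)


@pytest.fixture
def tiny_genotypes():
    return make_genotypes([[0, 1], [2, 1]])


@pytest.fixture(scope="session")
def null_cohort():
    """A small null cohort (no causal SNPs) reused across tests."""
    from gagwas.simulate import SimConfig, simulate_genotypes

    cfg = SimConfig(n_samples=200, n_chromosomes=2, blocks_per_chr=5,
                    snps_per_block=8, founder_haplotypes_per_block=32, seed=123)
    g = simulate_genotypes(cfg)
    rng = np.random.default_rng(5)
    y = rng.normal(270.0, 15.0, g.n_samples)
    return g, y
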