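"""Shared fixtures: small simulated gene pools generated at test time."""

import numpy as np
import pandas as pd
import pytest

from mangogp.geno_io import GenotypeMatrix
from mangogp.simdata import SimConfig, simulate_phenotype, simulate_structured_genotypes


@pytest.fixture(scope="session")
def sim_small():
    """Small two-subpopulation panel with depth and some low-depth calls."""
    cfg = SimConfig(
        n_subpop1=60, n_subpop2=30, n_snps=400, n_chrom=2, low_depth_frac=0.02, seed=42
    )
    return simulate_structured_genotypes(cfg)


@pytest.fixture(scope="session")
def trait_small(sim_small):
    pheno, truth = simulate_phenotype(
        sim_small.geno, sim_small.labels, n_qtl=40, target_h2=0.5, seed=7
    )
    return pheno, truth


@pytest.fixture(scope="session")
def ld_rich():
    """Single dense chromosome with strong short-range LD."""
    cfg = SimConfig(
        n_subpop1=120,
        n_subpop2=40,
        n_snps=600,
        n_chrom=1,
        chrom_length_bp=1_000_000,
        n_founder_haps=3,
        switch_rate=1e-5,
        seed=11,
    )
    return simulate_structured_genotypes(cfg)


def toy_geno(dosages, depth=None, chrom=None, pos=None):
    """GenotypeMatrix from a plain array, one chromosome by default."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    chrom = ["chr1"] * m if chrom is None else list(chrom)
    pos = list(range(1, m + 1)) if pos is None else list(pos)
    markers = pd.DataFrame(
        dict(
            chrom=chrom,
            pos=pos,
            ref="A",
            alt="G",
            id=[f"{c}_{p}" for c, p in zip(chrom, pos)],
        )
    )
    ids = np.array([f"i{k}" for k in range(n)], dtype=object)
    return GenotypeMatrix(ids=ids, markers=markers, dosages=dosages, depth=depth)
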