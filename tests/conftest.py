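import numpy as np
import pytest

from ibshe import (GenotypeMatrix, LocusInfo, SimConfig, compute_grm,
                   simulate_quantitative_study, standardize)


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def small_genotypes(rng):
    """60 individuals x 40 independent HWE loci at p = 0.5."""
    calls = rng.binomial(2, 0.5, size=(60, 40)).astype(np.int8)
    samples = [("F" + str(i), "i" + str(i)) for i in range(60)]
    loci = [LocusInfo(id=f"snp{k}", pos=k + 1) for k in range(40)]
    return GenotypeMatrix(samples, loci, calls)


@pytest.fixture(scope="session")
def polygenic_replicate():
    """One Simulation-III-style dataset (N=600, M=100, rho=0.25, h2=0.5)."""
    cfg = SimConfig(n=600, m=100, rho=0.25, h2=0.5, seed=7)
    G, y, betas, info = simulate_quantitative_study(cfg)
    S = standardize(G)
    grm = compute_grm(S)
    return G, y, betas, info, grm
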