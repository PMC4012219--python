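"""Synthetic-data generators: AR(1)-LD genotypes, polygenic quantitative
traits, and ascertained case-control samples.

Genotypes are built from two independent haplotypes per individual.  On a
haplotype the first allele is Bernoulli(p) and each subsequent allele is
drawn conditional on its left neighbor so that adjacent loci have
correlation rho; loci at distance d then have correlation rho^d (a
first-order Markov LD chain).  Under random mating the genotypic
correlation equals the haplotypic correlation, so the analytic relatedness
variance 1/M + (1/M^2) sum rho^{2d} applies directly.

Quantitative traits are additive: y_i = sum_l x_il beta_l + e_i, with the
residual variance chosen from the covariance-inclusive additive variance so
that the realized heritability targets h2.  Case-control samples are drawn
from a liability-threshold model with rejection sampling until the case and
control quotas are filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, LocusInfo
from .he_core import PhenotypeVector


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults mirror the desk-scale quantitative design: equifrequent
    biallelic loci (p = 0.5), markers coinciding with QTLs, target
    heritability 0.5, effects iid N(0, 1).
    """

    n: int = 1000
    m: int = 100
    p: float = 0.5
    rho: float = 0.0
    l_qtl: int | None = None
    h2: float = 0.5
    effect_law: str = "standard-normal"
    sorted_effects: bool = False
    seed: int | None = None
    K: float = 0.1
    n_cases: int = 1000
    n_controls: int = 1000
    max_draws: int = 20_000_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must lie in (0, 1)")
        if not (0.0 < self.p < 1.0):
            raise ValueError("allele frequency must lie in (0, 1)")
        if self.l_qtl is None:
            self.l_qtl = self.m

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        return np.random.default_rng(self.seed)


def replicate_seeds(seed: int, n_replicates: int) -> list[np.random.Generator]:
    """Deterministic per-replicate generators spawned from one root seed."""
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n_replicates)]


def simulate_ar1_haplotypes(n_hap: int, m: int, p: float, rho: float,
                            rng: np.random.Generator) -> np.ndarray:
    """n_hap haplotypes of m 0/1 alleles with adjacent-locus correlation rho."""
    hap = np.empty((n_hap, m), dtype=np.int8)
    u = rng.random((n_hap, m))
    hap[:, 0] = u[:, 0] < p
    # conditional carrier probabilities of the chain: P(A|A) and P(A|a)
    prob_a_given_A = p + rho * (1.0 - p)
    prob_a_given_a = p * (1.0 - rho)
    for j in range(1, m):
        prev = hap[:, j - 1] == 1
        thresh = np.where(prev, prob_a_given_A, prob_a_given_a)
        hap[:, j] = u[:, j] < thresh
    return hap


def simulate_ar1_genotypes(config: SimConfig,
                           rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Genotypes as the sum of two independent AR(1) haplotypes."""
    rng = rng if rng is not None else config.rng()
    h1 = simulate_ar1_haplotypes(config.n, config.m, config.p, config.rho, rng)
    h2_ = simulate_ar1_haplotypes(config.n, config.m, config.p, config.rho, rng)
    calls = (h1 + h2_).astype(np.int8)
    samples = [("F" + str(i + 1), "ind" + str(i + 1)) for i in range(config.n)]
    loci = [LocusInfo(id=f"snp{k + 1}", pos=k + 1, p=config.p) for k in range(config.m)]
    return GenotypeMatrix(samples, loci, calls)


def simulate_effects(config: SimConfig,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-QTL additive effects.

    ``standard-normal``: beta_l ~ N(0, 1).  ``liability-scaled``:
    beta_l ~ N(0, h2 / (2 p q L)), which makes the expected genetic
    variance of L independent loci equal h2 (used for the liability-scale
    case-control design).  ``sorted_effects`` sorts ascending along the
    segment, creating the correlated-effect architecture.
    """
    rng = rng if rng is not None else config.rng()
    L = int(config.l_qtl)
    if config.effect_law == "standard-normal":
        beta = rng.standard_normal(L)
    elif config.effect_law == "liability-scaled":
        sigma2_b = config.h2 / (2.0 * config.p * (1.0 - config.p) * L)
        beta = rng.normal(0.0, np.sqrt(sigma2_b), L)
    else:
        raise ValueError(f"unknown effect law {config.effect_law!r}")
    if config.sorted_effects:
        beta = np.sort(beta)
    return beta


def analytic_sigma2_a(betas: np.ndarray, p: float, rho: float) -> float:
    """Covariance-inclusive additive variance 2 p q beta' R beta for the
    AR(1) chain with R_{l1 l2} = rho^|l1-l2|."""
    betas = np.asarray(betas, dtype=float)
    L = betas.size
    if rho == 0:
        quad = float(betas @ betas)
    else:
        idx = np.arange(L)
        R = rho ** np.abs(idx[:, None] - idx[None, :])
        quad = float(betas @ R @ betas)
    return 2.0 * p * (1.0 - p) * quad


def simulate_phenotype(G: GenotypeMatrix, betas: np.ndarray, h2: float,
                       rho: float, p: float,
                       rng: np.random.Generator) -> tuple[PhenotypeVector, dict]:
    """Additive phenotype with residual noise targeting heritability h2.

    The residual variance is set from the analytic covariance-inclusive
    additive variance of the generator (known rho and p), not from the
    realized sample, so the target h2 is the population-level truth.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.size != G.m:
        raise ValueError("one effect per locus required")
    sigma2_a = analytic_sigma2_a(betas, p, rho)
    if sigma2_a <= 0:
        raise ValueError("non-positive analytic additive variance")
    sigma2_e = sigma2_a * (1.0 - h2) / h2
    g = G.calls.astype(float) @ betas
    y = g + rng.normal(0.0, np.sqrt(sigma2_e), G.n)
    info = {"sigma2_a": sigma2_a, "sigma2_e": sigma2_e,
            "sigma2_y": sigma2_a + sigma2_e, "genetic_values": g}
    return PhenotypeVector(y, ids=list(G.samples)), info


def simulate_quantitative_study(config: SimConfig,
                                rng: np.random.Generator | None = None
                                ) -> tuple[GenotypeMatrix, PhenotypeVector, np.ndarray, dict]:
    """One replicate of the polygenic design: genotypes, phenotype, effects."""
    rng = rng if rng is not None else config.rng()
    G = simulate_ar1_genotypes(config, rng)
    betas = simulate_effects(config, rng)
    y, info = simulate_phenotype(G, betas, config.h2, config.rho, config.p, rng)
    return G, y, betas, info


def simulate_case_control(config: SimConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Ascertained case-control sample under the liability-threshold model.

    Loci are in linkage equilibrium (the chain is only defined for the
    quantitative designs).  The genetic liability share is config.h2 on the
    liability scale; total liability variance is 1.  Batches of candidates
    are drawn and thresholded at the upper-K quantile until the case and
    control quotas are reached.
    """
    from scipy import stats as _st

    rng = rng if rng is not None else config.rng()
    L = int(config.l_qtl)
    p, K, h2l = config.p, config.K, config.h2
    if not (0.0 < K < 1.0):
        raise ValueError("prevalence K must lie in (0, 1)")
    betas = simulate_effects(
        SimConfig(n=1, m=L, p=p, h2=h2l, effect_law="liability-scaled", seed=0),
        rng)
    sigma2_g = 2.0 * p * (1.0 - p) * float(betas @ betas)
    g_scale = np.sqrt(h2l / sigma2_g)
    g_mean = 2.0 * p * betas.sum()
    thresh = float(_st.norm.isf(K))

    expected_draws = max(config.n_cases / K, config.n_controls / (1 - K))
    if expected_draws * 1.5 > config.max_draws:
        raise ValueError(
            f"filling {config.n_cases} cases at K={K} needs about "
            f"{expected_draws:.0f} candidate draws, above the cap "
            f"{config.max_draws}; reduce the quotas or raise K"
        )

    batch = int(min(max(4 * config.n_cases / K, 10_000), 200_000))
    kept_calls: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    n_case = n_ctrl = 0
    drawn = 0
    while (n_case < config.n_cases or n_ctrl < config.n_controls):
        if drawn > config.max_draws:
            raise ValueError("sampling effort cap exceeded before quotas were met")
        X = rng.binomial(2, p, size=(batch, L)).astype(np.int8)
        drawn += batch
        g = X.astype(float) @ betas
        liab = (g - g_mean) * g_scale + rng.normal(0.0, np.sqrt(1.0 - h2l), batch)
        is_case = liab > thresh
        take_case = np.flatnonzero(is_case)[: config.n_cases - n_case]
        take_ctrl = np.flatnonzero(~is_case)[: config.n_controls - n_ctrl]
        take = np.concatenate([take_case, take_ctrl])
        if take.size:
            kept_calls.append(X[take])
            kept_status.append(is_case[take].astype(np.int8))
            n_case += take_case.size
            n_ctrl += take_ctrl.size
    calls = np.vstack(kept_calls)
    status = np.concatenate(kept_status)
    n = calls.shape[0]
    samples = [("F" + str(i + 1), "ind" + str(i + 1)) for i in range(n)]
    loci = [LocusInfo(id=f"qtl{k + 1}", pos=k + 1, p=p) for k in range(L)]
    return GenotypeMatrix(samples, loci, calls), status
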