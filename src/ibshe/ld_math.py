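"""Exact two-locus haplotype and linkage-disequilibrium algebra.

A pair of biallelic loci k, l under random mating is fully described by the
allele frequencies (p_k, p_l) and the haplotype covariance D.  Derived
quantities:

* r = p(a_l | a_k) and R = p(A_l | A_k), the coupling-phase conditional
  probabilities;
* rho = D / sqrt(p_k q_k p_l q_l), the Pearson correlation of the loci;
* tau = 1 - r - R = -D / (p_k q_k), the contrast that carries the
  marker-QTL regression signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class InvalidHaplotypeError(ValueError):
    """D outside the admissible range for the given allele frequencies."""


def d_bounds(p_k: float, p_l: float) -> tuple[float, float]:
    """Admissible interval for the haplotype covariance D."""
    q_k, q_l = 1.0 - p_k, 1.0 - p_l
    return (max(-p_k * p_l, -q_k * q_l), min(p_k * q_l, q_k * p_l))


@dataclass(frozen=True)
class LDPair:
    """Two-locus LD parameterization; build via :func:`ld_pair`."""

    p_k: float
    p_l: float
    D: float
    r: float
    R: float
    rho: float
    tau: float

    @property
    def q_k(self) -> float:
        return 1.0 - self.p_k

    @property
    def q_l(self) -> float:
        return 1.0 - self.p_l


def ld_pair(p_k: float, p_l: float, D: float, _tol: float = 1e-12) -> LDPair:
    """Construct an :class:`LDPair` from allele frequencies and D.

    D is the covariance of the allele indicators, equal both to
    f(A_k A_l) - p_k p_l and to f(a_k a_l) - q_k q_l for biallelic loci.
    """
    if not (0.0 < p_k < 1.0 and 0.0 < p_l < 1.0):
        raise ValueError("allele frequencies must lie strictly inside (0, 1)")
    lo, hi = d_bounds(p_k, p_l)
    if D < lo - _tol or D > hi + _tol:
        raise InvalidHaplotypeError(
            f"D={D} outside admissible interval [{lo}, {hi}] for p_k={p_k}, p_l={p_l}"
        )
    D = float(np.clip(D, lo, hi))
    q_k, q_l = 1.0 - p_k, 1.0 - p_l
    r = q_l + D / q_k
    R = p_l + D / p_k
    rho = D / np.sqrt(p_k * q_k * p_l * q_l)
    tau = -D / (p_k * q_k)
    return LDPair(p_k=p_k, p_l=p_l, D=D, r=r, R=R, rho=rho, tau=tau)


def ld_pair_from_rho(p_k: float, p_l: float, rho: float) -> LDPair:
    """Construct an LDPair from the locus correlation rho."""
    q_k, q_l = 1.0 - p_k, 1.0 - p_l
    return ld_pair(p_k, p_l, rho * np.sqrt(p_k * q_k * p_l * q_l))


def ld_pair_from_haplotypes(f_AA: float, f_Aa: float, f_aA: float, f_aa: float) -> LDPair:
    """Construct an LDPair from the four haplotype frequencies.

    Order: A_k A_l, A_k a_l, a_k A_l, a_k a_l.  Frequencies must sum to 1.
    """
    total = f_AA + f_Aa + f_aA + f_aa
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"haplotype frequencies sum to {total}, expected 1")
    p_k = f_AA + f_Aa
    p_l = f_AA + f_aA
    return ld_pair(p_k, p_l, f_AA - p_k * p_l)


def haplotype_freqs(pair: LDPair) -> np.ndarray:
    """Four haplotype frequencies (A_kA_l, A_ka_l, a_kA_l, a_ka_l)."""
    return np.array([
        pair.p_k * pair.p_l + pair.D,
        pair.p_k * pair.q_l - pair.D,
        pair.q_k * pair.p_l - pair.D,
        pair.q_k * pair.q_l + pair.D,
    ])


def joint_genotype_probs(pair: LDPair) -> np.ndarray:
    """3x3 joint genotype distribution of the two loci under random mating.

    ``table[i, j] = P(x_k = i, x_l = j)`` with i, j counting reference
    alleles (0, 1, 2).  Rows sum to the Hardy-Weinberg marginal of locus k.
    """
    p, q, r, R = pair.p_k, pair.q_k, pair.r, pair.R
    table = np.array([
        # x_l = 0 (a_l a_l)      x_l = 1 (A_l a_l)                   x_l = 2 (A_l A_l)
        [q * q * r * r,          2 * q * q * r * (1 - r),            q * q * (1 - r) ** 2],
        [2 * p * q * r * (1 - R), 2 * p * q * (r * R + (1 - r) * (1 - R)), 2 * p * q * R * (1 - r)],
        [p * p * (1 - R) ** 2,   2 * p * p * R * (1 - R),            p * p * R * R],
    ])
    return table


def conditional_phenotype_expectation(pair: LDPair, beta: float) -> np.ndarray:
    """E(y | marker genotype) for one QTL l in LD with marker k.

    The QTL genotypes are valued (-beta, 0, +beta).  Returns the expected
    phenotype for marker genotypes (a_k a_k, A_k a_k, A_k A_k):
    ((1 - 2r) beta, (R - r) beta, (2R - 1) beta).
    """
    r, R = pair.r, pair.R
    return beta * np.array([1.0 - 2.0 * r, R - r, 2.0 * R - 1.0])


def conditional_phenotype_expectation_multi(pairs: list[LDPair],
                                            betas: np.ndarray) -> np.ndarray:
    """Multi-QTL version: contributions sum across QTLs tagged by marker k."""
    betas = np.asarray(betas, dtype=float)
    if len(pairs) != betas.size:
        raise ValueError("one LDPair per QTL effect required")
    out = np.zeros(3)
    for pair, beta in zip(pairs, betas):
        out += conditional_phenotype_expectation(pair, float(beta))
    return out
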