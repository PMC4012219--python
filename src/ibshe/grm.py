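"""IBS genetic relatedness matrix, effective marker count, relatedness filter.

The relatedness of two individuals is the mean over markers of the product
of their standardized genotype scores, Omega_ij = s_i . s_j / M.  Across
unrelated pairs E(Omega) = 0, and 1/var(Omega) estimates the effective
number of independent markers M_e, which shrinks below M as inter-marker LD
grows.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass

import numpy as np

from .genotype_io import StandardizedMatrix
from .ld_math import LDPair, joint_genotype_probs


@dataclass
class RelatednessMatrix:
    """Symmetric N x N relatedness built from M markers."""

    omega: np.ndarray
    m: int
    ids: list[tuple[str, str]] | None = None
    diagonal_convention: str = "self-relatedness"

    @property
    def n(self) -> int:
        return self.omega.shape[0]

    def offdiag(self) -> np.ndarray:
        """Upper-triangular (i < j) entries in lexicographic pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.omega[iu]


@dataclass(frozen=True)
class PairStatistics:
    n_pairs: int
    mean_omega: float
    var_omega: float
    me: float


def compute_grm(S: StandardizedMatrix) -> RelatednessMatrix:
    """Relatedness Omega = S S^T / M from standardized genotypes.

    Under the default mean-imputation policy the denominator is the total
    marker count M for every pair; under the ``pairwise`` policy each pair
    is divided by its count of mutually observed markers.
    """
    if S.m == 0:
        raise ValueError("cannot build a relatedness matrix from zero markers")
    cross = S.values @ S.values.T
    if S.missing_policy == "pairwise" and S.mask is not None:
        counts = S.mask.astype(float) @ S.mask.astype(float).T
        if (counts == 0).any():
            raise ValueError("some pairs share no observed markers")
        omega = cross / counts
    else:
        omega = cross / S.m
    return RelatednessMatrix(omega=omega, m=S.m)


def effective_marker_count(grm: RelatednessMatrix) -> PairStatistics:
    """M_e = 1 / var(Omega) over the off-diagonal pairs.

    The variance is centered on the sample mean of the off-diagonal entries:
    sample-estimated allele frequencies pull the mean slightly below zero
    (about -1/(N-1)), and centering removes that finite-sample offset.
    """
    if grm.n < 3:
        raise ValueError("at least 3 individuals required to estimate M_e")
    off = grm.offdiag()
    var = float(off.var(ddof=1))
    if var <= 0.0:
        raise ValueError("zero variance of relatedness; M_e undefined")
    return PairStatistics(
        n_pairs=off.size,
        mean_omega=float(off.mean()),
        var_omega=var,
        me=1.0 / var,
    )


def single_locus_relatedness_distribution(p: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the single-locus relatedness of a random pair.

    Returns (values, probabilities) for the 3x3 products of standardized
    scores of two independent Hardy-Weinberg individuals.  At p = 0.5 this
    collapses to seven distinct values with E = 0 and var = 1.
    """
    q = 1.0 - p
    s = np.array([-2 * p, q - p, 2 * q]) / np.sqrt(2 * p * q)
    freq = np.array([q * q, 2 * p * q, p * p])
    vals = np.outer(s, s).ravel()
    probs = np.outer(freq, freq).ravel()
    order = np.argsort(vals)
    vals, probs = vals[order], probs[order]
    # merge numerically equal products
    out_v, out_p = [vals[0]], [probs[0]]
    for v, pr in zip(vals[1:], probs[1:]):
        if np.isclose(v, out_v[-1], atol=1e-12):
            out_p[-1] += pr
        else:
            out_v.append(v)
            out_p.append(pr)
    return np.array(out_v), np.array(out_p)


def pairwise_ld_cov_oracle(pair: LDPair) -> float:
    """Brute-force cov(Omega_k, Omega_l) for one pair of loci.

    Enumerates the 9 x 9 joint distribution of the two-locus genotypes of
    two independent individuals and averages the product of the per-locus
    relatedness scores.  Analytically this equals rho^2.
    """
    joint = joint_genotype_probs(pair)  # P(x_k, x_l) for one individual
    p_k, q_k = pair.p_k, pair.q_k
    p_l, q_l = pair.p_l, pair.q_l
    s_k = np.array([-2 * p_k, q_k - p_k, 2 * q_k]) / np.sqrt(2 * p_k * q_k)
    s_l = np.array([-2 * p_l, q_l - p_l, 2 * q_l]) / np.sqrt(2 * p_l * q_l)
    e_kl = 0.0  # E over one individual of s_k(x_k) s_l(x_l)
    mean_k = 0.0
    mean_l = 0.0
    for i in range(3):
        for j in range(3):
            pr = joint[i, j]
            e_kl += pr * s_k[i] * s_l[j]
            mean_k += pr * s_k[i]
            mean_l += pr * s_l[j]
    # two independent individuals: E(Omega_k Omega_l) = (E[s_k s_l])^2
    cov = 0.0
    for i1 in range(3):
        for j1 in range(3):
            for i2 in range(3):
                for j2 in range(3):
                    pr = joint[i1, j1] * joint[i2, j2]
                    cov += pr * (s_k[i1] * s_k[i2]) * (s_l[j1] * s_l[j2])
    e_omega_k = mean_k * mean_k
    e_omega_l = mean_l * mean_l
    return cov - e_omega_k * e_omega_l


def ar1_var_omega(m: int, rho: float) -> float:
    """Analytic var(Omega) for M loci with correlation rho^|k-l|.

    var(Omega) = 1/M + (1/M^2) sum_{k != l} rho^{2|k-l|}; the reciprocal is
    the analytic effective marker count.
    """
    d = np.arange(1, m)
    return 1.0 / m + (2.0 / m**2) * float(np.sum((m - d) * rho ** (2 * d)))


def filter_relatedness(grm: RelatednessMatrix, cutoff: float) -> np.ndarray:
    """Greedy cryptic-relatedness pruning; returns retained sample indices.

    Repeatedly removes the individual participating in the most pairs with
    Omega > cutoff (ties broken by sample order) until no such pair remains.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = grm.n
    over = grm.omega > cutoff
    np.fill_diagonal(over, False)
    active = np.ones(n, dtype=bool)
    counts = over.sum(axis=1)
    while True:
        counts_active = np.where(active, counts, -1)
        worst = int(np.argmax(counts_active))
        if counts_active[worst] <= 0:
            break
        active[worst] = False
        counts -= over[:, worst]
        counts[worst] = 0
    return np.flatnonzero(active)


# ---------------------------------------------------------------------------
# GCTA-style GRM text interchange


def write_gcta_grm(grm: RelatednessMatrix, prefix: str | os.PathLike) -> None:
    """Write <prefix>.grm.gz (i j m omega, 1-based, lower triangle incl.
    diagonal) and <prefix>.grm.id."""
    prefix = os.fspath(prefix)
    ids = grm.ids or [("F" + str(i + 1), "ind" + str(i + 1)) for i in range(grm.n)]
    with open(prefix + ".grm.id", "w") as fh:
        for fid, iid in ids:
            fh.write(f"{fid}\t{iid}\n")
    with gzip.open(prefix + ".grm.gz", "wt") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.m}\t{grm.omega[i, j]:.10g}\n")


def read_gcta_grm(prefix: str | os.PathLike) -> RelatednessMatrix:
    prefix = os.fspath(prefix)
    ids = []
    with open(prefix + ".grm.id") as fh:
        for line in fh:
            parts = line.split()
            if parts:
                ids.append((parts[0], parts[1]))
    n = len(ids)
    omega = np.zeros((n, n))
    m = 0
    with gzip.open(prefix + ".grm.gz", "rt") as fh:
        for line in fh:
            i_s, j_s, m_s, v_s = line.split()
            i, j = int(i_s) - 1, int(j_s) - 1
            omega[i, j] = omega[j, i] = float(v_s)
            m = max(m, int(float(m_s)))
    return RelatednessMatrix(omega=omega, m=m, ids=ids)
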