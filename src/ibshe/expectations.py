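"""Closed-form expectations of the HE regression coefficient, and the
power/sample-size calculus of the single-marker test.

Single marker, single QTL:   E(b) = -4 tau^2 p_k q_k beta^2 = -2 rho^2 sigma_l^2.
Single marker, L QTLs:       E(b) = -4 p_k q_k (sum_l tau_kl beta_l)^2.
M markers, L QTLs:
    E(b) = [sum_k -4 p_k q_k (sum_l tau_kl beta_l)^2 / M]
           / [sum_{k,k'} rho_{kk'}^2 / M^2]
which decomposes as E(b) = -2 sigma_A^2 Lambda + Delta, where
Lambda = mean(rho_MQ^2) / mean(rho_MM^2) measures how well markers tag the
causal loci and Delta collects between-locus covariance terms (zero when
QTL effects are randomly allocated along the genome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ld_math import LDPair


@dataclass(frozen=True)
class QTLModel:
    """Marker/QTL architecture for the multi-marker expectation.

    ``rho_mq[k, l]`` is the signed correlation between marker k and QTL l;
    ``rho_qq`` the QTL-QTL correlation matrix (used for the covariance-
    inclusive additive variance); ``rho_mm`` the marker-marker correlation
    matrix including the unit diagonal.
    """

    p_marker: np.ndarray
    p_qtl: np.ndarray
    beta: np.ndarray
    rho_mq: np.ndarray
    rho_mm: np.ndarray
    rho_qq: np.ndarray

    def __post_init__(self) -> None:
        m, l = self.rho_mq.shape
        if self.p_marker.shape != (m,) or self.p_qtl.shape != (l,):
            raise ValueError("frequency vectors inconsistent with rho_mq")
        if self.beta.shape != (l,):
            raise ValueError("effect vector inconsistent with rho_mq")
        if self.rho_mm.shape != (m, m) or self.rho_qq.shape != (l, l):
            raise ValueError("LD matrix dimensions inconsistent")
        for mat in (self.rho_mq, self.rho_mm, self.rho_qq):
            if np.abs(mat).max() > 1 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass(frozen=True)
class ExpectedCoefficient:
    """E(b) with its variance-decomposition bookkeeping."""

    e_b: float
    sigma2_a_within: float
    sigma2_a_total: float
    lambda_: float
    delta: float
    rho2_m: float
    rho2_q: float

    def predicted_h2(self, sigma2_y: float = 1.0) -> float:
        """-E(b)/2 on the standardized-phenotype scale (divide by var(y))."""
        return -self.e_b / (2.0 * sigma2_y)


def expected_b_single(pair: LDPair, beta: float) -> float:
    """E(b) = -4 tau^2 p_k q_k beta^2 for one marker tagging one QTL."""
    return -4.0 * pair.tau**2 * pair.p_k * pair.q_k * beta**2


def expected_b_single_rho_form(pair: LDPair, beta: float) -> float:
    """Identical expectation in the correlation form -2 rho^2 sigma_l^2."""
    sigma2_l = 2.0 * pair.p_l * pair.q_l * beta**2
    return -2.0 * pair.rho**2 * sigma2_l


def expected_b_one_marker_multi_qtl(pairs: list[LDPair], betas: np.ndarray) -> float:
    """E(b) = -4 p_k q_k (sum_l tau_kl beta_l)^2, all QTLs tagged by one marker."""
    betas = np.asarray(betas, dtype=float)
    if len(pairs) != betas.size:
        raise ValueError("one LDPair per effect required")
    p_k, q_k = pairs[0].p_k, pairs[0].q_k
    if any(not np.isclose(pr.p_k, p_k) for pr in pairs):
        raise ValueError("all pairs must share the same marker")
    total = sum(pr.tau * b for pr, b in zip(pairs, betas))
    return -4.0 * p_k * q_k * total**2


def expected_b_one_marker_rho_form(pairs: list[LDPair], betas: np.ndarray) -> float:
    """Double-sum form -2 sum_{l1,l2} rho_{k l1} rho_{k l2} sigma_{l1} sigma_{l2}.

    The signed square roots sigma_l = sqrt(2 p_l q_l) beta_l keep the sign of
    the effect so that the two closed forms agree term by term.
    """
    betas = np.asarray(betas, dtype=float)
    sig = np.array([math.sqrt(2 * pr.p_l * pr.q_l) * b for pr, b in zip(pairs, betas)])
    rho = np.array([pr.rho for pr in pairs])
    return -2.0 * float(np.outer(rho * sig, rho * sig).sum())


def sigma2_a_components(p_qtl: np.ndarray, beta: np.ndarray,
                        rho_qq: np.ndarray) -> tuple[float, float]:
    """(within-locus, total) additive variance of the polygenic trait.

    within = sum_l 2 p_l q_l beta_l^2; total adds the between-locus
    covariance sum_{l1 != l2} 2 rho sqrt(p q p q) beta beta.
    """
    pq = p_qtl * (1.0 - p_qtl)
    within = float(np.sum(2.0 * pq * beta**2))
    root = np.sqrt(pq) * beta
    cross = rho_qq * np.outer(root, root)
    total = within + 2.0 * (float(cross.sum()) - float(np.sum(pq * beta**2)))
    return within, total


def expected_b_multi(model: QTLModel) -> ExpectedCoefficient:
    """Exact multi-marker expectation and its Lambda/Delta decomposition.

    tau_kl is recovered from the signed correlation as
    tau_kl = -rho_kl sqrt(p_l q_l / (p_k q_k)).  Delta is defined as the
    exact remainder E(b) + 2 sigma_A^2(within) Lambda, which is the only
    definition consistent with the full ratio expectation.
    """
    pq_m = model.p_marker * (1.0 - model.p_marker)
    pq_q = model.p_qtl * (1.0 - model.p_qtl)
    m, l = model.rho_mq.shape
    tau = -model.rho_mq * np.sqrt(pq_q)[None, :] / np.sqrt(pq_m)[:, None]
    contrib = tau @ model.beta  # per-marker sum_l tau_kl beta_l
    numerator = float(np.sum(-4.0 * pq_m * contrib**2)) / m
    rho2_m = float(np.sum(model.rho_mm**2)) / m**2
    rho2_q = float(np.sum(model.rho_mq**2)) / (m * l)
    e_b = numerator / rho2_m
    lambda_ = rho2_q / rho2_m
    within, total = sigma2_a_components(model.p_qtl, model.beta, model.rho_qq)
    delta = e_b + 2.0 * within * lambda_
    return ExpectedCoefficient(
        e_b=e_b, sigma2_a_within=within, sigma2_a_total=total,
        lambda_=lambda_, delta=delta, rho2_m=rho2_m, rho2_q=rho2_q,
    )


def ar1_qtl_model(m: int, rho: float, beta: np.ndarray, p: float = 0.5) -> QTLModel:
    """Model where markers coincide with QTLs on an AR(1) LD chain.

    The correlation between loci at distance d is rho^d; all loci share
    frequency p.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (m,):
        raise ValueError("beta must have one entry per locus")
    idx = np.arange(m)
    dist = np.abs(idx[:, None] - idx[None, :])
    R = rho ** dist if rho != 0 else np.eye(m)
    freqs = np.full(m, float(p))
    return QTLModel(p_marker=freqs, p_qtl=freqs, beta=beta,
                    rho_mq=R, rho_mm=R, rho_qq=R)


# ---------------------------------------------------------------------------
# Power calculus of the single-marker HE test


def breakeven_sample_size(h2: float, rho: float) -> int:
    """Smallest N at which the single-marker HE test overtakes linear
    regression in non-centrality: N >= 4 / (h^2 rho^2), rounded up.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("per-QTL heritability must lie in (0, 1)")
    if not (0.0 < rho <= 1.0):
        raise ValueError("marker-QTL correlation must lie in (0, 1]")
    x = 4.0 / (h2 * rho * rho)
    # guard against float noise at exactly integral thresholds
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return int(nearest)
    return int(math.ceil(x))


def ncp(n: int, h2: float, rho: float, test: str = "he") -> float:
    """Non-centrality parameter of the chi^2_1 association test.

    ``linear``: N h^2 rho^2 / (1 - h^2 rho^2), the standard single-marker
    regression.  ``he``: (N h^2 rho^2 / 2)^2, from the t statistic
    h^2 rho^2 / se(h2) with se(h2) = 2/N at M_e = 1.  Their ratio
    N h^2 rho^2 / 4 equals 1 exactly at the breakeven sample size.
    """
    v = h2 * rho * rho
    if v >= 1.0:
        raise ValueError("h2 * rho^2 must be below 1")
    if v < 0.0:
        raise ValueError("h2 * rho^2 must be non-negative")
    if test == "linear":
        return n * v / (1.0 - v)
    if test == "he":
        return (n * v / 2.0) ** 2
    raise ValueError(f"unknown test {test!r}")


def sample_size_for_power(h2: float, rho: float, alpha: float = 5e-8,
                          power: float = 0.8, test: str = "he") -> int:
    """Smallest N giving the requested power for the chi^2_1 test at alpha."""
    crit = stats.chi2.isf(alpha, df=1)

    def achieved(n: int) -> float:
        return float(stats.ncx2.sf(crit, df=1, nc=ncp(n, h2, rho, test)))

    lo, hi = 2, 4
    while achieved(hi) < power:
        hi *= 2
        if hi > 10**9:
            raise ValueError("required sample size exceeds 1e9")
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo
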