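"""Observed-scale / liability-scale heritability transformation.

A binary disease trait is modeled as a thresholded latent Gaussian
liability: individuals whose liability exceeds the upper-K quantile t are
cases, where K is the population prevalence.  Heritability estimated on the
observed 0/1 scale from an ascertained case-control sample (case proportion
P) converts to the liability scale as

    h2_l = h2_o * K^2 (1 - K)^2 / (z^2 * P (1 - P))

with z the standard normal density at the threshold t.  The map is linear
in h2_o, so the same multiplicative constant applies to standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class LiabilityParams:
    """Prevalence K, sample case proportion P, and derived threshold values."""

    K: float
    P: float

    def __post_init__(self) -> None:
        if not (0.0 < self.K < 1.0):
            raise ValueError(f"prevalence K={self.K} must lie in (0, 1)")
        if not (0.0 < self.P < 1.0):
            raise ValueError(f"case proportion P={self.P} must lie in (0, 1)")

    @property
    def t(self) -> float:
        """Liability threshold: the upper-K quantile of N(0, 1)."""
        return float(stats.norm.isf(self.K))

    @property
    def z(self) -> float:
        """Standard normal density at the threshold."""
        return float(stats.norm.pdf(self.t))

    @property
    def factor(self) -> float:
        """Multiplier taking observed-scale to liability-scale heritability."""
        return (self.K**2 * (1.0 - self.K) ** 2) / (
            self.z**2 * self.P * (1.0 - self.P)
        )


def observed_to_liability(h2_o: float, params: LiabilityParams) -> float:
    """Convert observed-scale heritability to the liability scale.

    h2_o may legitimately exceed 1 under strong ascertainment.
    """
    return h2_o * params.factor


def liability_to_observed(h2_l: float, params: LiabilityParams) -> float:
    """Exact inverse of :func:`observed_to_liability`."""
    return h2_l / params.factor


def se_observed_to_liability(se_o: float, params: LiabilityParams) -> float:
    """Delta-method standard error on the liability scale (linear map)."""
    return se_o * params.factor
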