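"""The IBS-based Haseman-Elston regression.

For every pair of individuals a phenotype similarity score Y_ij — the
squared difference (y_i - y_j)^2 or the cross-product y_i y_j — is regressed
on the genetic relatedness Omega_ij.  On the standardized-phenotype scale
the squared-difference coefficient has expectation -2 h^2 Lambda, so
-b/2 estimates the tagged heritability; the cross-product coefficient has
half that magnitude and estimates h^2 Lambda directly.

The ordinary-least-squares fit over all N(N-1)/2 pairs is computed by
accumulating five sufficient statistics with matrix algebra; the pair-level
design matrix is never materialized, so the fit costs O(N^2) time and O(1)
memory beyond the relatedness matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grm import RelatednessMatrix, effective_marker_count

METHOD_SD = "squared-difference"
METHOD_CP = "cross-product"


@dataclass
class PhenotypeVector:
    """Phenotype values aligned to the relatedness sample order."""

    values: np.ndarray
    ids: list[tuple[str, str]] | None = None
    standardized: bool = False
    residualized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    def zscored(self) -> "PhenotypeVector":
        v = self.values
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("constant phenotype cannot be standardized")
        return PhenotypeVector((v - v.mean()) / sd, self.ids, standardized=True,
                               residualized=self.residualized)


@dataclass
class AnalyticSE:
    """Analytic sampling errors of the HE coefficient and heritability.

    ``se_b``/``se_h2`` use the large-sample simplification
    sqrt(16 M_e / (N (N-1))) valid for a standardized phenotype;
    ``se_b_full``/``se_h2_full`` keep the exact error sum of squares
    8 sigma_y^4 - 4 sigma_A^4.
    """

    se_b: float
    se_h2: float
    se_b_full: float
    se_h2_full: float


@dataclass
class HEFit:
    mu: float
    b: float
    se_b_analytic: float
    se_b_ols: float
    h2: float
    se_h2: float
    n_pairs: int
    me: float
    method: str
    phenotype_standardized: bool
    h2_out_of_range: bool = False
    se_b_analytic_full: float = float("nan")


class HEInputError(ValueError):
    pass


def pair_response(y: PhenotypeVector | np.ndarray, method: str = METHOD_SD) -> np.ndarray:
    """Pairwise response Y_ij over i < j in lexicographic order.

    Materializes the full pair vector; intended for inspection and small N.
    """
    v = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    if v.size < 2:
        raise HEInputError("at least two individuals required")
    iu, ju = np.triu_indices(v.size, k=1)
    if method == METHOD_SD:
        return (v[iu] - v[ju]) ** 2
    if method == METHOD_CP:
        return v[iu] * v[ju]
    raise ValueError(f"unknown method {method!r}")


def _pair_sufficient_stats(v: np.ndarray, omega: np.ndarray, method: str):
    """Sums over i<j of (1, Omega, Omega^2, Y, Y*Omega, Y^2) in closed form."""
    n = v.size
    od = omega.copy()
    np.fill_diagonal(od, 0.0)
    n_pairs = n * (n - 1) // 2
    s_o = od.sum() / 2.0
    s_oo = (od * od).sum() / 2.0
    a1, a2 = v.sum(), (v**2).sum()
    a3, a4 = (v**3).sum(), (v**4).sum()
    row = od.sum(axis=1)
    quad = v @ od @ v
    if method == METHOD_SD:
        s_y = n * a2 - a1**2
        s_yo = (v**2) @ row - quad
        s_yy = n * a4 + 3 * a2**2 - 4 * a3 * a1
    elif method == METHOD_CP:
        s_y = (a1**2 - a2) / 2.0
        s_yo = quad / 2.0
        s_yy = (a2**2 - a4) / 2.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return n_pairs, s_o, s_oo, s_y, s_yo, s_yy


def analytic_se(n: int, me: float, sigma2_a: float = 0.5, sigma2_y: float = 1.0,
                d: int = 1) -> AnalyticSE:
    """Analytic standard errors of the HE coefficient and of -b/2.

    Full form: se_b^2 = [(8 sigma_y^4 - 4 sigma_A^4) / (n_pairs - d)] * M_e,
    with var(Omega) = 1/M_e and d regression parameters (default 1).
    Simplified form (standardized phenotype, 8 M_e >> 4 sigma_A^4 Lambda^2):
    se_b = sqrt(16 M_e / (N (N-1))), se_h2 = se_b / 2.
    """
    if n < 3:
        raise ValueError("N must be at least 3")
    if me <= 0:
        raise ValueError("effective marker count must be positive")
    n_pairs = n * (n - 1) // 2
    if n_pairs <= d:
        raise ValueError("pair count must exceed the parameter count d")
    sse = 8.0 * sigma2_y**2 - 4.0 * sigma2_a**2
    se_b_full = math.sqrt(sse / (n_pairs - d) * me)
    se_b = math.sqrt(16.0 * me / (n * (n - 1)))
    return AnalyticSE(se_b=se_b, se_h2=se_b / 2.0,
                      se_b_full=se_b_full, se_h2_full=se_b_full / 2.0)


def he_fit(y: PhenotypeVector, grm: RelatednessMatrix, method: str = METHOD_SD,
           standardize: bool = True) -> HEFit:
    """Fit the HE regression of Y_ij on Omega_ij over all pairs.

    With ``standardize`` (default) the phenotype is z-scored first and the
    heritability is -b/2 (squared-difference) or b (cross-product); the
    unstandardized squared-difference path uses -b/mu instead.  Estimates
    outside [0, 1] are flagged, never clipped.
    """
    if y.n != grm.n:
        raise HEInputError(f"phenotype length {y.n} != sample count {grm.n}")
    if y.n < 3:
        raise HEInputError("HE regression needs at least 3 individuals")
    yv = y.zscored() if standardize and not y.standardized else y
    v = yv.values
    if method == METHOD_CP and not (standardize or y.standardized):
        v = v - v.mean()  # cross-product carries covariance only if centered
    n_pairs, s_o, s_oo, s_y, s_yo, s_yy = _pair_sufficient_stats(v, grm.omega, method)
    sxx = s_oo - s_o**2 / n_pairs
    if sxx <= 0:
        raise HEInputError("zero variance of relatedness across pairs")
    sxy = s_yo - s_y * s_o / n_pairs
    syy = s_yy - s_y**2 / n_pairs
    b = sxy / sxx
    mu = (s_y - b * s_o) / n_pairs
    sse_ols = max(syy - b * sxy, 0.0)
    se_b_ols = math.sqrt(sse_ols / (n_pairs - 2) / sxx)

    standardized = standardize or y.standardized
    if method == METHOD_SD:
        h2 = -b / 2.0 if standardized else -b / mu
    else:
        # cross-product coefficient directly carries the tagged variance
        h2 = b if standardized else b / (v.var(ddof=1))
    out_of_range = not (0.0 <= h2 <= 1.0)
    if out_of_range:
        warnings.warn(f"heritability estimate {h2:.4f} outside [0, 1]; not clipped",
                      RuntimeWarning, stacklevel=2)

    stats = effective_marker_count(grm)
    sigma2_y = 1.0 if standardized else float(v.var(ddof=1))
    sigma2_a = h2 * sigma2_y
    se = analytic_se(y.n, stats.me, sigma2_a=sigma2_a, sigma2_y=sigma2_y)
    scale = 1.0 if method == METHOD_SD else 0.5  # |b_CP| = |b_SD| / 2
    return HEFit(
        mu=mu, b=b,
        se_b_analytic=se.se_b * scale,
        se_b_ols=se_b_ols,
        h2=h2,
        se_h2=se.se_h2,
        n_pairs=n_pairs,
        me=stats.me,
        method=method,
        phenotype_standardized=standardized,
        h2_out_of_range=out_of_range,
        se_b_analytic_full=se.se_b_full * scale,
    )


def residualize_covariates(y: PhenotypeVector, covariates: np.ndarray) -> PhenotypeVector:
    """Replace the phenotype by residuals from OLS on covariates + intercept."""
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.n:
        raise ValueError("covariate rows must align with samples")
    X = np.column_stack([np.ones(y.n), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(X, y.values, rcond=None)
    resid = y.values - X @ coef
    return PhenotypeVector(resid, y.ids, standardized=False, residualized=True)


@dataclass
class MultiComponentFit:
    b: np.ndarray
    mu: float
    h2: np.ndarray
    n_pairs: int


def multi_component_he(y: PhenotypeVector, grms: list[RelatednessMatrix],
                       standardize: bool = True) -> MultiComponentFit:
    """HE regression on several relatedness components jointly.

    Y_ij is regressed on (Omega^(1)_ij, ..., Omega^(C)_ij) with an
    intercept; per-component heritability is -b_c / 2 on the standardized
    scale.  Used e.g. for per-chromosome partitioning of the genetic
    variance.
    """
    if not grms:
        raise ValueError("at least one relatedness component required")
    n = y.n
    if any(g.n != n for g in grms):
        raise ValueError("all components must align with the phenotype")
    yv = y.zscored() if standardize and not y.standardized else y
    iu = np.triu_indices(n, k=1)
    cols = [g.omega[iu] for g in grms]
    for a in range(len(cols)):
        for b_ in range(a + 1, len(cols)):
            c = np.corrcoef(cols[a], cols[b_])[0, 1]
            if abs(c) > 0.999:
                raise ValueError(
                    f"components {a} and {b_} are collinear (|corr| = {abs(c):.4f})"
                )
    Y = pair_response(yv, METHOD_SD)
    X = np.column_stack([np.ones(Y.size)] + cols)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    b = coef[1:]
    return MultiComponentFit(b=b, mu=coef[0], h2=-b / 2.0, n_pairs=Y.size)
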