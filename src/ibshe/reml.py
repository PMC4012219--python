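"""Single-component GREML via eigendecomposition and 1-D profiling.

Model: y = X b + g + e with cov(g) = sigma2_g Omega and cov(e) = sigma2_e I.
Writing V = sigma2 [h2 Omega + (1 - h2) I], the restricted likelihood is
profiled analytically over sigma2 and numerically over h2 on the eigenbasis
of Omega; one eigendecomposition per dataset makes every likelihood
evaluation O(N).  For one variance ratio this is exact and avoids the
convergence pathologies of iterative AI-REML schemes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .grm import RelatednessMatrix
from .he_core import PhenotypeVector

_EIG_FLOOR = -1e-8


@dataclass
class REMLFit:
    h2: float
    sigma2_g: float
    sigma2_e: float
    loglik: float
    se_h2: float
    constrained: bool
    converged: bool


@dataclass
class _Profile:
    """Rotated data reused across likelihood evaluations."""

    eigvals: np.ndarray
    y_rot: np.ndarray
    x_rot: np.ndarray

    @property
    def n(self) -> int:
        return self.y_rot.size

    @property
    def p(self) -> int:
        return self.x_rot.shape[1]


def _prepare(y: PhenotypeVector, grm: RelatednessMatrix,
             covariates: np.ndarray | None = None) -> _Profile:
    if y.n != grm.n:
        raise ValueError("phenotype and relatedness dimensions differ")
    if y.n < 10:
        raise ValueError("REML needs at least 10 individuals")
    X = np.ones((y.n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([X, C])
    w, U = np.linalg.eigh(grm.omega)
    if w.min() < _EIG_FLOOR * max(1.0, abs(w.max())):
        w = np.clip(w, 0.0, None)  # PSD repair for numerically indefinite GRMs
    return _Profile(eigvals=w, y_rot=U.T @ y.values, x_rot=U.T @ X)


def reml_loglik(h2: float, profile: _Profile) -> float:
    """Restricted log-likelihood at variance ratio h2 (sigma2 profiled out).

    Returns -inf where h2 makes the covariance h2 L + (1 - h2) I singular
    or indefinite.
    """
    w = 1.0 + h2 * (profile.eigvals - 1.0)
    if w.min() <= 1e-12:
        return -np.inf
    inv = 1.0 / w
    X, yv = profile.x_rot, profile.y_rot
    xtwx = X.T @ (X * inv[:, None])
    xtwy = X.T @ (yv * inv)
    try:
        beta = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = yv - X @ beta
    quad = float(resid @ (resid * inv))
    n, p = profile.n, profile.p
    if quad <= 0:
        return -np.inf
    sigma2 = quad / (n - p)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    ll = -0.5 * (
        (n - p) * (math.log(2.0 * math.pi * sigma2) + 1.0)
        + float(np.log(w).sum())
        + logdet_xtwx
    )
    return ll


def _feasible_interval(eigvals: np.ndarray, span: float = 5.0) -> tuple[float, float]:
    """Open h2 interval on which 1 + h2 (lambda - 1) > 0 for all lambda."""
    lo, hi = -span, span
    lmin, lmax = float(eigvals.min()), float(eigvals.max())
    if lmin < 1.0:
        hi = min(hi, 1.0 / (1.0 - lmin))
    if lmax > 1.0:
        lo = max(lo, -1.0 / (lmax - 1.0))
    eps = 1e-6 * (hi - lo)
    return lo + eps, hi - eps


def reml_fit(y: PhenotypeVector, grm: RelatednessMatrix, constrained: bool = True,
             covariates: np.ndarray | None = None, tol: float = 1e-8) -> REMLFit:
    """Fit the one-component GREML model.

    ``constrained`` restricts h2 to [0, 1]; otherwise the search covers the
    full interval on which the covariance matrix stays positive definite
    (clipped to (-5, 5)), allowing observed-scale estimates above 1 under
    case-control ascertainment.
    """
    profile = _prepare(y, grm, covariates)
    if np.ptp(profile.eigvals) < 1e-10:
        raise ValueError("relatedness matrix is (numerically) a multiple of I; "
                         "variance components are unidentifiable")
    if constrained:
        lo, hi = 0.0, 1.0
    else:
        lo, hi = _feasible_interval(profile.eigvals)

    # coarse grid guards against flat shoulders before the bounded refine
    grid = np.linspace(lo, hi, 41)
    vals = np.array([reml_loglik(float(h), profile) for h in grid])
    if not np.isfinite(vals).any():
        return REMLFit(h2=float("nan"), sigma2_g=float("nan"), sigma2_e=float("nan"),
                       loglik=float("-inf"), se_h2=float("nan"),
                       constrained=constrained, converged=False)
    k = int(np.argmax(vals))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(lambda h: -reml_loglik(float(h), profile),
                                   bounds=(blo, bhi), method="bounded",
                                   options={"xatol": tol})
    h2 = float(res.x)
    ll = -float(res.fun)
    converged = bool(res.success) and np.isfinite(ll)

    # profiled total variance at the optimum
    w = 1.0 + h2 * (profile.eigvals - 1.0)
    inv = 1.0 / w
    X, yv = profile.x_rot, profile.y_rot
    beta = np.linalg.solve(X.T @ (X * inv[:, None]), X.T @ (yv * inv))
    resid = yv - X @ beta
    sigma2 = float(resid @ (resid * inv)) / (profile.n - profile.p)

    # observed-information SE from a central second difference of the profile
    step = max(1e-4, tol * 10)
    h_lo = max(h2 - step, lo + 1e-9)
    h_hi = min(h2 + step, hi - 1e-9)
    f0 = reml_loglik(h2, profile)
    f1 = reml_loglik(h_lo, profile)
    f2 = reml_loglik(h_hi, profile)
    d2 = (f1 - 2.0 * f0 + f2) / ((0.5 * (h_hi - h_lo)) ** 2)
    se = math.sqrt(-1.0 / d2) if d2 < 0 else float("nan")

    return REMLFit(h2=h2, sigma2_g=h2 * sigma2, sigma2_e=(1.0 - h2) * sigma2,
                   loglik=ll, se_h2=se, constrained=constrained,
                   converged=converged)
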