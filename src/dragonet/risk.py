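"""Penalty selection by minimizing the expected squared Frobenius risk.

The expected risk E||Sigma_hat - Sigma||_F^2 of the two-penalty shrinkage
estimator decomposes, up to an additive constant, into a bivariate
polynomial in (lambda_1, lambda_2) plus a sqrt((1-lambda_1)(1-lambda_2))
term. Its coefficients are functions of per-entry covariance moments
(var(s_ij) and E(s_ij^2)) that can be estimated from the data alone, so
the penalties are chosen analytically, without cross-validation:

    R - const = l1*T1_1 + l2*T1_2 + l1^2*T2_1 + l2^2*T2_2
                + l1*l2*T3 + sqrt(1-l1)*sqrt(1-l2)*T4

Minimizing along the diagonal l1 = l2 recovers the classical single-penalty
(layer-agnostic) selection for the appended data, used here as the GGM
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .covariance import BlockCovariance, block_covariances, shrunken_covariance
from .datatypes import PairedOmicsData
from .preprocessing import standardize


@dataclass
class CovarianceMoments:
    """Per-pair moment estimates of covariance entries.

    ``var_*`` holds the estimated sampling variance of s_ij; ``esq_*``
    holds the plug-in estimate s_ij^2 of the second moment E(s_ij^2)
    (unbiased, since E[s_ij^2] is its own expectation). Within-layer
    matrices are p_k x p_k (the diagonal is present but never summed);
    the cross matrix is p1 x p2.
    """

    var_s11: np.ndarray
    var_s22: np.ndarray
    var_s12: np.ndarray
    esq_s11: np.ndarray
    esq_s22: np.ndarray
    esq_s12: np.ndarray
    n: int


@dataclass
class RiskTerms:
    """Scalar coefficients of the lambda-dependent part of the risk."""

    t1_1: float
    t1_2: float
    t2_1: float
    t2_2: float
    t3: float
    t4: float

    def as_tuple(self):
        return (self.t1_1, self.t1_2, self.t2_1, self.t2_2, self.t3, self.t4)


@dataclass
class LambdaEstimate:
    """Selected shrinkage intensities and the (relative) risk at the optimum.

    ``risk_value`` omits the lambda-independent constant of the risk; only
    differences between candidate penalties are meaningful.
    """

    lambda1: float
    lambda2: float
    risk_value: float
    constrained: bool = False


def _pair_moments(Ya: np.ndarray, Yb: np.ndarray, n: int):
    """Moment matrices for all (i in a, j in b) pairs from centered data.

    With w_mij = y_mi * y_mj and wbar its sample mean:
        s_ij        = n/(n-1) * wbar_ij
        var(s_ij)   = n/(n-1)^3 * sum_m (w_mij - wbar_ij)^2
        E(s_ij^2)   is estimated by s_ij^2 itself, which is unbiased for
                    its own expectation var(s_ij) + sigma_ij^2.
    """
    wbar = (Ya.T @ Yb) / n
    wsq = (Ya * Ya).T @ (Yb * Yb)  # sum_m w_mij^2
    s = (n / (n - 1.0)) * wbar
    var = (n / (n - 1.0) ** 3) * (wsq - n * wbar**2)
    var = np.maximum(var, 0.0)  # guard tiny negative round-off
    esq = s * s
    return var, esq


def covariance_moments(data: PairedOmicsData, scale: bool = True) -> CovarianceMoments:
    """Estimate var(s_ij) and E(s_ij^2) for every covariance entry.

    Operates on standardized data by default, consistent with the
    covariance computation. Requires n >= 3 for the variance-of-covariance
    estimates to be meaningful.
    """
    n = data.n
    if n < 3:
        raise ValueError(f"moment estimation requires at least 3 samples, got {n}")
    X1, X2 = data.X1, data.X2
    if scale:
        X1 = standardize(X1, data.feature_ids_1)
        X2 = standardize(X2, data.feature_ids_2)
    Y1 = X1 - X1.mean(axis=0)
    Y2 = X2 - X2.mean(axis=0)
    var11, esq11 = _pair_moments(Y1, Y1, n)
    var22, esq22 = _pair_moments(Y2, Y2, n)
    var12, esq12 = _pair_moments(Y1, Y2, n)
    return CovarianceMoments(
        var_s11=var11, var_s22=var22, var_s12=var12,
        esq_s11=esq11, esq_s22=esq22, esq_s12=esq12, n=n,
    )


def _offdiag_sum(M: np.ndarray) -> float:
    return float(M.sum() - np.trace(M))


def risk_terms(moments: CovarianceMoments) -> RiskTerms:
    """Collapse the moment tables into the six risk coefficients.

    Within-layer sums run over off-diagonal pairs only (diagonal entries
    coincide with the target and contribute to the constant); cross-layer
    sums run over all p1*p2 pairs.
    """
    sum_var11 = _offdiag_sum(moments.var_s11)
    sum_var22 = _offdiag_sum(moments.var_s22)
    sum_esq11 = _offdiag_sum(moments.esq_s11)
    sum_esq22 = _offdiag_sum(moments.esq_s22)
    sum_var12 = float(moments.var_s12.sum())
    sum_esq12 = float(moments.esq_s12.sum())
    return RiskTerms(
        t1_1=-2.0 * (sum_var11 + sum_esq12),
        t1_2=-2.0 * (sum_var22 + sum_esq12),
        t2_1=sum_esq11,
        t2_2=sum_esq22,
        t3=2.0 * sum_esq12,
        t4=4.0 * (sum_var12 - sum_esq12),
    )


def risk(lambda1, lambda2, terms: RiskTerms):
    """Evaluate the relative risk R - const at (lambda1, lambda2).

    Accepts scalars or broadcastable arrays of penalties in [0, 1].
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 < 0) or np.any(l1 > 1) or np.any(l2 < 0) or np.any(l2 > 1):
        raise ValueError("penalties must lie in [0, 1]")
    t1_1, t1_2, t2_1, t2_2, t3, t4 = terms.as_tuple()
    val = (
        l1 * t1_1 + l2 * t1_2 + l1**2 * t2_1 + l2**2 * t2_2
        + l1 * l2 * t3 + np.sqrt(1.0 - l1) * np.sqrt(1.0 - l2) * t4
    )
    return val if val.ndim else float(val)


def _check_terms(terms: RiskTerms):
    if not all(np.isfinite(terms.as_tuple())):
        raise ValueError("risk terms must be finite")


def select_lambdas(terms: RiskTerms, grid_size: int = 101) -> LambdaEstimate:
    """Minimize the risk over the closed unit square.

    A coarse grid search (boundaries included) locates the basin; a
    bounded derivative-free refinement polishes the optimum. The grid
    stage is kept because the sqrt(1-lambda) term has unbounded slope at
    lambda = 1, which defeats gradient-based starts. Ties on the grid are
    broken toward smaller lambda1 + lambda2.
    """
    _check_terms(terms)
    g = np.linspace(0.0, 1.0, grid_size)
    L1, L2 = np.meshgrid(g, g, indexing="ij")
    R = risk(L1, L2, terms)
    flat = R.ravel()
    best = flat.min()
    ties = np.flatnonzero(flat <= best)
    sums = L1.ravel()[ties] + L2.ravel()[ties]
    idx = ties[np.argmin(sums)]
    x0 = np.array([L1.ravel()[idx], L2.ravel()[idx]])

    res = optimize.minimize(
        lambda x: risk(x[0], x[1], terms),
        x0,
        method="Nelder-Mead",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        options={"xatol": 1e-8, "fatol": 1e-12},
    )
    if np.isfinite(res.fun) and res.fun <= best:
        l1, l2 = np.clip(res.x, 0.0, 1.0)
        best = float(res.fun)
    else:
        l1, l2 = x0
    return LambdaEstimate(lambda1=float(l1), lambda2=float(l2), risk_value=float(best))


def select_lambda_diagonal(terms: RiskTerms, grid_size: int = 1001) -> LambdaEstimate:
    """Minimize the risk along lambda1 = lambda2 (single-penalty baseline).

    On the diagonal the sqrt term is linear, so the objective is an exact
    quadratic; the grid stage plus a bounded scalar refinement recovers
    its minimum. This is the layer-agnostic GGM comparator.
    """
    _check_terms(terms)

    def f(lam):
        return risk(lam, lam, terms)

    g = np.linspace(0.0, 1.0, grid_size)
    vals = f(g)
    idx = int(np.argmin(vals))
    lo = g[max(idx - 1, 0)]
    hi = g[min(idx + 1, grid_size - 1)]
    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    lam, val = (float(res.x), float(res.fun))
    if vals[idx] < val:
        lam, val = float(g[idx]), float(vals[idx])
    return LambdaEstimate(lambda1=lam, lambda2=lam, risk_value=val, constrained=True)


def monte_carlo_risk(
    sigma_true: np.ndarray,
    p1: int,
    lambda1_grid: np.ndarray,
    lambda2_grid: np.ndarray,
    n: int,
    reps: int,
    seed,
) -> np.ndarray:
    """Monte-Carlo estimate of the true risk surface (for validation).

    For each (lambda1, lambda2) on the grid, averages
    ||Sigma_hat - Sigma||_F^2 over ``reps`` datasets of size n drawn from
    N(0, sigma_true). Because Sigma_hat is affine in the data blocks for
    fixed penalties, the squared distance collapses to a quadratic in
    (l1, l2, sqrt((1-l1)(1-l2))) with eight data-dependent coefficients
    per replicate, which is what is accumulated.
    """
    sigma_true = np.asarray(sigma_true, dtype=float)
    p = sigma_true.shape[0]
    try:
        chol = np.linalg.cholesky(sigma_true)
    except np.linalg.LinAlgError as err:
        raise ValueError("sigma_true must be positive definite") from err
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    l1g = np.asarray(lambda1_grid, dtype=float)
    l2g = np.asarray(lambda2_grid, dtype=float)
    L1, L2 = np.meshgrid(l1g, l2g, indexing="ij")
    C = np.sqrt(1.0 - L1) * np.sqrt(1.0 - L2)

    S11_t = sigma_true[:p1, :p1]
    S12_t = sigma_true[:p1, p1:]
    S22_t = sigma_true[p1:, p1:]

    acc = np.zeros_like(L1)
    for _ in range(reps):
        X = rng.standard_normal((n, p)) @ chol.T
        Y = X - X.mean(axis=0)
        S = (Y.T @ Y) / (n - 1)
        S11, S12, S22 = S[:p1, :p1], S[:p1, p1:], S[p1:, p1:]
        T1 = np.diag(np.diag(S11))
        T2 = np.diag(np.diag(S22))
        # block (1,1): ||A1 + l1*B1||^2 with A1 = S11 - Sigma11, B1 = T1 - S11
        A1, B1 = S11 - S11_t, T1 - S11
        A2, B2 = S22 - S22_t, T2 - S22
        acc += (A1 * A1).sum() + 2 * L1 * (A1 * B1).sum() + L1**2 * (B1 * B1).sum()
        acc += (A2 * A2).sum() + 2 * L2 * (A2 * B2).sum() + L2**2 * (B2 * B2).sum()
        # both cross blocks: 2 * ||c*S12 - Sigma12||^2
        acc += 2 * (C**2 * (S12 * S12).sum() - 2 * C * (S12 * S12_t).sum() + (S12_t * S12_t).sum())
    return acc / reps
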