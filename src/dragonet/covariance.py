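"""Block covariances and the two-penalty shrunken covariance / precision estimator.

The joint covariance of two paired layers is assembled from four blocks
S^(k,l). Shrinkage replaces the diagonal blocks by convex combinations
(1-lambda_k) S^(k,k) + lambda_k T^(k) with diagonal targets
T^(k) = diag(S^(k,k)), and scales the cross block by
sqrt(1-lambda_1) sqrt(1-lambda_2). With nonzero penalties the result is
positive definite even when p > n, so the precision matrix exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datatypes import PairedOmicsData
from .preprocessing import standardize


@dataclass
class BlockCovariance:
    """Empirical covariance blocks of a paired two-layer dataset.

    Only S12 is stored for the cross block; S21 is its transpose by
    construction. ``t1`` and ``t2`` are the diagonal shrinkage targets,
    equal to the diagonals of S11 and S22.
    """

    S11: np.ndarray
    S12: np.ndarray
    S22: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    n: int

    @property
    def p1(self) -> int:
        return self.S11.shape[0]

    @property
    def p2(self) -> int:
        return self.S22.shape[0]

    @property
    def p(self) -> int:
        return self.p1 + self.p2


def block_covariances(data: PairedOmicsData, scale: bool = True) -> BlockCovariance:
    """Compute the unbiased (1/(n-1)) covariance blocks S^(1,1), S^(1,2), S^(2,2).

    Parameters
    ----------
    data
        Paired two-layer dataset with n >= 2.
    scale
        Standardize each feature (mean 0, unit sd) before computing the
        blocks; the default, matching how variables enter performance
        comparisons. Targets are diag(S) either way.
    """
    n = data.n
    if n < 2:
        raise ValueError(f"need at least 2 samples to estimate covariances, got {n}")
    X1, X2 = data.X1, data.X2
    if scale:
        X1 = standardize(X1, data.feature_ids_1)
        X2 = standardize(X2, data.feature_ids_2)
    mu1 = X1.mean(axis=0)
    mu2 = X2.mean(axis=0)
    Y1 = X1 - mu1
    Y2 = X2 - mu2
    S11 = (Y1.T @ Y1) / (n - 1)
    S22 = (Y2.T @ Y2) / (n - 1)
    S12 = (Y1.T @ Y2) / (n - 1)
    S11 = (S11 + S11.T) / 2
    S22 = (S22 + S22.T) / 2
    return BlockCovariance(
        S11=S11, S12=S12, S22=S22, mu1=mu1, mu2=mu2,
        t1=np.diag(S11).copy(), t2=np.diag(S22).copy(), n=n,
    )


def _check_lambda(lam: float, name: str) -> float:
    lam = float(lam)
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {lam}")
    return lam


def shrunken_covariance(blocks: BlockCovariance, lambda1: float, lambda2: float) -> np.ndarray:
    """Assemble the (p1+p2) x (p1+p2) shrunken covariance.

    Diagonal blocks are (1-lambda_k) S^(k,k) + lambda_k diag(S^(k,k));
    the cross block is sqrt(1-lambda_1) sqrt(1-lambda_2) S^(1,2). At
    lambda_1 = lambda_2 this reduces to single-penalty shrinkage of the
    appended data; at lambda_2 = 1 layer 1 decouples from layer 2.
    """
    l1 = _check_lambda(lambda1, "lambda1")
    l2 = _check_lambda(lambda2, "lambda2")
    p1, p2 = blocks.p1, blocks.p2
    sigma = np.empty((p1 + p2, p1 + p2))
    top = (1.0 - l1) * blocks.S11
    top[np.diag_indices(p1)] = (1.0 - l1) * blocks.t1 + l1 * blocks.t1
    bot = (1.0 - l2) * blocks.S22
    bot[np.diag_indices(p2)] = (1.0 - l2) * blocks.t2 + l2 * blocks.t2
    cross = np.sqrt(1.0 - l1) * np.sqrt(1.0 - l2) * blocks.S12
    sigma[:p1, :p1] = top
    sigma[p1:, p1:] = bot
    sigma[:p1, p1:] = cross
    sigma[p1:, :p1] = cross.T
    return sigma


def precision(sigma_hat: np.ndarray) -> np.ndarray:
    """Invert a shrunken covariance via Cholesky; returns a symmetrized inverse.

    Fails (rather than silently regularizing) if the matrix is not
    positive definite — e.g. at lambda_1 = lambda_2 = 0 with p > n — since
    nonzero shrinkage is the intended remedy.
    """
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    try:
        c, low = linalg.cho_factor(sigma_hat, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            "shrunken covariance is not positive definite; increase the "
            "shrinkage intensities (lambda1, lambda2 > 0)"
        ) from err
    theta = linalg.cho_solve((c, low), np.eye(sigma_hat.shape[0]), check_finite=False)
    return (theta + theta.T) / 2
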