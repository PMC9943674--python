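"""Partial correlations and their shrunken-null significance.

Shrinkage compresses partial correlations toward zero, so their null
distribution is supported on (-(1-lambda), 1-lambda) rather than (-1, 1).
The null density used here is

    f(rho) = ((1-lambda)^2 - rho^2)^((kappa-3)/2)
             / ( Beta(1/2, (kappa-1)/2) * (1-lambda)^(kappa-2) ),

a scaled symmetric Beta law: t = rho/(1-lambda) has t^2 ~ Beta(1/2,
(kappa-1)/2). For n >> p the shape parameter is kappa = n - 1 - (p - 2);
otherwise kappa is fitted per block by maximum likelihood on partial
correlations recomputed from data simulated under the global null with
the penalties held fixed at the values selected on the observed data.
p-values are two-sided tail areas; Benjamini-Hochberg adjustment is
applied within each block separately, which also controls the overall FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.multitest import multipletests

from .covariance import block_covariances, precision, shrunken_covariance
from .datatypes import PairedOmicsData

_BLOCKS = ("11", "12", "22")
_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class PartialCorrelationNetwork:
    """Partial-correlation matrix of a fitted model, split into layer blocks."""

    P: np.ndarray
    p1: int

    @property
    def p(self) -> int:
        return self.P.shape[0]

    @property
    def p2(self) -> int:
        return self.p - self.p1

    @property
    def P11(self) -> np.ndarray:
        return self.P[: self.p1, : self.p1]

    @property
    def P12(self) -> np.ndarray:
        return self.P[: self.p1, self.p1 :]

    @property
    def P22(self) -> np.ndarray:
        return self.P[self.p1 :, self.p1 :]

    def block_values(self, block: str) -> np.ndarray:
        """Unique partial correlations of one block as a flat vector."""
        if block == "11":
            return self.P11[np.triu_indices(self.p1, 1)]
        if block == "22":
            return self.P22[np.triu_indices(self.p2, 1)]
        if block == "12":
            return self.P12.ravel()
        raise ValueError(f"unknown block {block!r}")


@dataclass
class NullCalibration:
    """Per-block effective shrinkage and fitted null shape parameter."""

    lambda1: float
    lambda2: float
    lambda_eff: dict = field(default_factory=dict)  # block -> lambda in [0,1]
    kappa: dict = field(default_factory=dict)  # block -> kappa > 1
    n_null: dict = field(default_factory=dict)  # block -> sample count used
    seed: object = None
    mode: str = "empirical"
    #: layer-agnostic calibration: one null density fitted on all pairs
    #: pooled, and a single BH adjustment across the whole network
    #: (requires lambda1 == lambda2)
    pooled: bool = False


def partial_correlations(theta_hat: np.ndarray, p1: int) -> PartialCorrelationNetwork:
    """Convert a precision matrix to partial correlations.

    rho_ij = -theta_ij / sqrt(theta_ii * theta_jj) for i != j; the
    diagonal is stored as 0 (self-edges are excluded).
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    d = np.diag(theta_hat)
    if np.any(d <= 0):
        raise ValueError("precision matrix must have strictly positive diagonal")
    scale = 1.0 / np.sqrt(d)
    P = -theta_hat * scale[:, None] * scale[None, :]
    np.fill_diagonal(P, 0.0)
    return PartialCorrelationNetwork(P=P, p1=p1)


def effective_lambda(block: str, lambda1: float, lambda2: float) -> float:
    """Shrinkage intensity entering the null density for one block.

    The within-layer blocks use their own penalty. The cross block of the
    shrunken covariance is scaled by sqrt((1-lambda1)(1-lambda2)), so its
    effective intensity is 1 - sqrt((1-lambda1)(1-lambda2)); at
    lambda1 = lambda2 = lambda all three blocks coincide at lambda.
    """
    for lam, name in ((lambda1, "lambda1"), (lambda2, "lambda2")):
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if block == "11":
        return float(lambda1)
    if block == "22":
        return float(lambda2)
    if block == "12":
        return float(1.0 - np.sqrt((1.0 - lambda1) * (1.0 - lambda2)))
    raise ValueError(f"unknown block {block!r}")


def _check_null_params(lambda_eff: float, kappa: float):
    if kappa <= 1:
        raise ValueError(f"kappa must exceed 1 for a normalizable density, got {kappa}")
    if not (0.0 <= lambda_eff < 1.0):
        raise ValueError(f"lambda_eff must lie in [0, 1), got {lambda_eff}")


def null_density(rho, lambda_eff: float, kappa: float):
    """Shrunken-null density of a partial correlation; 0 outside the support."""
    _check_null_params(lambda_eff, kappa)
    rho = np.asarray(rho, dtype=float)
    width = 1.0 - lambda_eff
    inside = np.abs(rho) < width
    out = np.zeros_like(rho, dtype=float)
    r = rho[inside]
    log_f = (
        ((kappa - 3.0) / 2.0) * np.log(width**2 - r**2)
        - special.betaln(0.5, (kappa - 1.0) / 2.0)
        - (kappa - 2.0) * np.log(width)
    )
    out[inside] = np.exp(log_f)
    return out if out.ndim else float(out)


def p_value(rho, lambda_eff: float, kappa: float):
    """Two-sided tail probability of |rho| under the shrunken null.

    Uses the regularized incomplete beta function on t^2 with
    t = |rho|/(1-lambda); values at or beyond the support edge are clamped
    just inside, so p is small but never exactly 0. Floored at the
    smallest positive normal float.
    """
    _check_null_params(lambda_eff, kappa)
    rho = np.asarray(rho, dtype=float)
    t = np.minimum(np.abs(rho) / (1.0 - lambda_eff), 1.0 - 1e-15)
    p = 1.0 - special.betainc(0.5, (kappa - 1.0) / 2.0, t * t)
    p = np.maximum(p, _P_FLOOR)
    return p if p.ndim else float(p)


def simulate_null(
    n: int,
    p1: int,
    p2: int,
    lambda1: float,
    lambda2: float,
    seed,
    scale: bool = True,
) -> dict:
    """Recompute partial correlations on data simulated under the global null.

    Draws X1, X2 with all entries independent standard normal (H0:
    rho = 0 everywhere), runs the full shrinkage estimator with the
    *supplied* penalties — no re-selection — and returns the three blocks
    of resulting partial correlations as flat vectors keyed by
    '11', '12', '22'.
    """
    rng = np.random.default_rng(seed)
    data = PairedOmicsData(
        X1=rng.standard_normal((n, p1)),
        X2=rng.standard_normal((n, p2)),
        validate=False,
    )
    blocks = block_covariances(data, scale=scale)
    theta = precision(shrunken_covariance(blocks, lambda1, lambda2))
    net = partial_correlations(theta, p1)
    return {b: net.block_values(b) for b in _BLOCKS}


def fit_kappa(null_samples: np.ndarray, lambda_eff: float) -> float:
    """Maximum-likelihood estimate of kappa from null partial correlations.

    The log likelihood is linear in kappa given sum(log((1-l)^2 - rho^2)),
    so each objective evaluation is O(1) after one pass over the samples.
    Optimized over log(kappa) on a bounded interval. Samples at or beyond
    the support edge are clamped just inside before evaluation.
    """
    if not (0.0 <= lambda_eff < 1.0):
        raise ValueError("lambda_eff must lie in [0, 1)")
    rho = np.abs(np.asarray(null_samples, dtype=float))
    if rho.size < 100:
        raise ValueError(f"need at least 100 null samples to fit kappa, got {rho.size}")
    width = 1.0 - lambda_eff
    clamp = width * (1.0 - 1e-12)
    n_clamped = int(np.count_nonzero(rho >= clamp))
    if n_clamped == rho.size:
        raise ValueError("all null samples lie at the support edge; cannot fit kappa")
    rho = np.minimum(rho, clamp)
    N = rho.size
    slog = float(np.log(width**2 - rho**2).sum())
    logw = np.log(width)

    def neg_loglik(log_kappa):
        kappa = np.exp(log_kappa)
        return -(
            ((kappa - 3.0) / 2.0) * slog
            - N * special.betaln(0.5, (kappa - 1.0) / 2.0)
            - N * (kappa - 2.0) * logw
        )

    res = optimize.minimize_scalar(
        neg_loglik,
        bounds=(np.log(2.001), np.log(1e7)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(np.exp(res.x))


def analytic_kappa(n: int, p: int) -> float:
    """Closed-form kappa = n - 1 - (p - 2), valid only for n >> p.

    p is the total number of variables across both layers (the full
    conditioning set).
    """
    kappa = n - 1 - (p - 2)
    if kappa <= 1:
        raise ValueError(
            f"n - 1 - (p - 2) = {kappa} <= 1: the null density is degenerate; "
            "use the empirical MLE calibration instead"
        )
    return float(kappa)


def calibrate_null(
    n: int,
    p1: int,
    p2: int,
    lambda1: float,
    lambda2: float,
    seed=0,
    reps: int = 1,
    mode: str = "empirical",
    scale: bool = True,
    pooled: bool = False,
) -> NullCalibration:
    """Calibrate the per-block null densities for a fitted model.

    ``mode='empirical'`` (default) simulates ``reps`` null datasets of the
    same (n, p1, p2), pools the resulting partial correlations per block,
    and fits kappa by MLE. ``mode='analytic'`` uses kappa = n-1-(p-2) for
    all blocks; only appropriate when the caller asserts n >> p.

    ``pooled=True`` gives the layer-agnostic calibration used by the
    single-penalty baseline: the whole network is one block, kappa is
    fitted on all null partial correlations together, and downstream BH
    runs once across all pairs. Requires lambda1 == lambda2.
    """
    if pooled and lambda1 != lambda2:
        raise ValueError("pooled (layer-agnostic) calibration requires lambda1 == lambda2")
    cal = NullCalibration(lambda1=float(lambda1), lambda2=float(lambda2), seed=seed,
                          mode=mode, pooled=pooled)
    for b in _BLOCKS:
        cal.lambda_eff[b] = effective_lambda(b, lambda1, lambda2)
    if mode == "analytic":
        kappa = analytic_kappa(n, p1 + p2)
        for b in _BLOCKS:
            cal.kappa[b] = kappa
            cal.n_null[b] = 0
        return cal
    if mode != "empirical":
        raise ValueError(f"unknown calibration mode {mode!r}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pooled_draws = {b: [] for b in _BLOCKS}
    for child in ss.spawn(reps):
        draws = simulate_null(n, p1, p2, lambda1, lambda2, child, scale=scale)
        for b in _BLOCKS:
            pooled_draws[b].append(draws[b])
    if pooled:
        samples = np.concatenate([v for b in _BLOCKS for v in pooled_draws[b]])
        kappa = fit_kappa(samples, cal.lambda_eff["11"])
        for b in _BLOCKS:
            cal.kappa[b] = kappa
            cal.n_null[b] = samples.size
    else:
        for b in _BLOCKS:
            samples = np.concatenate(pooled_draws[b])
            cal.kappa[b] = fit_kappa(samples, cal.lambda_eff[b])
            cal.n_null[b] = samples.size
    return cal


def _pair_indices(p1: int, p2: int):
    """Upper-triangle pair index arrays (i, j, block code) for p1+p2 variables.

    Block codes: 0 -> (1,1), 1 -> (1,2), 2 -> (2,2); ordering matches
    np.triu_indices(p, 1) on the joint matrix.
    """
    p = p1 + p2
    iu, ju = np.triu_indices(p, 1)
    code = np.where(ju < p1, 0, np.where(iu < p1, 1, 2))
    return iu, ju, code


def score_pairs(network: PartialCorrelationNetwork, calibration: NullCalibration):
    """Vectorized per-pair scores over the joint upper triangle.

    Returns (i, j, block_code, rho, p, q) arrays aligned with
    np.triu_indices(p, 1). q-values come from Benjamini-Hochberg applied
    within each block separately, or once across all pairs when the
    calibration is pooled (layer-agnostic baseline).
    """
    p1, p2 = network.p1, network.p2
    iu, ju, code = _pair_indices(p1, p2)
    rho = network.P[iu, ju]
    if calibration.pooled:
        pvals = p_value(rho, calibration.lambda_eff["11"], calibration.kappa["11"])
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        pvals = np.empty_like(rho)
        qvals = np.empty_like(rho)
        for bcode, bname in zip((0, 1, 2), _BLOCKS):
            mask = code == bcode
            if not np.any(mask):
                continue
            pvals[mask] = p_value(rho[mask], calibration.lambda_eff[bname], calibration.kappa[bname])
            qvals[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    qvals = np.maximum(qvals, _P_FLOOR)
    return iu, ju, code, rho, pvals, qvals


def score_edges(
    network: PartialCorrelationNetwork,
    calibration: NullCalibration,
    feature_ids=None,
) -> pd.DataFrame:
    """Build the per-edge table: one row per unordered variable pair.

    Columns: feature_a, layer_a, feature_b, layer_b, block,
    partial_correlation, p_value, q_value; sorted by (q, p, names).
    """
    iu, ju, code, rho, pvals, qvals = score_pairs(network, calibration)
    p1 = network.p1
    if feature_ids is None:
        feature_ids = [f"L1:V{k}" for k in range(p1)] + [f"L2:V{k}" for k in range(network.p2)]
    names = np.asarray(feature_ids, dtype=object)
    block_names = np.array(["(1,1)", "(1,2)", "(2,2)"], dtype=object)
    table = pd.DataFrame(
        {
            "feature_a": names[iu],
            "layer_a": np.where(iu < p1, 1, 2),
            "feature_b": names[ju],
            "layer_b": np.where(ju < p1, 1, 2),
            "block": block_names[code],
            "partial_correlation": rho,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    table = table.sort_values(
        ["q_value", "p_value", "feature_a", "feature_b"], kind="mergesort"
    ).reset_index(drop=True)
    return table
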