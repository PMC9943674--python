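"""Model / Results objects tying the estimation pipeline together.

``DragonGGM`` holds a paired two-layer dataset; ``fit`` selects the
shrinkage penalties by risk minimization (two free penalties, or a single
shared penalty for the layer-agnostic baseline), inverts the shrunken
covariance, converts to partial correlations, calibrates the per-block
null densities, and scores every edge. The returned ``DragonResults``
carries the estimates and diagnostics, statsmodels-style.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariance as _cov
from . import significance as _sig
from .datatypes import PairedOmicsData
from .risk import (
    LambdaEstimate,
    RiskTerms,
    covariance_moments,
    risk_terms,
    select_lambda_diagonal,
    select_lambdas,
)


class DragonGGM:
    """Two-layer Gaussian graphical model with per-layer covariance shrinkage.

    Parameters
    ----------
    data
        ``PairedOmicsData`` with aligned samples.
    standardize
        Standardize each feature (mean 0, unit sd) before computing
        covariances and moments. Default True.

    Examples
    --------
    >>> truth = generate_precision(study_config("C"), seed=1)
    >>> data = sample_dataset(truth, n=256, seed=2)
    >>> res = DragonGGM(data).fit(null_seed=3)
    >>> res.lambdas, res.edges.head()
    """

    def __init__(self, data: PairedOmicsData, standardize: bool = True):
        self.data = data
        self.standardize = bool(standardize)

    @classmethod
    def from_dataframes(cls, df1: pd.DataFrame, df2: pd.DataFrame, standardize: bool = True):
        """Build from two samples x features DataFrames (index = sample IDs).

        Sample IDs are inner-joined, preserving the order of ``df1``.
        """
        from .io import align_samples

        return cls(align_samples(df1, df2), standardize=standardize)

    def fit(
        self,
        method: str = "dragon",
        lambdas: tuple | None = None,
        kappa_mode: str = "empirical",
        null_seed=0,
        null_reps: int = 1,
        compute_edges: bool = True,
    ) -> "DragonResults":
        """Estimate the partial-correlation network.

        Parameters
        ----------
        method
            ``'dragon'`` selects (lambda1, lambda2) freely over the unit
            square; ``'ggm'`` constrains lambda1 = lambda2 (layer-agnostic
            single-penalty baseline).
        lambdas
            Fix the penalties instead of selecting them (used for null
            recomputation and ablation).
        kappa_mode
            ``'empirical'`` fits kappa per block by MLE on simulated null
            data; ``'analytic'`` uses n - 1 - (p - 2), valid for n >> p.
        null_seed, null_reps
            Seed and replicate count for the null simulation.
        compute_edges
            Skip null calibration and edge scoring when False (e.g. when
            only the penalties or the precision matrix are needed).
        """
        data = self.data
        blocks = _cov.block_covariances(data, scale=self.standardize)
        if lambdas is not None:
            l1, l2 = (float(lambdas[0]), float(lambdas[1]))
            est = LambdaEstimate(l1, l2, np.nan, constrained=(method == "ggm"))
            terms = None
        else:
            moments = covariance_moments(data, scale=self.standardize)
            terms = risk_terms(moments)
            if method == "dragon":
                est = select_lambdas(terms)
            elif method == "ggm":
                est = select_lambda_diagonal(terms)
            else:
                raise ValueError(f"unknown method {method!r}; expected 'dragon' or 'ggm'")
        sigma = _cov.shrunken_covariance(blocks, est.lambda1, est.lambda2)
        theta = _cov.precision(sigma)
        network = _sig.partial_correlations(theta, data.p1)
        calibration = None
        if compute_edges:
            # the single-penalty baseline is layer-agnostic end to end:
            # one pooled null density and a single BH pass
            calibration = _sig.calibrate_null(
                data.n, data.p1, data.p2,
                est.lambda1, est.lambda2,
                seed=null_seed, reps=null_reps, mode=kappa_mode,
                scale=self.standardize, pooled=(method == "ggm"),
            )
        return DragonResults(
            model=self,
            method=method,
            lambda_estimate=est,
            risk_terms=terms,
            sigma=sigma,
            theta=theta,
            network=network,
            calibration=calibration,
        )


@dataclass
class DragonResults:
    """Fitted two-layer shrinkage GGM."""

    model: DragonGGM
    method: str
    lambda_estimate: LambdaEstimate
    risk_terms: RiskTerms | None
    sigma: np.ndarray
    theta: np.ndarray
    network: _sig.PartialCorrelationNetwork
    calibration: _sig.NullCalibration | None
    _edges: pd.DataFrame | None = field(default=None, repr=False)
    _scores: tuple | None = field(default=None, repr=False)

    @property
    def lambdas(self) -> tuple:
        return (self.lambda_estimate.lambda1, self.lambda_estimate.lambda2)

    @property
    def partial_correlations(self) -> np.ndarray:
        return self.network.P

    def pair_scores(self):
        """(i, j, block_code, rho, p, q) arrays over the joint upper triangle."""
        if self.calibration is None:
            raise ValueError("fit was run with compute_edges=False; no calibration available")
        if self._scores is None:
            self._scores = _sig.score_pairs(self.network, self.calibration)
        return self._scores

    @property
    def edges(self) -> pd.DataFrame:
        """Per-edge table with partial correlation, p-value and BH q-value."""
        if self._edges is None:
            if self.calibration is None:
                raise ValueError("fit was run with compute_edges=False; no calibration available")
            self._edges = _sig.score_edges(
                self.network, self.calibration, self.model.data.feature_ids
            )
        return self._edges

    def significant_edges(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.edges[self.edges["q_value"] < alpha].reset_index(drop=True)

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text fit summary."""
        data = self.model.data
        lines = [
            "Two-layer shrinkage Gaussian graphical model",
            "=" * 52,
            f"method:          {self.method}",
            f"samples (n):     {data.n}",
            f"features:        p1={data.p1}, p2={data.p2} (p={data.p})",
            f"lambda1:         {self.lambda_estimate.lambda1:.6f}",
            f"lambda2:         {self.lambda_estimate.lambda2:.6f}",
        ]
        if np.isfinite(self.lambda_estimate.risk_value):
            lines.append(f"risk (rel.):     {self.lambda_estimate.risk_value:.6g}")
        if self.calibration is not None:
            for b in ("11", "12", "22"):
                lines.append(
                    f"block ({b[0]},{b[1]}):     lambda_eff={self.calibration.lambda_eff[b]:.4f}, "
                    f"kappa={self.calibration.kappa[b]:.2f}"
                )
            n_sig = int((self.edges["q_value"] < alpha).sum())
            lines.append(f"edges q<{alpha}:   {n_sig} of {len(self.edges)}")
        return "\n".join(lines)
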