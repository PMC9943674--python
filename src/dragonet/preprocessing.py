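"""Feature-wise preprocessing: standardization and the nonparanormal transform."""

from __future__ import annotations

import numpy as np
from scipy import stats


def standardize(X: np.ndarray, feature_names=None) -> np.ndarray:
    """Center each column to mean 0 and scale to unit sample sd (ddof=1).

    Raises ``ValueError`` naming the offending feature if a column is
    constant.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("standardize requires at least 2 samples")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        name = feature_names[bad[0]] if feature_names is not None else f"column {bad[0]}"
        raise ValueError(f"constant feature cannot be standardized: {name}")
    return (X - mu) / sd


def nonparanormal(X: np.ndarray, feature_names=None) -> np.ndarray:
    """Rank-based Gaussianization of each column.

    Each value is replaced by the standard-normal quantile of its average
    rank divided by n+1, making skewed continuous features approximately
    Gaussian while preserving within-feature order. Tied values map to
    identical outputs.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("nonparanormal requires at least 3 samples")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            name = feature_names[j] if feature_names is not None else f"column {j}"
            raise ValueError(f"constant feature cannot be transformed: {name}")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf(ranks / (n + 1))
    return out
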