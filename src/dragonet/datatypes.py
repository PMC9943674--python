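"""Container for paired two-layer omics data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def _as_matrix(X, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {X.shape}")
    return X


@dataclass
class PairedOmicsData:
    """Two sample-aligned omics matrices.

    Rows are samples (identical order in both layers), columns are features.
    Feature names must be unique; collisions across layers are resolved by
    prefixing ``L1:`` / ``L2:``. Features that are constant to machine
    precision are rejected: they carry no covariance information and would
    produce zero shrinkage targets.
    """

    X1: np.ndarray
    X2: np.ndarray
    sample_ids: Sequence[str] | None = None
    feature_ids_1: Sequence[str] | None = None
    feature_ids_2: Sequence[str] | None = None
    validate: bool = field(default=True, repr=False)

    def __post_init__(self):
        self.X1 = _as_matrix(self.X1, "X1")
        self.X2 = _as_matrix(self.X2, "X2")
        if self.X1.shape[0] != self.X2.shape[0]:
            raise ValueError(
                f"layers must share samples: X1 has {self.X1.shape[0]} rows, X2 has {self.X2.shape[0]}"
            )
        if self.sample_ids is None:
            self.sample_ids = [f"S{i}" for i in range(self.n)]
        else:
            self.sample_ids = list(map(str, self.sample_ids))
        if self.feature_ids_1 is None:
            self.feature_ids_1 = [f"L1:V{j}" for j in range(self.p1)]
        else:
            self.feature_ids_1 = list(map(str, self.feature_ids_1))
        if self.feature_ids_2 is None:
            self.feature_ids_2 = [f"L2:V{j}" for j in range(self.p2)]
        else:
            self.feature_ids_2 = list(map(str, self.feature_ids_2))
        if len(self.sample_ids) != self.n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.feature_ids_1) != self.p1 or len(self.feature_ids_2) != self.p2:
            raise ValueError("feature id lengths do not match matrix widths")
        if self.validate:
            self._validate()

    def _validate(self):
        for name, X in (("X1", self.X1), ("X2", self.X2)):
            if not np.all(np.isfinite(X)):
                raise ValueError(f"{name} contains missing or non-finite values")
        for k, (X, ids) in enumerate([(self.X1, self.feature_ids_1), (self.X2, self.feature_ids_2)], 1):
            if self.n >= 2:
                sd = X.std(axis=0, ddof=1)
                bad = np.flatnonzero(sd <= np.finfo(float).eps * np.maximum(1.0, np.abs(X).max(axis=0)))
                if bad.size:
                    raise ValueError(
                        f"layer {k} has constant feature(s): {[ids[j] for j in bad[:5]]}"
                    )
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate feature names within layer {k}")
        overlap = set(self.feature_ids_1) & set(self.feature_ids_2)
        if overlap:
            self.feature_ids_1 = [f"L1:{f}" if f in overlap else f for f in self.feature_ids_1]
            self.feature_ids_2 = [f"L2:{f}" if f in overlap else f for f in self.feature_ids_2]

    @property
    def n(self) -> int:
        return self.X1.shape[0]

    @property
    def p1(self) -> int:
        return self.X1.shape[1]

    @property
    def p2(self) -> int:
        return self.X2.shape[1]

    @property
    def p(self) -> int:
        return self.p1 + self.p2

    @property
    def feature_ids(self) -> list[str]:
        """Joint feature names, layer 1 first."""
        return list(self.feature_ids_1) + list(self.feature_ids_2)

    def appended(self) -> np.ndarray:
        """The n x (p1+p2) matrix [X1, X2]."""
        return np.hstack([self.X1, self.X2])
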