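"""Synthetic ground-truth networks and Gaussian datasets.

Sparse two-layer precision matrices are built in four steps: start from
the identity, fill a fixed number of randomly chosen off-diagonal
positions per block with Uniform(-1, 1) draws, make the diagonal strictly
dominant (theta_ii <- sum_j |theta_ij| + eps), and normalize to unit
diagonal. Data are drawn from N(0, Theta^{-1}) with independent Gaussian
measurement noise added to every entry. The study configurations mimic a
paired transcriptome/methylome design: a narrow layer (p1 = 100) and a
wide layer (p2 = 500) with varying within- and cross-layer edge densities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .datatypes import PairedOmicsData

#: edge densities eta per block (1,1), (1,2), (2,2) for studies A-C;
#: study D is specified by explicit counts (its printed densities are
#: rounded versions of count/positions, so counts are authoritative).
_STUDY_DENSITIES = {
    "A": (0.05, 0.05, 0.05),
    "B": (0.05, 0.05, 0.005),
    "C": (0.05, 0.005, 0.005),
}
_STUDY_D_COUNTS = (500, 500, 500)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class StudyConfig:
    """Configuration of a simulated two-layer network.

    Each block (1,1), (1,2), (2,2) is specified either by a density
    ``eta`` (fraction of available positions, converted to a count by
    round-half-up) or by an explicit edge count; counts win if both are
    given.
    """

    p1: int = 100
    p2: int = 500
    density: tuple = (0.05, 0.05, 0.05)
    edge_count: tuple | None = None
    diag_epsilon: float = 1e-4
    noise_sd: float = 0.1
    name: str = "custom"

    def positions(self) -> tuple:
        """Available off-diagonal positions per block (unordered pairs)."""
        return (
            self.p1 * (self.p1 - 1) // 2,
            self.p1 * self.p2,
            self.p2 * (self.p2 - 1) // 2,
        )

    def counts(self) -> tuple:
        """Edge counts per block after resolving densities."""
        if self.edge_count is not None:
            counts = tuple(int(c) for c in self.edge_count)
        else:
            counts = tuple(
                _round_half_up(eta * npos) for eta, npos in zip(self.density, self.positions())
            )
        for c, npos, blk in zip(counts, self.positions(), ("(1,1)", "(1,2)", "(2,2)")):
            if c > npos:
                raise ValueError(f"block {blk}: requested {c} edges but only {npos} positions")
        if self.diag_epsilon <= 0:
            raise ValueError("diag_epsilon must be positive")
        return counts


@dataclass
class GroundTruth:
    """A simulated precision matrix and its edge indicator."""

    theta: np.ndarray
    adjacency: np.ndarray  # boolean, symmetric, zero diagonal
    p1: int
    config: StudyConfig | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def p2(self) -> int:
        return self.p - self.p1


def study_config(name: str) -> StudyConfig:
    """Named benchmark configuration (A, B, C or D)."""
    key = name.upper()
    if key in _STUDY_DENSITIES:
        return StudyConfig(density=_STUDY_DENSITIES[key], name=key)
    if key == "D":
        return StudyConfig(density=(0.101, 0.01, 0.004), edge_count=_STUDY_D_COUNTS, name="D")
    raise ValueError(f"unknown study {name!r}; expected one of A, B, C, D")


def _within_pairs(rng: np.random.Generator, p: int, count: int):
    npos = p * (p - 1) // 2
    chosen = rng.choice(npos, size=count, replace=False)
    iu, ju = np.triu_indices(p, 1)
    return iu[chosen], ju[chosen]


def generate_precision(config: StudyConfig, seed) -> GroundTruth:
    """Draw a sparse positive-definite precision matrix per the four-step recipe.

    The number of filled positions per block is exact and seed-independent
    (only their locations and values vary). Strict diagonal dominance
    before normalization guarantees positive definiteness for every seed;
    after normalization the diagonal is exactly 1.

    The random stream is split into a structure stream (edge locations)
    and a value stream (edge weights), so edge placement for a given seed
    does not depend on how the values are drawn.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_structure, rng_values = (np.random.default_rng(c) for c in ss.spawn(2))
    p1, p2 = config.p1, config.p2
    p = p1 + p2
    c11, c12, c22 = config.counts()

    theta = np.eye(p)
    i11, j11 = _within_pairs(rng_structure, p1, c11)
    i22, j22 = _within_pairs(rng_structure, p2, c22)
    flat12 = rng_structure.choice(p1 * p2, size=c12, replace=False)
    i12, j12 = flat12 // p2, flat12 % p2

    rows = np.concatenate([i11, i12, i22 + p1])
    cols = np.concatenate([j11, j12 + p1, j22 + p1])
    vals = rng_values.uniform(-1.0, 1.0, size=rows.size)
    theta[rows, cols] = vals
    theta[cols, rows] = vals

    adjacency = np.zeros((p, p), dtype=bool)
    adjacency[rows, cols] = vals != 0.0
    adjacency[cols, rows] = adjacency[rows, cols]

    # diagonal dominance: theta_ii <- sum_j |theta_ij| (incl. the current 1) + eps
    diag = np.abs(theta).sum(axis=1) + config.diag_epsilon
    theta[np.diag_indices(p)] = diag
    scale = 1.0 / np.sqrt(diag)
    theta *= scale[:, None]
    theta *= scale[None, :]
    theta = (theta + theta.T) / 2
    return GroundTruth(theta=theta, adjacency=adjacency, p1=p1, config=config)


def sample_dataset(
    truth: GroundTruth,
    n: int,
    noise_sd: float | None = None,
    seed=None,
) -> PairedOmicsData:
    """Draw n samples from N(0, Theta^{-1}) plus i.i.d. Gaussian noise.

    ``noise_sd`` defaults to the value in the truth's config (0.1 for the
    benchmark studies). Sampling uses the Cholesky factor of Theta:
    x = L^{-T} z has covariance Theta^{-1}.
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    if noise_sd is None:
        noise_sd = truth.config.noise_sd if truth.config is not None else 0.0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_samples, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    p = truth.p
    try:
        L = np.linalg.cholesky(truth.theta)
    except np.linalg.LinAlgError as err:
        raise ValueError("truth precision matrix is not positive definite") from err
    Z = rng_samples.standard_normal((n, p))
    X = linalg.solve_triangular(L, Z.T, lower=True, trans="T", check_finite=False).T
    if noise_sd > 0:
        X = X + noise_sd * rng_noise.standard_normal((n, p))
    return PairedOmicsData(
        X1=X[:, : truth.p1],
        X2=X[:, truth.p1 :],
        validate=False,
    )


def regulator_toy(
    n: int = 100,
    effect_a: float = 1.0,
    effect_b: float = 1.0,
    noise_sd: float = 0.5,
    seed=None,
):
    """Three-variable co-regulation example: one regulator driving genes A and B.

    A and B respond linearly to the same regulator but have no direct
    link, so their Pearson correlation is large while their partial
    correlation given the regulator is near zero. Returns
    ``(data, true_edges)`` where data columns are (regulator, A, B) and
    ``true_edges`` is {("regulator", "A"), ("regulator", "B")}. The
    effect sizes and noise level are illustrative defaults.
    """
    if n < 10:
        raise ValueError("need n >= 10 for the toy example")
    rng = np.random.default_rng(seed)
    regulator = rng.standard_normal(n)
    a = effect_a * regulator + noise_sd * rng.standard_normal(n)
    b = effect_b * regulator + noise_sd * rng.standard_normal(n)
    data = np.column_stack([regulator, a, b])
    true_edges = {("regulator", "A"), ("regulator", "B")}
    return data, true_edges
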