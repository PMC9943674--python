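"""Edge-recovery benchmarking: AUC, AUC-PR, observed FDR, sample-size scans.

Pairs are ranked by ascending adjusted significance (the per-block BH
q-value, ties broken by descending absolute partial correlation): the
calibrated per-block adjustment makes ranks comparable across blocks with
different shrinkage and different edge densities. For the layer-agnostic
single-penalty baseline the adjustment is global, so its ranking is
monotone in |rho|. ROC-AUC is the midrank Mann-Whitney statistic with tie
correction; AUC-PR is stepwise average precision. Scans regenerate the
ground-truth precision matrix for every replicate, so replicate
variability includes network variability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .datatypes import PairedOmicsData
from .model import DragonGGM
from .significance import _pair_indices
from .simulate import GroundTruth, StudyConfig, generate_precision, sample_dataset, study_config

logger = logging.getLogger(__name__)

#: n in {2^6, floor(2^6.5), ..., 2^14}
DEFAULT_GRID = tuple(int(2 ** (k / 2)) for k in range(12, 29))


@dataclass
class RecoveryResult:
    """Edge-recovery metrics of one fitted network against its ground truth."""

    auc: float = np.nan
    auc_pr: float = np.nan
    observed_fdr: float = np.nan
    n: int | None = None
    study: str | None = None
    estimator: str | None = None
    seed: object = None


@dataclass
class ScanResult:
    """Sample-size scan summary: per-n medians/quartiles and the minimal n."""

    study: str
    estimator: str
    grid: tuple
    replicates: pd.DataFrame  # columns: n, replicate, auc, auc_pr, fdr
    summary: pd.DataFrame  # columns: n, median, q25, q75
    minimal_n: int | None
    p_over_n: float | None


def gaussian_log_likelihood(theta_hat: np.ndarray, X_test: np.ndarray) -> float:
    """Gaussian log likelihood (n/2) * (log|Theta| - Tr(S_n Theta)).

    S_n is the 1/n-scaled second-moment matrix of the test sample about
    its own mean.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    X = np.asarray(X_test, dtype=float)
    if X.shape[1] != theta_hat.shape[0]:
        raise ValueError("test data width does not match the precision matrix")
    sign, logdet = np.linalg.slogdet(theta_hat)
    if sign <= 0:
        raise ValueError("precision matrix must be positive definite")
    n = X.shape[0]
    Y = X - X.mean(axis=0)
    # Tr(S_n Theta) = (1/n) sum_i y_i' Theta y_i
    trace_term = float(np.einsum("ij,jk,ik->", Y, theta_hat, Y)) / n
    return 0.5 * n * (logdet - trace_term)


def _composite_ranks(p_values: np.ndarray, abs_rho: np.ndarray) -> np.ndarray:
    """Midranks of the edge-strength ordering (higher rank = stronger edge).

    Strength is defined by smaller p, ties broken by larger |rho|; pairs
    equal on both get the average of their ordinal ranks (the Mann-Whitney
    tie convention).
    """
    m = p_values.size
    order = np.lexsort((-abs_rho, p_values))  # strongest edge first
    ranks = np.empty(m)
    # ordinal ranks descend from m (strongest) to 1; exact (p, |rho|) ties
    # get their group's average rank
    key_p = p_values[order]
    key_r = abs_rho[order]
    new_group = np.empty(m, dtype=bool)
    new_group[0] = True
    new_group[1:] = (key_p[1:] != key_p[:-1]) | (key_r[1:] != key_r[:-1])
    group_id = np.cumsum(new_group) - 1
    ngroups = group_id[-1] + 1
    sums = np.bincount(group_id, weights=np.arange(m, 0, -1, dtype=float), minlength=ngroups)
    counts = np.bincount(group_id, minlength=ngroups)
    mean_rank = sums / counts
    ranks[order] = mean_rank[group_id]
    return ranks


def _truth_labels(truth: GroundTruth) -> np.ndarray:
    iu, ju, _ = _pair_indices(truth.p1, truth.p2)
    return truth.adjacency[iu, ju]


def edge_recovery_auc(scores, abs_rho, labels) -> float:
    """ROC-AUC of the edge ranking via the midrank Mann-Whitney U.

    ``scores`` orders pairs ascending-is-stronger (a p- or q-value);
    ``abs_rho`` breaks ties. Returns nan when the truth has zero or only
    edges.
    """
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = _composite_ranks(np.asarray(scores, float), np.asarray(abs_rho, float))
    r1 = ranks[labels].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def edge_recovery_aucpr(scores, abs_rho, labels) -> float:
    """Stepwise average precision of the edge ranking (nan if degenerate)."""
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0 or labels.all():
        return np.nan
    ranks = _composite_ranks(np.asarray(scores, float), np.asarray(abs_rho, float))
    return float(average_precision_score(labels, ranks))


def observed_fdr(q_values, labels, alpha: float = 0.05) -> float:
    """Fraction of q < alpha discoveries that are false; nan if none."""
    q = np.asarray(q_values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    disc = q < alpha
    if not disc.any():
        return np.nan
    return float((disc & ~labels).sum() / disc.sum())


def _fit_for_scan(data: PairedOmicsData, estimator: str, null_seed):
    method = {"dragon": "dragon", "ggm": "ggm"}[estimator]
    return DragonGGM(data).fit(method=method, null_seed=null_seed)


def evaluate_replicate(
    truth: GroundTruth,
    data: PairedOmicsData,
    estimator: str,
    null_seed,
    alpha: float = 0.05,
    metrics: tuple = ("auc",),
) -> RecoveryResult:
    """Run one estimator on one dataset and score it against the truth."""
    res = _fit_for_scan(data, estimator, null_seed)
    _, _, _, rho, pvals, qvals = res.pair_scores()
    labels = _truth_labels(truth)
    out = RecoveryResult(n=data.n, estimator=estimator)
    if "auc" in metrics:
        out.auc = edge_recovery_auc(qvals, np.abs(rho), labels)
    if "auc_pr" in metrics:
        out.auc_pr = edge_recovery_aucpr(qvals, np.abs(rho), labels)
    if "fdr" in metrics:
        out.observed_fdr = observed_fdr(qvals, labels, alpha)
    return out


def _replicate_seed(base_seed: int, n_index: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((int(base_seed), int(n_index), int(replicate)))


def _scan_summary(rep_df: pd.DataFrame, grid, p_total: int):
    rows = []
    for n in grid:
        vals = rep_df.loc[rep_df["n"] == n, "auc"].dropna().to_numpy()
        if vals.size:
            rows.append((n, float(np.median(vals)), float(np.percentile(vals, 25)),
                         float(np.percentile(vals, 75))))
        else:
            rows.append((n, np.nan, np.nan, np.nan))
    summary = pd.DataFrame(rows, columns=["n", "median", "q25", "q75"])
    above = summary[summary["median"] > 0.8]
    minimal_n = int(above["n"].iloc[0]) if len(above) else None
    p_over_n = round(p_total / minimal_n, 2) if minimal_n else None
    return summary, minimal_n, p_over_n


def sample_size_scan(
    study,
    estimator: str = "dragon",
    grid=None,
    reps: int = 20,
    base_seed: int = 0,
    metrics: tuple = ("auc", "auc_pr", "fdr"),
) -> ScanResult:
    """Median edge-recovery AUC versus sample size for one estimator.

    For each n on the grid, ``reps`` independent (truth, dataset) pairs
    are generated and the full pipeline is run; ``minimal_n`` is the
    smallest grid n whose median AUC strictly exceeds 0.8. Replicates
    that fail are recorded as missing with a warning.
    """
    config = study if isinstance(study, StudyConfig) else study_config(study)
    grid = tuple(DEFAULT_GRID if grid is None else grid)
    records = []
    for ni, n in enumerate(grid):
        for rep in range(reps):
            ss = _replicate_seed(base_seed, ni, rep)
            s_truth, s_data, s_null = ss.spawn(3)
            try:
                truth = generate_precision(config, s_truth)
                data = sample_dataset(truth, n, seed=s_data)
                r = evaluate_replicate(truth, data, estimator, s_null, metrics=metrics)
            except Exception as err:  # pragma: no cover - defensive
                warnings.warn(f"replicate (n={n}, rep={rep}) failed: {err}")
                r = RecoveryResult(n=n)
            records.append((n, rep, r.auc, r.auc_pr, r.observed_fdr))
    rep_df = pd.DataFrame(records, columns=["n", "replicate", "auc", "auc_pr", "fdr"])
    summary, minimal_n, p_over_n = _scan_summary(rep_df, grid, config.p1 + config.p2)
    return ScanResult(
        study=config.name, estimator=estimator, grid=grid,
        replicates=rep_df, summary=summary, minimal_n=minimal_n, p_over_n=p_over_n,
    )


def _paired_metric_curve(study, grid, reps, base_seed, metric: str, test_n: int = 1000):
    """Shared driver for paired DRAGON-vs-GGM difference curves."""
    config = study if isinstance(study, StudyConfig) else study_config(study)
    grid = tuple(grid)
    records = []
    for ni, n in enumerate(grid):
        for rep in range(reps):
            ss = _replicate_seed(base_seed, ni, rep)
            s_truth, s_data, s_null, s_test = ss.spawn(4)
            truth = generate_precision(config, s_truth)
            data = sample_dataset(truth, n, seed=s_data)
            if metric == "auc":
                labels = _truth_labels(truth)
                vals = {}
                for est in ("dragon", "ggm"):
                    res = _fit_for_scan(data, est, s_null)
                    _, _, _, rho, _, qvals = res.pair_scores()
                    vals[est] = edge_recovery_auc(qvals, np.abs(rho), labels)
            else:  # held-out log likelihood; no null calibration needed
                X_test = sample_dataset(truth, test_n, seed=s_test).appended()
                vals = {}
                for est in ("dragon", "ggm"):
                    res = DragonGGM(data).fit(method=est, compute_edges=False)
                    vals[est] = gaussian_log_likelihood(res.theta, X_test)
            records.append((n, rep, vals["dragon"], vals["ggm"]))
    df = pd.DataFrame(records, columns=["n", "replicate", "dragon", "ggm"])
    df["difference"] = df["dragon"] - df["ggm"]
    rows = [
        (
            n,
            float(np.median(g["difference"])),
            float(np.percentile(g["difference"], 25)),
            float(np.percentile(g["difference"], 75)),
        )
        for n, g in df.groupby("n", sort=True)
    ]
    summary = pd.DataFrame(rows, columns=["n", "median", "q25", "q75"])
    return df, summary


def auc_difference_curve(study, grid, reps: int = 20, base_seed: int = 0):
    """Median paired AUC difference (DRAGON - GGM) versus sample size.

    Both estimators run on the identical replicate datasets, which removes
    variability due to different simulated networks. Returns
    ``(replicates, summary)`` DataFrames.
    """
    return _paired_metric_curve(study, grid, reps, base_seed, metric="auc")


def likelihood_difference_curve(study, grid, reps: int = 20, test_n: int = 1000, base_seed: int = 0):
    """Median paired held-out log-likelihood difference (DRAGON - GGM).

    The test set of ``test_n`` samples is drawn from the same truth as the
    training data. Returns ``(replicates, summary)`` DataFrames.
    """
    return _paired_metric_curve(study, grid, reps, base_seed, metric="loglik", test_n=test_n)
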