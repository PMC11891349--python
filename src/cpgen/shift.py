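"""Kernel two-sample testing between cohorts (maximum mean discrepancy).

The squared MMD with a Gaussian kernel measures the distance between
two sample distributions in a reproducing-kernel Hilbert space; its
null distribution is obtained by permuting the pooled samples, giving
an exact test of "same distribution" regardless of dimension.  Used to
audit covariate shift between a training cohort and an external
validation cohort before trusting exchangeability-based guarantees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist


@dataclass(frozen=True)
class ShiftTestResult:
    """MMD statistic with its permutation p-value and test settings."""

    mmd: float
    p_value: float
    n_permutations: int
    bandwidth: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "mmd": self.mmd,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "bandwidth": self.bandwidth,
            "seed": self.seed,
        }


def median_heuristic_bandwidth(X: np.ndarray, Y: np.ndarray) -> float:
    """Median pairwise Euclidean distance over the pooled sample.

    The standard bandwidth heuristic for Gaussian-kernel MMD; falls
    back to 1 when all pooled points coincide (median distance 0).
    Symmetric in (X, Y) by construction.
    """
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    pooled = np.vstack([X, Y])
    if pooled.shape[0] < 2:
        raise ValueError("need at least two pooled points")
    med = float(np.median(pdist(pooled)))
    return med if med > 0 else 1.0


def _gaussian_kernel(sq_dists: np.ndarray, bandwidth: float) -> np.ndarray:
    return np.exp(-sq_dists / (2.0 * bandwidth**2))


def mmd_statistic(X: np.ndarray, Y: np.ndarray, bandwidth: float) -> float:
    """Biased (V-statistic) squared MMD with a Gaussian kernel.

    ``mean(K_XX) + mean(K_YY) − 2·mean(K_XY)`` with
    ``k(a,b) = exp(−‖a−b‖²/(2·bandwidth²))``; non-negative and
    symmetric in (X, Y).
    """
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("both samples must be non-empty")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature mismatch: {X.shape[1]} vs {Y.shape[1]}")
    kxx = _gaussian_kernel(cdist(X, X, "sqeuclidean"), bandwidth)
    kyy = _gaussian_kernel(cdist(Y, Y, "sqeuclidean"), bandwidth)
    kxy = _gaussian_kernel(cdist(X, Y, "sqeuclidean"), bandwidth)
    return max(float(kxx.mean() + kyy.mean() - 2.0 * kxy.mean()), 0.0)


def _mmd_from_pooled_kernel(K: np.ndarray, idx_x: np.ndarray, idx_y: np.ndarray) -> float:
    kxx = K[np.ix_(idx_x, idx_x)].mean()
    kyy = K[np.ix_(idx_y, idx_y)].mean()
    kxy = K[np.ix_(idx_x, idx_y)].mean()
    return max(float(kxx + kyy - 2.0 * kxy), 0.0)


def mmd_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 199,
    seed: int = 0,
    bandwidth: float | None = None,
) -> ShiftTestResult:
    """Permutation test of "X and Y share a distribution" via the MMD.

    The bandwidth is the pooled median heuristic (permutation-invariant,
    so fixing it across permutations keeps the test exact).  The pooled
    kernel matrix is computed once; each permutation reshuffles the
    pooled rows into groups of the original sizes.
    ``p = (1 + #{MMD_perm ≥ MMD_obs}) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature mismatch: {X.shape[1]} vs {Y.shape[1]}")
    bw = median_heuristic_bandwidth(X, Y) if bandwidth is None else float(bandwidth)
    n, m = X.shape[0], Y.shape[0]
    pooled = np.vstack([X, Y])
    K = _gaussian_kernel(cdist(pooled, pooled, "sqeuclidean"), bw)
    observed = _mmd_from_pooled_kernel(K, np.arange(n), np.arange(n, n + m))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n + m)
        stat = _mmd_from_pooled_kernel(K, perm[:n], perm[n:])
        exceed += stat >= observed
    p = (1 + exceed) / (n_permutations + 1)
    return ShiftTestResult(mmd=observed, p_value=p, n_permutations=n_permutations, bandwidth=bw, seed=seed)
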