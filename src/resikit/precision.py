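"""RESI precision quantification.

Two complementary estimates of sigma_RESI(K):

* in-silico: simulate M localizations per site as a 2D Gaussian of s.d.
  sigma_SMLM, partition them into n = M/K disjoint subsets of K, average
  each subset, and measure the scalar spread of the subset means,
  sigma_RESI = sqrt(1/2 * tr(cov(x, y))). The curve tracks
  sigma_SMLM / sqrt(K).
* resampling of experimental clusters: the same subset procedure applied to
  a measured cluster's M localizations, with the final precision
  extrapolated as sigma_cluster / sqrt(M) since the actual RESI localization
  uses all M localizations.

Both require K << M (enforced as M/K >= 10) for a statistically meaningful
number of subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError


@dataclass
class PrecisionCurve:
    """sigma_RESI as a function of the number of grouped localizations K."""

    K_values: np.ndarray
    sigma_resi: np.ndarray
    sigma_theory: np.ndarray  # sigma_SMLM / sqrt(K)
    n_subsets: np.ndarray

    def __post_init__(self) -> None:
        self.K_values = np.asarray(self.K_values, dtype=int)
        if np.any(np.diff(self.K_values) <= 0):
            raise ValidationError("K_values must be strictly increasing")
        if np.any(np.asarray(self.n_subsets) < 10):
            raise ValidationError("need >= 10 subsets per reported K")

    def loglog_slope(self) -> float:
        """Least-squares slope of log sigma_RESI vs log K (expected -1/2)."""
        coeffs = np.polyfit(np.log(self.K_values), np.log(self.sigma_resi), 1)
        return float(coeffs[0])


def scalar_spread(points: np.ndarray) -> float:
    """Scalar 2D spread sqrt(1/2 * tr(cov(x, y))) with unbiased covariance.

    Equals sigma for an isotropic Gaussian sample. NaN (with a warning) for
    fewer than 2 points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(points) < 2:
        warnings.warn("scalar spread undefined for < 2 points")
        return float("nan")
    cov = np.cov(points[:, 0], points[:, 1], ddof=1)
    return float(np.sqrt(0.5 * np.trace(cov)))


def _subset_means(points: np.ndarray, k: int, rng) -> np.ndarray:
    """Means of n = M//k disjoint random subsets of size k."""
    m = len(points)
    n = m // k
    perm = rng.permutation(m)[: n * k]
    groups = points[perm].reshape(n, k, points.shape[1])
    return groups.mean(axis=1)


def insilico_curve(
    sigma_smlm: float,
    M: int,
    K_values,
    seed: int | None = None,
    n_sites: int = 1,
) -> PrecisionCurve:
    """Numerically measure sigma_RESI(K) from simulated localization clouds.

    For each of ``n_sites`` sites, M localizations are drawn from an
    isotropic 2D Gaussian of s.d. ``sigma_smlm``; for every K the scalar
    spread of the disjoint K-subset means is computed and averaged across
    sites. Requires M/K >= 10 for every K.
    """
    if sigma_smlm <= 0:
        raise ValidationError("sigma_smlm must be > 0")
    K_values = np.asarray(sorted(int(k) for k in K_values))
    if np.any(K_values < 1):
        raise ValidationError("K values must be >= 1")
    if M < 10 * K_values.max():
        raise ValidationError("need M >= 10 * max(K) for sufficient subsets")
    rng = np.random.default_rng(seed)
    sig = np.zeros(len(K_values))
    for s in range(n_sites):
        pts = rng.normal(0.0, sigma_smlm, size=(M, 2))
        for i, k in enumerate(K_values):
            sig[i] += scalar_spread(_subset_means(pts, int(k), rng))
    sig /= n_sites
    return PrecisionCurve(
        K_values=K_values,
        sigma_resi=sig,
        sigma_theory=sigma_smlm / np.sqrt(K_values),
        n_subsets=(M // K_values).astype(int),
    )


def resample_cluster(points: np.ndarray, K: int, seed: int | None = None) -> dict:
    """Estimate RESI precision of one measured cluster by resampling.

    Returns a dict with ``sigma_resi_K`` (scalar spread of the K-subset
    means), ``sigma_smlm_est`` (the cluster's own scalar spread),
    ``sigma_resi_final`` (extrapolated all-M precision,
    sigma_smlm_est/sqrt(M)), ``n_subsets`` and ``M``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = len(points)
    if K < 1:
        raise ValidationError("K must be >= 1")
    if m < 10 * K:
        raise ValidationError("resampling requires M >= 10 * K (K << M)")
    rng = np.random.default_rng(seed)
    means = _subset_means(points, K, rng)
    sigma_smlm_est = scalar_spread(points)
    return {
        "sigma_resi_K": scalar_spread(means),
        "sigma_smlm_est": sigma_smlm_est,
        "sigma_resi_final": sigma_smlm_est / np.sqrt(m),
        "n_subsets": m // K,
        "M": m,
    }
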