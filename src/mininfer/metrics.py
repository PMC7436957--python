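"""Scoring: Bray-Curtis dissimilarity, reconstruction accuracy, the
two-sample Kolmogorov-Smirnov statistic and matrix mean squared error."""

from __future__ import annotations

import numpy as np

__all__ = [
    "bcd_timepoint",
    "bcd_overall",
    "reconstruction_accuracy",
    "ks_statistic",
    "matrix_mse",
]


def _as_profile_values(P) -> np.ndarray:
    values = getattr(P, "values", P)
    return np.asarray(values, dtype=float)


def bcd_timepoint(x: np.ndarray, x_star: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two composition vectors.

    BCD = sum_i |x_i - x*_i| / sum_i (x_i + x*_i), in [0, 1].
    Two all-zero vectors are maximally similar: BCD = 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    x_star = np.asarray(x_star, dtype=float)
    if x.shape != x_star.shape:
        raise ValueError("vectors must have the same length")
    if np.any(x < 0) or np.any(x_star < 0):
        raise ValueError("abundances must be nonnegative")
    denom = x.sum() + x_star.sum()
    if denom == 0.0:
        return 0.0
    # roundoff can push the ratio a few ulp past 1 for disjoint supports
    return float(min(np.abs(x - x_star).sum() / denom, 1.0))


def bcd_overall(P, P_star) -> float:
    """Mean Bray-Curtis dissimilarity over the T compared time points."""
    V = _as_profile_values(P)
    V_star = _as_profile_values(P_star)
    if V.shape != V_star.shape:
        raise ValueError(f"profile shapes differ: {V.shape} vs {V_star.shape}")
    return float(np.mean([bcd_timepoint(V[:, k], V_star[:, k])
                          for k in range(V.shape[1])]))


def reconstruction_accuracy(P, P_star) -> float:
    """Reconstructed-abundance-profile accuracy: (1 - mean BCD) * 100%."""
    return (1.0 - bcd_overall(P, P_star)) * 100.0


def ks_statistic(sample1, sample2) -> float:
    """Two-sample Kolmogorov-Smirnov statistic.

    The supremum over x of |F1(x) - F2(x)| for the two empirical
    distribution functions; evaluated exactly at the pooled sample points.
    """
    x = np.sort(np.asarray(sample1, dtype=float).ravel())
    y = np.sort(np.asarray(sample2, dtype=float).ravel())
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, pooled, side="right") / x.size
    cdf2 = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.max(np.abs(cdf1 - cdf2)))


def ks_statistic_presorted(values: np.ndarray, sorted_reference: np.ndarray) -> float:
    """KS statistic against a reference sample that is already sorted.

    Hot-loop variant used by the genetic algorithm, where the same
    reference sample is reused for every fitness evaluation.
    """
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size == 0 or sorted_reference.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, sorted_reference])
    cdf1 = np.searchsorted(x, pooled, side="right") / x.size
    cdf2 = np.searchsorted(sorted_reference, pooled, side="right") / sorted_reference.size
    return float(np.max(np.abs(cdf1 - cdf2)))


def matrix_mse(A_true: np.ndarray, A_hat: np.ndarray) -> float:
    """Mean squared error between two matrices over all entries."""
    A_true = np.asarray(A_true, dtype=float)
    A_hat = np.asarray(A_hat, dtype=float)
    if A_true.shape != A_hat.shape:
        raise ValueError(f"matrix shapes differ: {A_true.shape} vs {A_hat.shape}")
    return float(np.mean((A_true - A_hat) ** 2))
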