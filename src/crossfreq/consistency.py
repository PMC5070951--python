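"""Harmonic consistency of connection density across frequency ratios.

If cross-frequency coupling at a low frequency f_low reflects a genuine
oscillatory hierarchy, its connection density K should be elevated
across many 1:m ratios rather than at one isolated ratio.  The
consistency measure

    C = K_bar * exp( - sum_m |K_m - K_bar| / (N * K_bar) )

(K_bar the mean density over the N ratios) rewards uniformly high
density: it equals K_bar when all K_m agree and shrinks with their
dispersion.  Significance is assessed against surrogates that shuffle
the K values over low frequencies independently within each ratio
column, destroying any frequency-specific consistency while preserving
each ratio's marginal distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConsistencyProfile", "harmonic_consistency", "consistency_null"]


@dataclass
class ConsistencyProfile:
    """Consistency per low frequency with its surrogate threshold."""

    f_low: np.ndarray
    C: np.ndarray
    null_threshold: np.ndarray
    n_shuffles: int

    @property
    def significant(self) -> np.ndarray:
        return self.C > self.null_threshold


def harmonic_consistency(K_values: np.ndarray) -> float:
    """Consistency C of per-ratio connection densities.

    C = K_bar * exp(-sum_m |K_m - K_bar| / (N * K_bar)); defined as 0
    when all densities are zero (K_bar = 0).
    """
    K = np.asarray(K_values, dtype=float)
    if K.ndim != 1 or K.size < 2:
        raise ValueError("need a 1-D array of at least 2 per-ratio densities")
    if np.any((K < 0) | (K > 1)):
        raise ValueError("densities must lie in [0, 1]")
    k_bar = K.mean()
    if k_bar == 0:
        return 0.0
    disp = np.sum(np.abs(K - k_bar)) / (K.size * k_bar)
    return float(k_bar * np.exp(-disp))


def consistency_null(
    K_matrix: np.ndarray,
    n_shuffles: int = 2000,
    percentile: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-f_low consistency thresholds from frequency-shuffled surrogates.

    ``K_matrix`` is (n_f_low, n_ratios).  Each shuffle permutes the K
    values across low frequencies independently per ratio column and
    recomputes C for every row; the threshold is the stated percentile
    of the shuffled C values per row.
    """
    K = np.asarray(K_matrix, dtype=float)
    if K.ndim != 2 or K.shape[0] < 2:
        raise ValueError("K_matrix must be (n_f_low >= 2, n_ratios)")
    n_f, n_r = K.shape
    rng = np.random.default_rng(rng)
    surr = np.empty((n_shuffles, n_f))
    for i in range(n_shuffles):
        shuffled = np.empty_like(K)
        for j in range(n_r):
            shuffled[:, j] = K[rng.permutation(n_f), j]
        for f in range(n_f):
            surr[i, f] = harmonic_consistency(shuffled[f])
    return np.percentile(surr, percentile, axis=0)


def consistency_profile(
    f_low: np.ndarray,
    K_matrix: np.ndarray,
    n_shuffles: int = 2000,
    percentile: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> ConsistencyProfile:
    """Observed consistency per low frequency plus its surrogate threshold."""
    K = np.asarray(K_matrix, dtype=float)
    C = np.array([harmonic_consistency(row) for row in K])
    thr = consistency_null(K, n_shuffles=n_shuffles, percentile=percentile, rng=rng)
    return ConsistencyProfile(np.asarray(f_low, dtype=float), C, thr, n_shuffles)
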