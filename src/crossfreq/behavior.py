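"""Behavioral capacity and its correlation with coupling-network strength.

Working-memory capacity per subject and load is C(l) = HR(l) * l, hit
rate times the number of memorized objects.  A subject's network
strength S(l, m, f_low) is the sum of their coupling values over the
edges significant in the positive tail of the Mean-condition group
statistics, over the two retention windows.  Before correlating, both S
and C are detrended and normalized:

    S'(l, s) = ( S(l, s) - S_L(s) - S_pop(l) ) / S_abs

with S_L(s) the subject's mean over loads, S_pop(l) the load-wise
population mean of subject-centered values, and S_abs the population
mean of the summed absolute subject-centered values.  This removes the
subject's overall level and the common load trend, leaving the
subject-by-load interaction whose Pearson correlation with equally
processed capacity is the statistic of interest; p-values across low
frequencies are Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "capacity",
    "network_strength",
    "detrend_normalize",
    "strength_capacity_correlation",
    "per_ratio_correlations",
    "RATIO_GROUPS",
    "RATIO_GROUPS_POSTHOC",
]

#: default ratio groupings for strength averaging
RATIO_GROUPS = {"low": (2, 3, 4, 5), "high": (6, 7, 8, 9)}

#: post-hoc split separating the 1:2 ratio from the rest of the low group
RATIO_GROUPS_POSTHOC = {"1:2": (2,), "1:3-1:5": (3, 4, 5)}


def capacity(hit_rate: np.ndarray) -> np.ndarray:
    """VWM capacity C(l) = HR(l) * l for (n_subjects, n_loads) hit rates."""
    hr = np.asarray(hit_rate, dtype=float)
    if np.any((hr < 0) | (hr > 1)):
        raise ValueError("hit rates must lie in [0, 1]")
    loads = np.arange(1, hr.shape[-1] + 1)
    return hr * loads


def network_strength(plv: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked coupling strength summed over edges and retention windows.

    ``plv`` is (n_subjects, n_loads, n_windows, n_edges); ``mask`` is a
    binary per-(window, edge) or per-edge selection built from the
    positive tail of the Mean-condition statistics.  The sum runs over
    the last two (retention) windows and all masked edges, giving
    S per (subject, load).
    """
    plv = np.asarray(plv, dtype=float)
    if plv.ndim != 4:
        raise ValueError("plv must be (n_subjects, n_loads, n_windows, n_edges)")
    n_win = plv.shape[2]
    if n_win < 2:
        raise ValueError("need at least two windows (retention windows are the last two)")
    mask = np.asarray(mask)
    if mask.ndim == 1:
        mask = np.broadcast_to(mask, (2, mask.size))
    elif mask.shape[0] != 2:
        raise ValueError("per-window mask must cover the two retention windows")
    if not mask.any():
        logger.info("network_strength: empty mask, S = 0")
    ret = plv[:, :, n_win - 2 :, :]
    return np.einsum("slwe,we->sl", ret, mask.astype(float))


def detrend_normalize(values: np.ndarray) -> np.ndarray:
    """Remove subject level and common load trend; scale to unit mean |.|.

    Output is invariant to adding per-subject or per-load constants to
    the input; its mean over subjects is zero at every load (hence so is
    its grand sum).  Raises when the input carries no subject-by-load
    variation (normalizer zero).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("values must be (n_subjects >= 2, n_loads >= 2)")
    centered = v - v.mean(axis=1, keepdims=True)  # subtract S_L(s)
    pop = centered.mean(axis=0, keepdims=True)  # S_pop(l)
    s_abs = np.abs(centered).sum(axis=1).mean()  # mean over subjects of sum over loads
    if s_abs == 0:
        raise ValueError("no subject-by-load variation: normalization undefined")
    return (centered - pop) / s_abs


def per_ratio_correlations(
    S_prime_by_ratio: dict[int, np.ndarray],
    C_prime: np.ndarray,
) -> dict[int, float]:
    """Correlation coefficients per individual ratio, for visualization.

    No p-values are attached — single-ratio strengths are too
    collinear with their group averages for independent tests; use
    :func:`strength_capacity_correlation` on ratio groups for
    statistics.
    """
    C = np.asarray(C_prime, dtype=float).ravel()
    out: dict[int, float] = {}
    for m, s in sorted(S_prime_by_ratio.items()):
        s = np.asarray(s, dtype=float).ravel()
        if np.std(s) == 0 or np.std(C) == 0:
            out[m] = float("nan")
        else:
            out[m] = float(np.corrcoef(s, C)[0, 1])
    return out


def strength_capacity_correlation(
    S_prime: dict[float, np.ndarray],
    C_prime: np.ndarray,
    alpha: float = 0.05,
) -> dict[float, dict]:
    """Pearson correlation of detrended strength vs detrended capacity.

    ``S_prime`` maps each f_low to a detrended (n_subjects, n_loads)
    strength array (already averaged over a ratio group); ``C_prime`` is
    the equally detrended capacity.  Observations pool subjects and
    loads; p-values are Benjamini-Hochberg corrected across the tested
    f_low set.
    """
    from statsmodels.stats.multitest import multipletests

    C = np.asarray(C_prime, dtype=float).ravel()
    f_lows = sorted(S_prime)
    out: dict[float, dict] = {}
    r_list, p_list, tested = [], [], []
    for f in f_lows:
        s = np.asarray(S_prime[f], dtype=float).ravel()
        if s.shape != C.shape:
            raise ValueError("strength and capacity shapes disagree")
        if np.std(s) == 0 or np.std(C) == 0:
            out[f] = {"r": np.nan, "p": np.nan, "p_adj": np.nan, "significant": False}
            continue
        r, p = stats.pearsonr(s, C)
        out[f] = {"r": float(r), "p": float(p)}
        r_list.append(r)
        p_list.append(p)
        tested.append(f)
    if tested:
        rej, p_adj, *_ = multipletests(p_list, alpha=alpha, method="fdr_bh")
        for f, pa, rj in zip(tested, p_adj, rej):
            out[f]["p_adj"] = float(pa)
            out[f]["significant"] = bool(rj)
    return out
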