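"""Group-level edge statistics for coupling graphs.

Two contrasts are tested per edge across the subject cohort:

Mean condition
    Coupling averaged over memory loads, retention windows vs the first
    pre-stimulus baseline, paired two-sided t-test; effect size is the
    mean difference divided by the SD of the difference (Cohen's d for
    paired designs).
Load condition
    Spearman rank correlation of retention-window coupling with memory
    load over pooled (subject x load) observations; effect size is the
    correlation coefficient.

Multiple comparisons across edges are handled by an
expected-false-positive removal rule — among edges with p < alpha, the
ceil(alpha * n_tests) with the largest p are dropped — with
Benjamini-Hochberg available as an alternative.  Positive and negative
tails are retained separately via the effect sign.  Robustness masks
(leave-one-out, effect-size thresholds) and the power analysis that
yields the minimum detectable effect for the cohort size complete the
module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .parcels import ParcelMeta

__all__ = [
    "StatGraph",
    "ParcelMeta",
    "equalize_trials",
    "collapse_adjacency",
    "fdr_mask",
    "mean_condition_test",
    "load_condition_test",
    "connection_density",
    "leave_one_out_mask",
    "effect_size_mask",
    "minimal_detectable_effect",
    "plv_amplitude_effect_correlation",
]


@dataclass
class StatGraph:
    """Per-edge group statistics for one (f_low, ratio, condition).

    Arrays are aligned with the caller's edge indexing (typically the
    flattened off-diagonal of a parcel x parcel matrix).  ``sign`` is +1
    where the effect is positive, -1 where negative, 0 where undefined.
    """

    effect_size: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    sign: np.ndarray
    n_possible: int = 0
    level: str = "fine"
    condition: str = "mean"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_possible == 0:
            self.n_possible = len(self.effect_size)

    @property
    def n_significant(self) -> int:
        return int(np.count_nonzero(self.significant))

    def tail(self, sign: int) -> np.ndarray:
        """Significance mask restricted to one tail (+1 or -1)."""
        return self.significant & (self.sign == sign)


def equalize_trials(
    trial_counts: Sequence[int],
    seed: int | np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Subsample every load to the minimum per-load trial count.

    PLV is biased by the number of observations, so conditions compared
    against each other must use equal trial counts.  Returns one sorted
    index array per load, drawn without replacement with a fixed seed.
    """
    counts = [int(c) for c in trial_counts]
    if any(c <= 0 for c in counts):
        raise ValueError("every load must have at least one trial")
    n_min = min(counts)
    rng = np.random.default_rng(seed)
    return [np.sort(rng.choice(c, size=n_min, replace=False)) for c in counts]


def collapse_adjacency(fine_matrix: np.ndarray, meta: ParcelMeta) -> np.ndarray:
    """Collapse a fine parcel x parcel matrix to the coarse parcellation.

    Each coarse entry is the mean of its constituent fine entries;
    excluded fine parcels are left out, and fine diagonal (self-
    coupling) entries are left out of coarse diagonal blocks unless the
    block contains nothing else (one fine parcel per coarse parcel).
    Orientation (low-frequency rows, high-frequency columns) is
    preserved.
    """
    fine = np.asarray(fine_matrix, dtype=float)
    n_fine = fine.shape[0]
    if fine.shape != (n_fine, n_fine):
        raise ValueError("fine matrix must be square")
    if n_fine != meta.n_fine:
        raise ValueError("matrix size does not match parcel metadata")
    nc = meta.n_coarse
    keep = ~meta.excluded
    weights = np.zeros((nc, n_fine))
    weights[meta.fine_to_coarse[keep], np.flatnonzero(keep)] = 1.0
    num = weights @ fine @ weights.T
    cnt = weights @ np.ones_like(fine) @ weights.T
    diag_contrib = weights @ np.diag(np.diag(fine)) @ weights.T
    diag_cnt = weights @ np.eye(n_fine) @ weights.T
    num2 = num - np.diag(np.diag(diag_contrib))
    cnt2 = cnt - np.diag(np.diag(diag_cnt))
    # fall back to the full block where removing the diagonal empties it
    empty = cnt2 == 0
    num2[empty] = num[empty]
    cnt2[empty] = cnt[empty]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cnt2 > 0, num2 / np.where(cnt2 > 0, cnt2, 1.0), np.nan)


def fdr_mask(
    p_values: np.ndarray,
    alpha: float = 0.05,
    method: str = "expected_fp",
) -> np.ndarray:
    """Multiple-comparison mask over edges.

    ``expected_fp`` (default): keep edges with p < alpha, then remove the
    ceil(alpha * n_tests) of them with the largest p — the number of
    false positives expected among n_tests true nulls at level alpha.
    ``bh``: Benjamini-Hochberg step-up.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if method == "bh":
        mask = np.zeros(p.shape, dtype=bool)
        if finite.any():
            from statsmodels.stats.multitest import multipletests

            mask[finite] = multipletests(p[finite], alpha=alpha, method="fdr_bh")[0]
        return mask
    if method != "expected_fp":
        raise ValueError(f"unknown FDR method {method!r}")
    mask = finite & (p < alpha)
    n_remove = math.ceil(alpha * p.size)
    if mask.any() and n_remove > 0:
        sig_idx = np.flatnonzero(mask)
        order = sig_idx[np.argsort(p[sig_idx], kind="stable")]
        mask[order[len(order) - min(n_remove, len(order)) :]] = False
    return mask


def mean_condition_test(
    retention: np.ndarray,
    baseline: np.ndarray,
    alpha: float = 0.05,
    fdr_method: str = "expected_fp",
    level: str = "fine",
) -> StatGraph:
    """Retention-vs-baseline paired t-test per edge across subjects.

    ``retention`` and ``baseline`` are (n_subjects, n_edges) arrays of
    coupling values already averaged across loads (and, for retention,
    across the two retention windows).  Effect size is mean(diff)/sd(diff);
    edges with zero difference variance are flagged indeterminate (NaN).
    """
    ret = np.asarray(retention, dtype=float)
    bl = np.asarray(baseline, dtype=float)
    if ret.shape != bl.shape or ret.ndim != 2:
        raise ValueError("retention and baseline must be (n_subjects, n_edges)")
    n_subj = ret.shape[0]
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    diff = ret - bl
    mean_d = diff.mean(axis=0)
    sd_d = diff.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        effect = np.where(sd_d > 0, mean_d / sd_d, np.nan)
        t = effect * np.sqrt(n_subj)
    p = 2.0 * stats.t.sf(np.abs(t), df=n_subj - 1)
    p = np.where(np.isfinite(t), p, np.nan)
    sig = fdr_mask(p, alpha=alpha, method=fdr_method)
    sign = np.sign(np.nan_to_num(effect)).astype(int)
    return StatGraph(effect, p, sig, sign, level=level, condition="mean",
                     meta={"alpha": alpha, "fdr": fdr_method, "n_subjects": n_subj})


def load_condition_test(
    values: np.ndarray,
    alpha: float = 0.05,
    fdr_method: str = "expected_fp",
    level: str = "fine",
) -> StatGraph:
    """Spearman correlation of coupling with memory load, per edge.

    ``values`` is (n_subjects, n_loads, n_edges) of retention-window
    coupling; observations are pooled over subjects and loads (n = S*L
    points per edge).  Effect size is the rank correlation coefficient.
    Edges with constant values are skipped (NaN, never significant).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3:
        raise ValueError("values must be (n_subjects, n_loads, n_edges)")
    S, L, E = v.shape
    loads = np.broadcast_to(np.arange(1, L + 1)[None, :], (S, L)).reshape(-1)
    obs = v.reshape(S * L, E)
    n = S * L
    rank_load = stats.rankdata(loads)
    ranks = np.apply_along_axis(stats.rankdata, 0, obs)
    rl = (rank_load - rank_load.mean()) / rank_load.std()
    rv = ranks - ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(sd > 0, (rl[:, None] * rv).mean(axis=0) / np.where(sd > 0, sd, 1.0), np.nan)
    # two-sided p via the t approximation used for Spearman's rho
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = np.where(np.isfinite(rho), 2.0 * stats.t.sf(np.abs(t), df=n - 2), np.nan)
    sig = fdr_mask(p, alpha=alpha, method=fdr_method)
    sign = np.sign(np.nan_to_num(rho)).astype(int)
    return StatGraph(rho, p, sig, sign, level=level, condition="load",
                     meta={"alpha": alpha, "fdr": fdr_method, "n_obs": n})


def connection_density(graph: StatGraph, tail: int | None = None) -> float:
    """Connection density K: significant edges / possible edges.

    ``tail`` restricts to the positive (+1) or negative (-1) tail.
    """
    mask = graph.significant if tail is None else graph.tail(tail)
    if graph.n_possible == 0:
        return 0.0
    return float(np.count_nonzero(mask)) / float(graph.n_possible)


def leave_one_out_mask(
    per_subject_stat: Callable[[np.ndarray], np.ndarray],
    subject_index: np.ndarray,
    base_graph: StatGraph,
    alpha: float = 0.05,
) -> StatGraph:
    """Retain base-significant edges that survive every leave-one-out cohort.

    ``per_subject_stat(keep)`` must return per-edge p-values for the
    cohort restricted to the boolean subject mask ``keep``.  An edge is
    retained if it is significant in the base analysis and p < alpha in
    each of the n_subjects cohorts of n-1 subjects.
    """
    n_subj = len(subject_index)
    if n_subj < 3:
        raise ValueError("leave-one-out requires at least 3 subjects")
    keep_mask = base_graph.significant.copy()
    for s in range(n_subj):
        if not keep_mask.any():
            break
        keep = np.ones(n_subj, dtype=bool)
        keep[s] = False
        p = per_subject_stat(keep)
        keep_mask &= np.nan_to_num(p, nan=1.0) < alpha
    out = StatGraph(
        base_graph.effect_size.copy(),
        base_graph.p_value.copy(),
        keep_mask,
        base_graph.sign.copy(),
        n_possible=base_graph.n_possible,
        level=base_graph.level,
        condition=base_graph.condition,
        meta={**base_graph.meta, "mask": "leave_one_out"},
    )
    return out


def effect_size_mask(graph: StatGraph, threshold: float) -> StatGraph:
    """Retain significant edges with |effect size| above ``threshold``."""
    mask = graph.significant & (np.abs(np.nan_to_num(graph.effect_size)) > threshold)
    return StatGraph(
        graph.effect_size.copy(),
        graph.p_value.copy(),
        mask,
        graph.sign.copy(),
        n_possible=graph.n_possible,
        level=graph.level,
        condition=graph.condition,
        meta={**graph.meta, "mask": f"effect>{threshold}"},
    )


def minimal_detectable_effect(
    n: int,
    alpha: float = 0.05,
    power: float = 0.8,
    design: str = "one_sample_t",
) -> float:
    """Smallest effect size reaching the target power, two-sided test.

    ``one_sample_t``: Cohen's d for a one-sample (equivalently paired)
    t-test with n subjects, via the noncentral t distribution.
    ``correlation``: Pearson r with n observations, via the Fisher-z
    normal approximation.
    """
    if not 0 < alpha < 1 or not alpha < power < 1:
        raise ValueError("require 0 < alpha < power < 1")
    if n < 3:
        raise ValueError("need n >= 3")

    if design == "one_sample_t":
        df = n - 1
        t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)

        def power_at(d: float) -> float:
            nc = d * math.sqrt(n)
            upper = stats.nct.sf(t_crit, df, nc)
            lower = stats.nct.cdf(-t_crit, df, nc)
            if math.isnan(lower):  # negligible opposite tail at large nc
                lower = 0.0
            return upper + lower

    elif design == "correlation":
        z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
        se = 1.0 / math.sqrt(n - 3)

        def power_at(r: float) -> float:
            z = np.arctanh(r)
            return float(
                stats.norm.sf(z_crit - z / se) + stats.norm.cdf(-z_crit - z / se)
            )

    else:
        raise ValueError(f"unknown design {design!r}")

    hi = 0.999 if design == "correlation" else 10.0
    if power_at(hi) < power:
        raise ValueError("target power unreachable at this sample size")
    return float(brentq(lambda e: power_at(e) - power, 1e-9, hi, xtol=1e-8))


def plv_amplitude_effect_correlation(
    plv_effects: np.ndarray,
    amplitude_effects: np.ndarray,
    n_surrogates: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Correlate per-edge PLV effects with per-edge amplitude effects.

    Both arrays are aligned over the same significant-edge set (the
    per-edge amplitude effect is the mean of its two endpoint parcels'
    amplitude effects, computed by the caller).  The observed Pearson r
    is compared against ``n_surrogates`` random reassignments of the
    amplitude effects across edges; it is significant when in the
    highest or lowest 2.5 percent of surrogate values.  Also reports
    r^2 * sign(r), the signed fraction of variance explained.
    """
    x = np.asarray(plv_effects, dtype=float)
    y = np.asarray(amplitude_effects, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("effect arrays must be 1-D and aligned")
    if x.size < 3:
        raise ValueError("need at least 3 edges")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(rng)
    surr = np.empty(n_surrogates)
    for i in range(n_surrogates):
        surr[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
    lo, hi = np.percentile(surr, [2.5, 97.5])
    return {
        "r": r,
        "signed_r2": r * abs(r),
        "significant": bool(r < lo or r > hi),
        "surrogate_bounds": (float(lo), float(hi)),
    }
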