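"""Canonical validation experiments on synthetic studies.

These functions encode the study conditions under which the pipeline's
statistical guarantees are checked: planted-effect recovery, surrogate
and FDR calibration, PAC/CFS dissociation, and the SNR-confound audit.
Each runs the full package machinery end to end at desk scale and
returns plain dictionaries of measured quantities; the acceptance
script and the test suite both consume them.
"""

from __future__ import annotations

import numpy as np

from . import group_stats as gs
from . import snr as snrmod
from . import synth
from .coupling import timeshift_null_plv_trials
from .pipeline import AnalysisConfig, compute_coupling, directed_edges, run_group_stats, run_snr_audit

__all__ = [
    "recovery_experiment",
    "surrogate_calibration",
    "fdr_null_calibration",
    "snr_audit_experiment",
]


def _edge_index(d_edges: np.ndarray, p: int, q: int) -> int:
    return int(np.flatnonzero((d_edges[:, 0] == p) & (d_edges[:, 1] == q))[0])


def recovery_experiment(
    seed: int = 0,
    n_subjects: int = 10,
    n_trials: int = 60,
    n_parcels: int = 8,
    snr: float = 2.0,
    coupling_factor: float = 0.8,
    alpha: float = 0.05,
) -> dict:
    """Planted-effect recovery on a full synthetic study.

    Plants five strong retention-only CFS edges (ratios 2 and 3 at
    f_low = 10 Hz), two load-dependent edges, and one PAC-only edge,
    then runs the coupling and group-statistics chain and scores:

    * Mean-condition sensitivity over the strong CFS edges,
    * edge-level false-positive rate over unplanted CFS edges,
    * Load-condition sensitivity over the load-slope edges,
    * PAC detection and the PAC/CFS dissociation (the PAC-only edge
      must not show significant CFS).
    """
    cfg = synth.StudyConfig(
        n_subjects=n_subjects,
        n_loads=6,
        n_trials_per_load=n_trials,
        n_parcels=n_parcels,
        snr=snr,
        seed=seed,
    )
    c = coupling_factor
    cfs_edges = {2: [(0, 1), (2, 3), (4, 5)], 3: [(6, 7), (7, 0)]}
    load_edges = {2: [(1, 2)], 3: [(3, 4)]}
    pac_edge = (5, 6)
    truth = [
        synth.CouplingSpec(p, q, 10.0, m, c, "cfs", retention_only=True)
        for m, edges in cfs_edges.items()
        for (p, q) in edges
    ]
    truth += [
        synth.CouplingSpec(p, q, 10.0, m, 0.0, "cfs", load_slope=0.15,
                           retention_only=True)
        for m, edges in load_edges.items()
        for (p, q) in edges
    ]
    truth.append(synth.CouplingSpec(*pac_edge, 10.0, 4, 0.7, "pac",
                                    retention_only=True))
    study = synth.generate_study(cfg, truth)
    acfg = AnalysisConfig(f_lows=(10.0,), ratios=(2, 3, 4), alpha=alpha,
                          fdr_method="bh", seed=seed)
    tensors = compute_coupling(study, acfg)
    stats = run_group_stats(tensors, acfg)
    d_edges = stats["edges_directed"]

    planted_mean = {(m, pq) for m, edges in cfs_edges.items() for pq in edges}
    planted_any = planted_mean | {(m, pq) for m, edges in load_edges.items()
                                  for pq in edges}
    hits = 0
    for m, (p, q) in planted_mean:
        g = stats["mean"][("cfs", (10.0, m))]
        hits += bool(g.tail(+1)[_edge_index(d_edges, p, q)])
    sensitivity = hits / len(planted_mean)

    fp = 0
    n_null = 0
    for m in (2, 3, 4):
        g = stats["mean"][("cfs", (10.0, m))]
        for e in range(len(d_edges)):
            pq = (int(d_edges[e, 0]), int(d_edges[e, 1]))
            if (m, pq) in planted_any:
                continue
            n_null += 1
            fp += bool(g.significant[e])
    fpr = fp / n_null

    load_hits = 0
    for m, edges in load_edges.items():
        g = stats["load"][("cfs", (10.0, m))]
        for (p, q) in edges:
            load_hits += bool(g.tail(+1)[_edge_index(d_edges, p, q)])
    load_sensitivity = load_hits / sum(len(v) for v in load_edges.values())

    g_pac = stats["mean"][("pac", (10.0, 4))]
    g_cfs4 = stats["mean"][("cfs", (10.0, 4))]
    e_pac = _edge_index(d_edges, *pac_edge)
    return {
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "load_sensitivity": load_sensitivity,
        "pac_detected": bool(g_pac.tail(+1)[e_pac]),
        "pac_edge_cfs_significant": bool(g_cfs4.significant[e_pac]),
        "n_planted": len(planted_mean),
        "n_null_edges": n_null,
        "alpha": alpha,
        "study": study,
        "tensors": tensors,
        "stats": stats,
    }


def surrogate_calibration(
    seed: int = 0,
    n_reps: int = 500,
    n_surrogates: int = 1000,
    n_trials: int = 60,
    n_samples: int = 600,
    f_low: float = 10.0,
    ratio: int = 3,
    fs: float = 600.0,
    percentile: float = 99.0,
) -> dict:
    """False-positive rate of the time-shift surrogate threshold.

    Repeatedly generates independent (uncoupled) multi-trial narrow-band
    series, thresholds the observed across-trials n:m PLV at the
    percentile of per-trial random-shift surrogates (linear shifts
    within trials that carry the extra shift margin), and counts
    exceedances; nominal rate is 1 - percentile/100.

    Defaults mirror the smallest study the recovery analyses use: 60
    trials and 1 s estimation windows.  The surrogate threshold's
    conditional coverage improves with the trial count (the per-trial
    lags are the source of surrogate variability), so calibration is
    assessed at the study's own scale.
    """
    hits = 0
    max_lag = int(round(0.3 * fs))
    shape = (n_trials, n_samples + max_lag)
    for rep in range(n_reps):
        rng_x = np.random.default_rng([seed, rep, 1])
        rng_y = np.random.default_rng([seed, rep, 2])
        x = synth._filtered_noise(shape, f_low, fs, rng_x)
        y = synth._filtered_noise(shape, ratio * f_low, fs, rng_y)
        observed, null = timeshift_null_plv_trials(
            np.angle(x), np.angle(y), 1, ratio, fs,
            n_surrogates=n_surrogates, percentile=percentile,
            rng=[seed, rep, 3],
        )
        hits += observed > null.threshold_value
    return {
        "fp_rate": hits / n_reps,
        "nominal": 1.0 - percentile / 100.0,
        "n_reps": n_reps,
    }


def _null_plv(rng: np.random.Generator, n_obs: int, shape: tuple[int, ...]) -> np.ndarray:
    """Finite-sample null PLV draws: |mean of n_obs random unit phasors|."""
    phasors = np.exp(1j * rng.uniform(-np.pi, np.pi, size=shape + (n_obs,)))
    return np.abs(phasors.mean(axis=-1))


def fdr_null_calibration(
    seed: int = 0,
    n_reps: int = 200,
    n_edges: int = 100,
    n_subjects: int = 12,
    n_obs: int = 300,
    alpha: float = 0.05,
    fdr_method: str = "bh",
) -> dict:
    """False-discovery proportion of the edge FDR under the global null.

    Retention and baseline PLV estimates are drawn from the exact
    finite-sample null of the estimator (modulus of the mean of n_obs
    random unit phasors) for every subject and edge; any discovery is a
    false discovery, so the mean FDP equals the FDR, which must stay at
    or below alpha.
    """
    rng = np.random.default_rng([seed, 0xFD])
    fdp = np.empty(n_reps)
    for rep in range(n_reps):
        ret = _null_plv(rng, n_obs, (n_subjects, n_edges))
        bl = _null_plv(rng, n_obs, (n_subjects, n_edges))
        g = gs.mean_condition_test(ret, bl, alpha=alpha, fdr_method=fdr_method)
        n_disc = g.n_significant
        fdp[rep] = 1.0 if n_disc > 0 else 0.0  # all discoveries are false
    return {
        "mean_fdp": float(np.mean(fdp)),
        "alpha": alpha,
        "n_reps": n_reps,
        "method": fdr_method,
    }


def snr_audit_experiment(
    seed: int = 0,
    n_subjects: int = 6,
    n_trials: int = 50,
    n_parcels: int = 8,
    snr: float = 1.5,
    n_sim_samples: int = 100_000,
) -> dict:
    """Observed vs predicted PLV changes under two planted regimes.

    Amplitude-only regime: constant coupling throughout the trial plus a
    retention-period amplitude gain — every observed PLV change is an
    SNR artifact, so observed and predicted changes should agree.
    Coupling-modulation regime: retention-only coupling at constant
    amplitude — the observed change must exceed the SNR prediction for
    nearly all planted edges.
    """
    m = 3
    edges = [(0, 1), (2, 3), (4, 5), (6, 7), (1, 2), (3, 4)]
    acfg = AnalysisConfig(f_lows=(10.0,), ratios=(m,), fdr_method="bh",
                          snr_sim_samples=n_sim_samples,
                          snr_top_edges=len(edges), seed=seed)

    def run(truth, gain):
        cfg = synth.StudyConfig(
            n_subjects=n_subjects, n_loads=2, n_trials_per_load=n_trials,
            n_parcels=n_parcels, snr=snr, retention_amplitude_gain=gain,
            seed=seed,
        )
        study = synth.generate_study(cfg, truth)
        tensors = compute_coupling(study, acfg)
        stats = run_group_stats(tensors, acfg)
        return run_snr_audit(tensors, stats, study, acfg)

    truth_amp = [synth.CouplingSpec(p, q, 10.0, m, 0.5, "cfs", retention_only=False)
                 for (p, q) in edges]
    audit_amp = run(truth_amp, gain=1.6)
    planted_idx = {(p, q) for (p, q) in edges}
    amp_rows = audit_amp[[(int(r.parcel_low), int(r.parcel_high)) in planted_idx
                          for _, r in audit_amp.iterrows()]]

    truth_mod = [synth.CouplingSpec(p, q, 10.0, m, 0.8, "cfs", retention_only=True)
                 for (p, q) in edges]
    audit_mod = run(truth_mod, gain=1.0)
    mod_rows = audit_mod[[(int(r.parcel_low), int(r.parcel_high)) in planted_idx
                          for _, r in audit_mod.iterrows()]]

    return {
        "amp_only_mean_observed": float(amp_rows.observed.mean()),
        "amp_only_mean_excess": float(amp_rows.excess.mean()),
        "coupling_mod_excess_positive_fraction": float((mod_rows.excess > 0).mean()),
        "coupling_mod_mean_observed": float(mod_rows.observed.mean()),
        "coupling_mod_mean_predicted": float(mod_rows.predicted.mean()),
        "n_edges": len(edges),
    }
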