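"""End-to-end pipeline: simulate -> filter/couple -> statistics -> graphs.

Each stage is an importable function operating on a
:class:`PipelineConfig`; :func:`run_pipeline` chains them, retains
partial outputs on failure, and writes a manifest with seeds and
checksums.  The in-memory entry points (:func:`compute_coupling`,
:func:`run_group_stats`, ...) are what tests and scripted analyses use;
the ``stage_*`` functions add file-based persistence around them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from . import behavior as bhv
from . import consistency as cons
from . import group_stats as gs
from . import io as cfio
from . import networks as net
from . import snr as snrmod
from .spectral import WaveletBank, morlet_kernel
from .synth import CouplingSpec, StudyConfig, SyntheticStudy, generate_noise_reference, generate_study

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "PipelineConfig",
    "directed_edges",
    "undirected_edges",
    "compute_coupling",
    "run_group_stats",
    "run_consistency",
    "run_networks",
    "run_behavior",
    "run_snr_audit",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis-side knobs: frequency pairs, statistics, surrogate counts."""

    f_lows: tuple[float, ...] = (10.0,)
    ratios: tuple[int, ...] = (2, 3, 4)
    alpha: float = 0.05
    fdr_method: str = "expected_fp"
    baseline_window: int = 0
    retention_windows: tuple[int, int] = (2, 3)
    consistency_shuffles: int = 2000
    system_randomizations: int = 5000
    attribution_permutations: int = 1000
    central_edges_mean: int = 500
    central_edges_load: int = 250
    snr_sim_samples: int = 100_000
    snr_top_edges: int = 200
    seed: int = 0

    @property
    def pairs(self) -> list[tuple[float, int]]:
        return [(f, m) for f in self.f_lows for m in self.ratios if m * f <= 90.0]

    @property
    def one_to_one_frequencies(self) -> list[float]:
        freqs = set(self.f_lows)
        for f, m in self.pairs:
            freqs.add(m * f)
        return sorted(freqs)


@dataclass
class PipelineConfig:
    """Full pipeline configuration: study design, truth, analysis, paths."""

    out_dir: str = "results/pipeline"
    study: StudyConfig = field(default_factory=StudyConfig)
    truth: list[CouplingSpec] = field(default_factory=list)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        study = StudyConfig(**{k: tuple(map(tuple, v)) if k == "windows" else
                               (tuple(v) if isinstance(v, list) else v)
                               for k, v in raw.get("study", {}).items()})
        truth = [CouplingSpec(**t) for t in raw.get("truth", [])]
        araw = {k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.get("analysis", {}).items()}
        return PipelineConfig(
            out_dir=raw.get("out_dir", "results/pipeline"),
            study=study,
            truth=truth,
            analysis=AnalysisConfig(**araw),
        )


# ---------------------------------------------------------------------------
# edge indexing


def directed_edges(n_parcels: int) -> np.ndarray:
    """Ordered (low, high) parcel pairs, p != q; shape (P*(P-1), 2)."""
    p, q = np.meshgrid(np.arange(n_parcels), np.arange(n_parcels), indexing="ij")
    keep = p != q
    return np.column_stack([p[keep], q[keep]])


def undirected_edges(n_parcels: int) -> np.ndarray:
    """Unordered parcel pairs p < q; shape (P*(P-1)/2, 2)."""
    p, q = np.triu_indices(n_parcels, k=1)
    return np.column_stack([p, q])


def _flatten(matrices: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """(..., P, P) -> (..., E) along an edge index."""
    return matrices[..., edges[:, 0], edges[:, 1]]


# ---------------------------------------------------------------------------
# coupling tensors


def _window_bounds(cfg: StudyConfig) -> list[tuple[int, int]]:
    return [(sl.start, sl.stop) for sl in cfg.window_slices()]


def compute_coupling(study: SyntheticStudy, acfg: AnalysisConfig) -> dict:
    """All coupling tensors for a study.

    Returns ``{"cfs"|"pac"|"cc": {(f_low, m): (S, L, W, P, P)},
    "one2one": {f: (S, L, W, P, P)}, "amp": {f: (S, L, W, P)}}``.
    CFS/PAC/CC matrices are directed low->high (rows are the
    low-frequency parcel); diagonals are NaN.  Only samples outside the
    wavelet edge margins of both bands enter each window's estimate.
    Trial counts are equalized across loads (PLV is biased by the
    observation count); generated studies have equal counts already, so
    the subsampling is the identity there.
    """
    cfg = study.config
    fs = cfg.sampling_rate
    S, L, T, P, ns = study.series.shape
    trial_sel = gs.equalize_trials([T] * L, seed=cfg.seed)
    freqs = acfg.one_to_one_frequencies
    bank = WaveletBank(sampling_rate=fs, frequencies=np.asarray(freqs))
    kernels = {f: morlet_kernel(f, bank) for f in freqs}
    half = {f: bank.half_width_samples(f) for f in freqs}
    wins = _window_bounds(cfg)
    W = len(wins)
    pairs = acfg.pairs

    def win_slice(i0: int, i1: int, margin: int) -> slice | None:
        a, b = max(i0, margin), min(i1, ns - margin)
        return slice(a, b) if a < b else None

    tensors: dict = {
        "cfs": {k: np.full((S, L, W, P, P), np.nan) for k in pairs},
        "pac": {k: np.full((S, L, W, P, P), np.nan) for k in pairs},
        "cc": {k: np.full((S, L, W, P, P), np.nan) for k in pairs},
        "one2one": {f: np.full((S, L, W, P, P), np.nan) for f in freqs},
        "amp": {f: np.full((S, L, W, P), np.nan) for f in freqs},
    }

    for s in range(S):
        for li in range(L):
            x = study.series[s, li][trial_sel[li]]  # (T, P, ns)
            phasor: dict[float, np.ndarray] = {}
            amp: dict[float, np.ndarray] = {}
            env_phasor: dict[tuple[float, int], np.ndarray] = {}
            for f in freqs:
                filt = fftconvolve(
                    x.astype(np.complex128), kernels[f][None, None, :], mode="same", axes=-1
                )
                a = np.abs(filt)
                phasor[f] = filt / np.where(a > 0, a, 1.0)
                amp[f] = a
                del filt
            for f_low, m in pairs:
                f_high = m * f_low
                env = fftconvolve(
                    amp[f_high].astype(np.complex128),
                    kernels[f_low][None, None, :],
                    mode="same",
                    axes=-1,
                )
                ea = np.abs(env)
                env_phasor[(f_low, m)] = env / np.where(ea > 0, ea, 1.0)
            for w, (i0, i1) in enumerate(wins):
                for f in freqs:
                    sl = win_slice(i0, i1, half[f])
                    if sl is None:
                        continue
                    z = phasor[f][:, :, sl].transpose(1, 0, 2).reshape(P, -1)
                    n_obs = z.shape[1]
                    plv = np.abs(z @ z.conj().T) / n_obs
                    np.fill_diagonal(plv, np.nan)
                    tensors["one2one"][f][s, li, w] = plv
                    tensors["amp"][f][s, li, w] = amp[f][:, :, sl].mean(axis=(0, 2))
                for f_low, m in pairs:
                    f_high = m * f_low
                    sl = win_slice(i0, i1, max(half[f_low], half[f_high]))
                    if sl is None:
                        continue
                    zl = phasor[f_low][:, :, sl].transpose(1, 0, 2).reshape(P, -1)
                    zh = phasor[f_high][:, :, sl].transpose(1, 0, 2).reshape(P, -1)
                    n_obs = zl.shape[1]
                    plv = np.abs((zl**m) @ zh.conj().T) / n_obs
                    np.fill_diagonal(plv, np.nan)
                    tensors["cfs"][(f_low, m)][s, li, w] = plv
                    # PAC: envelope carries both bands' margins
                    sl_e = win_slice(i0, i1, half[f_low] + half[f_high])
                    if sl_e is not None:
                        zl_e = phasor[f_low][:, :, sl_e].transpose(1, 0, 2).reshape(P, -1)
                        ze = env_phasor[(f_low, m)][:, :, sl_e].transpose(1, 0, 2).reshape(P, -1)
                        pacm = np.abs(zl_e @ ze.conj().T) / zl_e.shape[1]
                        np.fill_diagonal(pacm, np.nan)
                        tensors["pac"][(f_low, m)][s, li, w] = pacm
                    al = amp[f_low][:, :, sl].transpose(1, 0, 2).reshape(P, -1)
                    ah = amp[f_high][:, :, sl].transpose(1, 0, 2).reshape(P, -1)
                    zal = (al - al.mean(1, keepdims=True)) / al.std(1, keepdims=True)
                    zah = (ah - ah.mean(1, keepdims=True)) / ah.std(1, keepdims=True)
                    ccm = (zal @ zah.T) / al.shape[1]
                    np.fill_diagonal(ccm, np.nan)
                    tensors["cc"][(f_low, m)][s, li, w] = ccm
    return tensors


# ---------------------------------------------------------------------------
# group statistics


def run_group_stats(tensors: dict, acfg: AnalysisConfig) -> dict:
    """Mean- and Load-condition StatGraphs for every metric and pair.

    Returns a dict with per-(metric, key) StatGraphs under "mean" and
    "load", the directed/undirected edge index arrays, and a tidy
    connection-density table.
    """
    some = next(iter(tensors["one2one"].values()))
    P = some.shape[3]
    d_edges = directed_edges(P)
    u_edges = undirected_edges(P)
    rw = list(acfg.retention_windows)
    bw = acfg.baseline_window
    out: dict = {"mean": {}, "load": {}, "edges_directed": d_edges,
                 "edges_undirected": u_edges}
    rows = []
    for metric in ("cfs", "pac", "cc", "one2one"):
        for key, arr in tensors[metric].items():
            edges = u_edges if metric == "one2one" else d_edges
            flat = _flatten(arr, edges)  # (S, L, W, E)
            ret = flat[:, :, rw, :].mean(axis=2)  # (S, L, E)
            g_mean = gs.mean_condition_test(
                ret.mean(axis=1), flat[:, :, bw, :].mean(axis=1),
                alpha=acfg.alpha, fdr_method=acfg.fdr_method,
            )
            g_load = gs.load_condition_test(
                ret, alpha=acfg.alpha, fdr_method=acfg.fdr_method
            )
            out["mean"][(metric, key)] = g_mean
            out["load"][(metric, key)] = g_load
            for cond, g in (("mean", g_mean), ("load", g_load)):
                for tail, tname in ((1, "pos"), (-1, "neg")):
                    rows.append({
                        "metric": metric,
                        "f_low": key[0] if isinstance(key, tuple) else key,
                        "ratio": key[1] if isinstance(key, tuple) else 1,
                        "condition": cond,
                        "tail": tname,
                        "K": gs.connection_density(g, tail=tail),
                    })
    out["density"] = pd.DataFrame(rows)
    return out


def run_consistency(stats: dict, acfg: AnalysisConfig) -> pd.DataFrame:
    """Harmonic-consistency profiles per metric and condition.

    Builds the (f_low x ratio) positive-tail K matrix for each metric
    and condition and tests observed C against frequency-shuffle
    surrogates.  Requires at least two analyzed low frequencies.
    """
    dens = stats["density"]
    rows = []
    rng = np.random.default_rng([acfg.seed, 71])
    for metric in ("cfs", "pac", "cc"):
        for cond in ("mean", "load"):
            sub = dens[(dens["metric"] == metric) & (dens["condition"] == cond)
                       & (dens["tail"] == "pos")]
            piv = sub.pivot_table(index="f_low", columns="ratio", values="K")
            if piv.shape[0] < 2 or piv.shape[1] < 2:
                continue
            K = piv.to_numpy()
            prof = cons.consistency_profile(
                piv.index.to_numpy(), K,
                n_shuffles=acfg.consistency_shuffles, rng=rng,
            )
            for f, c_val, thr, sig in zip(prof.f_low, prof.C, prof.null_threshold,
                                          prof.significant):
                rows.append({"metric": metric, "condition": cond, "f_low": f,
                             "C": c_val, "null_95": thr, "significant": bool(sig)})
    return pd.DataFrame(rows)


def run_networks(stats: dict, meta, acfg: AnalysisConfig) -> dict:
    """Ratio-pooled summary graphs, hyperedges, system and hub analyses."""
    d_edges = stats["edges_directed"]
    u_edges = stats["edges_undirected"]
    rng = np.random.default_rng([acfg.seed, 72])
    out: dict = {"pooled": {}, "hyperedges": {}, "system": {}, "degree_corr": []}
    for f_low in sorted({k[0] for (metric, k) in stats["mean"] if metric == "cfs"}):
        edge_sets = {}
        pooled_ratio_labels: list[int] = []
        for (metric, key), g in stats["mean"].items():
            if metric != "cfs" or key[0] != f_low:
                continue
            m = key[1]
            sig = g.tail(+1)
            edge_sets[m] = [tuple(e) for e in d_edges[sig]]
            pooled_ratio_labels.extend([m] * int(sig.sum()))
        P = meta.n_fine
        pooled = net.pool_ratios(edge_sets, n_parcels=P)
        out["pooled"][f_low] = pooled
        if len(pooled.edges):
            # per-edge (not per-unique-pooled-edge) list with ratio labels
            flat_rows = [
                {"parcel_low": p, "parcel_high": q, "ratio": m}
                for m, es in sorted(edge_sets.items())
                for (p, q) in es
            ]
            flat = pd.DataFrame(flat_rows)
            aff = net.edge_adjacency(flat, meta)
            hyper = net.cluster_hyperedges(flat, aff)
            for h in hyper:
                h.single_ratio_p = net.single_ratio_attribution(
                    [r for (_, _, r) in h.member_edges], pooled_ratio_labels,
                    n_permutations=acfg.attribution_permutations, rng=rng,
                )
            out["hyperedges"][f_low] = [h for h in hyper if not (h.single_ratio_p < 0.05)]
            out["system"][f_low] = net.system_density(
                pooled, meta, n_rand=acfg.system_randomizations, rng=rng,
            )
        # hub-degree correlation per ratio against 1:1 networks
        for (metric, key), g in stats["mean"].items():
            if metric != "cfs" or key[0] != f_low:
                continue
            m = key[1]
            f_high = m * f_low
            cfs_graph = net.pool_ratios({m: [tuple(e) for e in d_edges[g.tail(+1)]]}, P)
            deg = {}
            for f_ps in (f_low, f_high):
                key_ps = ("one2one", min(
                    (k for (mm, k) in stats["mean"] if mm == "one2one"),
                    key=lambda k: abs(k - f_ps),
                ))
                g_ps = stats["mean"][key_ps]
                d = np.zeros(P, dtype=int)
                for (p, q) in u_edges[g_ps.tail(+1)]:
                    d[p] += 1
                    d[q] += 1
                deg[f_ps] = d
            dc = net.degree_correlation(cfs_graph, deg[f_low], deg[f_high])
            for end, res in dc.items():
                out["degree_corr"].append({
                    "f_low": f_low, "ratio": m, "end": end, **res,
                })
    dc_df = pd.DataFrame(out["degree_corr"])
    if len(dc_df):
        adj, rej = net.bh_adjust(list(dc_df["p"]), alpha=acfg.alpha)
        dc_df["p_adj"] = adj
        dc_df["significant"] = rej
    out["degree_corr"] = dc_df
    # frequency-by-frequency degree similarity of 1:1 networks
    one_freqs = sorted(k for (mm, k) in stats["mean"] if mm == "one2one")
    degrees = np.zeros((len(one_freqs), meta.n_fine), dtype=float)
    for i, f in enumerate(one_freqs):
        g_ps = stats["mean"][("one2one", f)]
        for (p, q) in u_edges[g_ps.tail(+1)]:
            degrees[i, p] += 1
            degrees[i, q] += 1
    out["degree_similarity"] = net.cross_frequency_degree_similarity(degrees)
    out["degree_similarity_freqs"] = one_freqs
    return out


def run_behavior(tensors: dict, stats: dict, study: SyntheticStudy,
                 acfg: AnalysisConfig) -> pd.DataFrame:
    """Strength-capacity correlations per f_low and ratio group."""
    d_edges = stats["edges_directed"]
    hr = study.behavior.hit_rate
    C = bhv.capacity(hr)
    C_prime = bhv.detrend_normalize(C)
    rows = []
    for group, ratios in bhv.RATIO_GROUPS.items():
        S_by_f: dict[float, np.ndarray] = {}
        for (metric, key), g in stats["mean"].items():
            if metric != "cfs" or key[1] not in ratios:
                continue
            f_low, m = key
            mask = g.tail(+1)
            if not mask.any():
                continue
            plv_flat = _flatten(tensors["cfs"][key], d_edges)
            S = bhv.network_strength(plv_flat, mask.astype(float))
            S_by_f.setdefault(f_low, []).append(S)  # type: ignore[arg-type]
        S_prime = {}
        for f_low, parts in S_by_f.items():
            S_avg = np.mean(parts, axis=0)
            try:
                S_prime[f_low] = bhv.detrend_normalize(S_avg)
            except ValueError:
                continue
        res = bhv.strength_capacity_correlation(S_prime, C_prime, alpha=acfg.alpha)
        for f_low, r in res.items():
            rows.append({"f_low": f_low, "ratio_group": group, **r})
    return pd.DataFrame(rows)


def run_snr_audit(tensors: dict, stats: dict, study: SyntheticStudy,
                  acfg: AnalysisConfig, condition: str = "mean") -> pd.DataFrame:
    """Observed vs SNR-predicted PLV change for the strongest edges.

    Focuses on the (f_low, ratio) pair with the highest positive-tail
    Mean-condition connection density, takes the edges with the largest
    observed change, estimates per-parcel SNR from apparent SNR against
    a matched noise-only reference, and predicts each edge's PLV change
    from the simulated PLV(c, SNR_x, SNR_y) surface at fixed inferred
    coupling.
    """
    dens = stats["density"]
    sub = dens[(dens["metric"] == "cfs") & (dens["condition"] == "mean")
               & (dens["tail"] == "pos")]
    if not len(sub):
        raise ValueError("no CFS density results to audit")
    best = sub.sort_values("K", ascending=False).iloc[0]
    f_low, m = float(best.f_low), int(best.ratio)
    f_high = m * f_low
    d_edges = stats["edges_directed"]
    plv_flat = _flatten(tensors["cfs"][(f_low, m)], d_edges)
    S_, L_, W_, E_ = plv_flat.shape
    rw = list(acfg.retention_windows)
    bw = acfg.baseline_window

    delta_obs = snrmod.observed_delta_plv(
        plv_flat, condition=condition, baseline_window=bw,
        retention_windows=tuple(rw),
    )
    top = snrmod.top_changed_edges(delta_obs, n_top=acfg.snr_top_edges)

    # per-parcel apparent SNR in baseline vs retention, per band
    cfg = study.config
    noise_ref = generate_noise_reference(cfg, n_trials=40, bands=[f_low, f_high])
    bank = WaveletBank(sampling_rate=cfg.sampling_rate, frequencies=np.asarray(sorted({f_low, f_high})))
    wins = _window_bounds(cfg)
    snr_est: dict[tuple[float, str], np.ndarray] = {}
    for f in (f_low, f_high):
        kern = morlet_kernel(f, bank)
        filt = fftconvolve(noise_ref.astype(np.complex128), kern[None, None, :],
                           mode="same", axes=-1)
        halfw = bank.half_width_samples(f)
        a_er = np.abs(filt[..., halfw:-halfw]).mean(axis=(0, 2))  # per parcel
        amp = tensors["amp"][f]  # (S, L, W, P)
        table = snrmod.build_asnr_table(f, n_samples=min(acfg.snr_sim_samples, 100_000),
                                        sampling_rate=cfg.sampling_rate,
                                        seed=acfg.seed)
        for cond_name, w_idx in (("init", [bw]), ("mod", rw)):
            a_exp = amp[:, :, w_idx, :].mean(axis=(0, 1, 2))  # per parcel
            vals = np.empty(len(a_exp))
            for p in range(len(a_exp)):
                a, _ = snrmod.asnr(np.atleast_1d(a_exp[p]), np.atleast_1d(a_er[p]))
                a = max(a, float(np.min(table[1])))
                s_val = snrmod.asnr_to_snr(a, table)
                vals[p] = float(np.clip(s_val, table[0].min(), table[0].max()))
            snr_est[(f, cond_name)] = vals

    grid = snrmod.build_snr_grid(
        f_low, m, n_samples=acfg.snr_sim_samples,
        sampling_rate=cfg.sampling_rate, seed=acfg.seed,
    )
    plv_init = plv_flat[:, :, bw, :].mean(axis=(0, 1))
    # chance level from the edges outside the audit's focus set: their
    # baseline PLV reflects the finite-sample modulus bias, which the
    # asymptotic simulation surface does not carry.  All surface values
    # are mapped onto the observed estimator's scale (Rice mean) before
    # inversion and prediction.
    off_focus = np.setdiff1d(np.arange(E_), top)
    chance = float(np.median(plv_init[off_focus])) if off_focus.size else 0.0
    n_eff = snrmod.effective_observations(chance)
    interp = grid.interpolator()
    rows = []
    lo_s, hi_s = grid.snr_values[0], grid.snr_values[-1]
    for e in top:
        p, q = int(d_edges[e, 0]), int(d_edges[e, 1])
        s_init = (float(np.clip(snr_est[(f_low, "init")][p], lo_s, hi_s)),
                  float(np.clip(snr_est[(f_high, "init")][q], lo_s, hi_s)))
        s_mod = (float(np.clip(snr_est[(f_low, "mod")][p], lo_s, hi_s)),
                 float(np.clip(snr_est[(f_high, "mod")][q], lo_s, hi_s)))
        curve_init = np.array([
            float(interp([cv, np.log(s_init[0]), np.log(s_init[1])])[0])
            for cv in grid.c_values
        ])
        obs_scale_init = snrmod.expected_plv(np.maximum.accumulate(curve_init), n_eff)
        if plv_init[e] <= obs_scale_init[0]:
            c_in = float(grid.c_values[0])
        elif plv_init[e] >= obs_scale_init[-1]:
            logger.warning("observed PLV %.3f above surface maximum; clipping",
                           plv_init[e])
            c_in = float(grid.c_values[-1])
        else:
            c_in = float(np.interp(plv_init[e], obs_scale_init, grid.c_values))
        pred = (float(snrmod.expected_plv(grid.lookup(c_in, *s_mod), n_eff))
                - float(snrmod.expected_plv(grid.lookup(c_in, *s_init), n_eff)))
        rows.append({
            "edge": int(e), "parcel_low": p, "parcel_high": q,
            "f_low": f_low, "ratio": m,
            "observed": float(delta_obs[e]), "predicted": float(pred),
            "excess": float(delta_obs[e] - pred), "c_inferred": float(c_in),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file-based stages


def stage_simulate(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = generate_study(cfg.study, cfg.truth)
    path = out / "study.h5"
    cfio.save_study(path, study)
    logger.info("simulate: wrote %s", path)
    return path


def stage_couple(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    study = cfio.load_study(out / "study.h5")
    tensors = compute_coupling(study, cfg.analysis)
    path = out / "coupling.h5"
    cfio.save_coupling(path, tensors)
    logger.info("couple: wrote %s", path)
    return path


def _load_tensors(cfg: PipelineConfig) -> dict:
    return cfio.load_coupling(Path(cfg.out_dir) / "coupling.h5")


def stage_stats(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    tensors = _load_tensors(cfg)
    stats = run_group_stats(tensors, cfg.analysis)
    cfio.write_tsv(out / "stats" / "density.tsv", stats["density"])
    for cond in ("mean", "load"):
        for (metric, key), g in stats[cond].items():
            edges = (stats["edges_undirected"] if metric == "one2one"
                     else stats["edges_directed"])
            name = (f"{metric}_f{key[0]:g}_m{key[1]}" if isinstance(key, tuple)
                    else f"{metric}_f{key:g}")
            cfio.write_tsv(out / "stats" / f"{cond}_{name}.tsv",
                           cfio.statgraph_frame(g, edges))
    logger.info("stats: wrote %s", out / "stats")
    return out / "stats"


def _rebuild_stats(cfg: PipelineConfig) -> tuple[dict, dict]:
    tensors = _load_tensors(cfg)
    return tensors, run_group_stats(tensors, cfg.analysis)


def stage_consistency(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    _, stats = _rebuild_stats(cfg)
    df = run_consistency(stats, cfg.analysis)
    return cfio.write_tsv(out / "consistency.tsv", df)


def stage_networks(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    study = cfio.load_study(out / "study.h5")
    _, stats = _rebuild_stats(cfg)
    res = run_networks(stats, study.parcel_meta, cfg.analysis)
    rows = []
    for f_low, g in res["pooled"].items():
        for _, e in g.edges.iterrows():
            rows.append({"f_low": f_low, "parcel_low": e.parcel_low,
                         "parcel_high": e.parcel_high, "weight": e.weight,
                         "ratios": ",".join(map(str, e.ratios))})
    cfio.write_tsv(out / "networks" / "pooled_edges.tsv",
                   pd.DataFrame(rows, columns=["f_low", "parcel_low",
                                               "parcel_high", "weight", "ratios"]))
    hrows = []
    for f_low, hs in res["hyperedges"].items():
        for i, h in enumerate(hs):
            for (p, q, r) in h.member_edges:
                hrows.append({"f_low": f_low, "hyperedge": i, "parcel_low": p,
                              "parcel_high": q, "ratio": r,
                              "single_ratio_p": h.single_ratio_p})
    cfio.write_tsv(out / "networks" / "hyperedges.tsv",
                   pd.DataFrame(hrows, columns=["f_low", "hyperedge", "parcel_low",
                                                "parcel_high", "ratio",
                                                "single_ratio_p"]))
    srows = []
    for f_low, sm in res["system"].items():
        n_sys = sm.K.shape[0]
        for i in range(n_sys):
            for j in range(n_sys):
                srows.append({"f_low": f_low, "system_low": i, "system_high": j,
                              "K": sm.K[i, j], "null_95": sm.null_threshold[i, j],
                              "significant": bool(sm.K[i, j] > sm.null_threshold[i, j])})
    cfio.write_tsv(out / "networks" / "system_density.tsv", pd.DataFrame(srows))
    if len(res["degree_corr"]):
        cfio.write_tsv(out / "networks" / "degree_correlation.tsv", res["degree_corr"])
    sim = res["degree_similarity"]
    freqs = res["degree_similarity_freqs"]
    cfio.write_tsv(out / "networks" / "degree_similarity.tsv",
                   pd.DataFrame(sim, index=freqs, columns=freqs).reset_index())
    return out / "networks"


def stage_behavior(cfg: PipelineConfig) -> Path | None:
    out = Path(cfg.out_dir)
    study = cfio.load_study(out / "study.h5")
    if study.behavior is None or study.behavior.hit_rate.size == 0:
        logger.warning("behavior: no behavior table in study; stage skipped")
        return None
    tensors, stats = _rebuild_stats(cfg)
    df = run_behavior(tensors, stats, study, cfg.analysis)
    return cfio.write_tsv(out / "behavior.tsv", df)


def stage_snr_audit(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    study = cfio.load_study(out / "study.h5")
    tensors, stats = _rebuild_stats(cfg)
    df = run_snr_audit(tensors, stats, study, cfg.analysis)
    return cfio.write_tsv(out / "snr_audit.tsv", df)


STAGES = [
    ("simulate", stage_simulate),
    ("couple", stage_couple),
    ("stats", stage_stats),
    ("consistency", stage_consistency),
    ("networks", stage_networks),
    ("behavior", stage_behavior),
    ("snr_audit", stage_snr_audit),
]


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Run the pipeline end to end; write a manifest with checksums.

    A stage failure aborts with a stage-named error while retaining the
    outputs of completed stages.  Re-running with an identical config
    and seed reproduces identical output checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            "study": dataclasses.asdict(cfg.study),
            "analysis": dataclasses.asdict(cfg.analysis),
            "truth": [dataclasses.asdict(t) for t in cfg.truth],
        },
        "stages": {},
    }
    for name, fn in STAGES:
        if stages is not None and name not in stages:
            continue
        try:
            result = fn(cfg)
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if result is None:
            manifest["stages"][name] = {"status": "skipped"}
        else:
            result = Path(result)
            files = sorted(p for p in (result.rglob("*") if result.is_dir() else [result])
                           if p.is_file())
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": {str(p.relative_to(out)): cfio.file_sha256(p) for p in files},
            }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
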