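"""Synthetic multi-subject studies of coupled narrow-band oscillations.

The generator emulates the statistical structure the analysis assumes in
source-space M/EEG: per (subject, load, trial, parcel) broadband real
time series assembled from band-limited oscillatory components plus
noise, with planted ground-truth coupling:

* ``cfs`` — n:m phase coupling between a slow oscillation at f_low in
  one parcel and a fast oscillation at m*f_low in another, injected as
  X' = X + c * A_y * exp(i*phi_y/m),  Y' = Y + c * A_x * exp(i*m*phi_x),
  each then renormalized to unit instantaneous amplitude;
* ``pac`` — the fast oscillation's amplitude modulated by the slow
  oscillation's phase, with no phase-phase injection;
* ``amp_corr`` — a shared slow modulation of both amplitude envelopes;
* ``one_to_one`` — within-frequency phase coupling (m = 1).

Coupling strength may grow with memory load (``load_slope``) and may be
restricted to the retention period of each trial.  Band-limited noise at
a controlled SNR is added per component, a pink-noise floor spans the
spectrum, and a row-normalized exponential-decay mixing matrix emulates
the distance-dependent cross-talk of source reconstruction.

Study-level defaults mirror the study design the analysis targets:
12 subjects, 6 memory loads, 300 trials per load at 600 Hz, trials with
two pre-stimulus baseline windows and retention windows at 0.4-0.7 and
0.7-1.0 s after stimulus onset.  All randomness derives from one master
seed through fixed per-(subject, load, parcel, component) spawn keys, so
a fixed seed yields a bit-identical study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .parcels import ParcelMeta, meta_from_mixing
from .spectral import WaveletBank, morlet_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "OscillatorSpec",
    "CouplingSpec",
    "StudyConfig",
    "StudyBehavior",
    "SyntheticStudy",
    "generate_oscillation",
    "inject_cfs",
    "add_noise",
    "mixing_matrix",
    "apply_mixing",
    "generate_behavior",
    "generate_study",
    "generate_noise_reference",
    "scaled_config",
]

F_MIN, F_MAX = 3.0, 90.0


@dataclass(frozen=True)
class OscillatorSpec:
    """A narrow-band oscillatory component of one parcel's signal."""

    center_frequency: float
    amplitude: float = 1.0
    parcel_id: int = 0

    def __post_init__(self) -> None:
        if not (F_MIN <= self.center_frequency <= F_MAX):
            raise ValueError(
                f"center_frequency {self.center_frequency} outside [{F_MIN}, {F_MAX}] Hz"
            )
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass(frozen=True)
class CouplingSpec:
    """A planted ground-truth interaction between two parcels.

    ``coupling_factor`` c is the injection strength at load 1; at load l
    the effective strength is clip(c + load_slope*(l-1), 0, 1).  For
    ``kind='pac'`` c is the amplitude-modulation depth.  With
    ``retention_only`` the coupling is switched on only after stimulus
    onset (smooth 100 ms ramps), so retention-vs-baseline contrasts can
    detect it.
    """

    source_parcel: int
    target_parcel: int
    f_low: float
    ratio_m: int = 1
    coupling_factor: float = 0.5
    kind: str = "cfs"
    load_slope: float = 0.0
    retention_only: bool = True

    def __post_init__(self) -> None:
        if self.kind not in {"cfs", "pac", "amp_corr", "one_to_one"}:
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        if self.kind == "one_to_one" and self.ratio_m != 1:
            raise ValueError("one_to_one coupling requires ratio_m = 1")
        if self.ratio_m < 1:
            raise ValueError("ratio_m must be a positive integer")
        if self.ratio_m * self.f_low > F_MAX:
            raise ValueError(f"ratio_m * f_low = {self.ratio_m * self.f_low} exceeds {F_MAX} Hz")
        if self.coupling_factor < 0:
            raise ValueError("coupling_factor must be nonnegative")

    @property
    def f_high(self) -> float:
        return self.ratio_m * self.f_low

    def strength_at_load(self, load: int) -> float:
        """Effective coupling factor at 1-based memory load ``load``."""
        c = self.coupling_factor + self.load_slope * (load - 1)
        if not 0.0 <= c <= 1.0:
            logger.warning(
                "coupling factor %.3f at load %d outside [0, 1]; clipped", c, load
            )
        return float(np.clip(c, 0.0, 1.0))


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic study.

    Defaults are the full-size design (12 subjects, 6 loads, 300 trials
    per load at 600 Hz); pass smaller counts for tractable analyses.
    Window boundaries are in seconds relative to stimulus onset; the
    first two are pre-stimulus baselines, the last two retention.
    """

    n_subjects: int = 12
    n_loads: int = 6
    n_trials_per_load: int = 300
    n_parcels: int = 400
    sampling_rate: float = 600.0
    trial_start: float = -1.25
    trial_stop: float = 1.45
    windows: tuple[tuple[float, float], ...] = (
        (-0.7, -0.4),
        (-0.35, -0.05),
        (0.4, 0.7),
        (0.7, 1.0),
    )
    snr: float = 2.0
    pink_floor: float = 0.2
    retention_amplitude_gain: float = 1.0
    mixing_width: float = 0.0
    background_frequencies: tuple[float, ...] = ()
    behavior_coupling_link: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loads < 1:
            raise ValueError("n_loads must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        bounds = [b for w in self.windows for b in w]
        if bounds != sorted(bounds) or any(a >= b for a, b in self.windows):
            raise ValueError("windows must be ordered and non-overlapping")
        if self.windows[0][0] < self.trial_start or self.windows[-1][1] > self.trial_stop:
            raise ValueError("windows must lie within the trial span")

    @property
    def n_samples(self) -> int:
        return int(round((self.trial_stop - self.trial_start) * self.sampling_rate))

    @property
    def times(self) -> np.ndarray:
        return self.trial_start + np.arange(self.n_samples) / self.sampling_rate

    def window_slices(self) -> list[slice]:
        out = []
        for a, b in self.windows:
            i0 = int(round((a - self.trial_start) * self.sampling_rate))
            i1 = int(round((b - self.trial_start) * self.sampling_rate))
            out.append(slice(i0, i1))
        return out


@dataclass
class StudyBehavior:
    """Per-subject, per-load hit rates and derived working-memory capacity."""

    hit_rate: np.ndarray  # (n_subjects, n_loads)

    @property
    def capacity(self) -> np.ndarray:
        """Capacity C(l) = HR(l) * l per subject and load."""
        loads = np.arange(1, self.hit_rate.shape[1] + 1)
        return self.hit_rate * loads


@dataclass
class SyntheticStudy:
    """A generated study: series, ground truth, behavior and metadata.

    ``series`` is real-valued broadband, shape
    (n_subjects, n_loads, n_trials, n_parcels, n_samples), float32.
    """

    series: np.ndarray
    truth: list[CouplingSpec]
    behavior: StudyBehavior
    parcel_meta: ParcelMeta
    config: StudyConfig
    subject_gain: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# elementary generators


def _band_kernel(f: float, fs: float) -> np.ndarray:
    bank = WaveletBank(sampling_rate=fs, frequencies=np.asarray([f]))
    return morlet_kernel(f, bank)


def _filtered_noise(shape: tuple[int, ...], f: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Morlet-filtered uniform white noise along the last axis, complex."""
    kern = _band_kernel(f, fs)
    pad = len(kern)  # discard wrap-in transients
    white = rng.uniform(-1.0, 1.0, size=shape[:-1] + (shape[-1] + 2 * pad,))
    from scipy.signal import fftconvolve

    filt = fftconvolve(white.astype(complex), kern[(np.newaxis,) * (white.ndim - 1)], mode="same", axes=-1)
    return filt[..., pad:-pad]


def generate_oscillation(
    n_samples: int,
    f: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Complex analytic narrow-band oscillation: Morlet-filtered white noise.

    The series has its spectral peak at ``f`` and is normalized to unit
    mean instantaneous amplitude.  A fixed seed gives an identical
    series.
    """
    if not 0 < f < fs / 2:
        raise ValueError(f"frequency {f} Hz must lie in (0, Nyquist={fs / 2} Hz)")
    rng = np.random.default_rng(seed)
    x = _filtered_noise((n_samples,), f, fs, rng)
    return x / np.mean(np.abs(x))


def inject_cfs(
    x_low: np.ndarray,
    y_high: np.ndarray,
    c: float | np.ndarray,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Inject 1:n phase coupling between a slow and a fast analytic series.

    The fast series is pulled toward a component phase-locked to n
    times the slow phase,

        Y' = (1 - c) * Y + c * A_x * exp(i * n * phi_x),

    a convex additive mixture: c = 0 leaves Y untouched, c = 1 makes
    the fast phase exactly n*phi_x (PLV_{1:n} = 1), and intermediate c
    interpolates monotonically.  The slow series is the phase
    reference and passes through unchanged — injection is directional
    (slow drives fast), since any slow-side phase mixture is amplified
    n-fold by the n:m comparison and cannot lock.  Both outputs are
    renormalized to unit instantaneous amplitude, so ``c`` shifts the
    phase-locked fraction without changing amplitudes.  ``c`` may be a
    scalar or a per-sample profile (e.g. retention-only coupling).
    """
    x = np.asarray(x_low)
    y = np.asarray(y_high)
    if x.shape != y.shape:
        raise ValueError(f"series shapes differ: {x.shape} vs {y.shape}")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("coupling factor must be nonnegative")
    ax, px = np.abs(x), np.angle(x)
    y_c = (1.0 - c) * y + c * ax * np.exp(1j * n * px)
    return _unit_amplitude(x), _unit_amplitude(y_c)


def _unit_amplitude(z: np.ndarray) -> np.ndarray:
    a = np.abs(z)
    return np.where(a > 0, z / np.where(a > 0, a, 1.0), 0.0)


def add_noise(
    x: np.ndarray,
    snr: float,
    f: float,
    fs: float,
    noise_seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Add an independent band-matched noise series scaled by 1/snr.

    The noise is Morlet-filtered white noise at ``f`` normalized to unit
    instantaneous amplitude, so ``snr`` is the amplitude ratio of signal
    to added noise; ``snr=inf`` returns the input unchanged.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    x = np.asarray(x)
    if not np.isfinite(snr):
        return x.copy()
    rng = np.random.default_rng(noise_seed)
    noise = _filtered_noise(x.shape, f, fs, rng)
    return x + (1.0 / snr) * _unit_amplitude(noise)


def mixing_matrix(n_parcels: int, width: float) -> np.ndarray:
    """Row-normalized exponential-decay mixing over parcel index distance.

    weight[p, q] proportional to exp(-|p - q| / width); ``width=0`` gives
    the identity (no mixing).  Diagonal dominance holds for width < 1/ln 2
    per neighbor; larger widths model heavier cross-talk.
    """
    if width <= 0:
        return np.eye(n_parcels)
    idx = np.arange(n_parcels)
    w = np.exp(-np.abs(idx[:, None] - idx[None, :]) / width)
    return w / w.sum(axis=1, keepdims=True)


def apply_mixing(series: np.ndarray, mixing: np.ndarray) -> np.ndarray:
    """Linear mixing across the parcel axis (second-to-last)."""
    mixing = np.asarray(mixing)
    if mixing.ndim != 2 or mixing.shape[0] != mixing.shape[1]:
        raise ValueError("mixing matrix must be square")
    if series.shape[-2] != mixing.shape[0]:
        raise ValueError("mixing matrix size does not match parcel axis")
    return np.einsum("pq,...qt->...pt", mixing, series)


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(
    config: StudyConfig,
    subject_gain: np.ndarray,
    rng: np.random.Generator,
    hr_max: float = 0.93,
    hr_floor: float = 0.52,
    midpoint: float = 4.0,
    steepness: float = 1.3,
    noise_sd: float = 0.02,
) -> StudyBehavior:
    """Hit rates declining logistically with load, above chance at load 6.

    HR(s, l) = floor + (max - floor) / (1 + exp((l - mid)/k)) plus a
    subject effect: subjects with a larger coupling gain decline later
    (``behavior_coupling_link`` scales how strongly the planted coupling
    gain shifts the midpoint), plus observation noise.
    """
    loads = np.arange(1, config.n_loads + 1)
    mid = midpoint + config.behavior_coupling_link * (subject_gain - 1.0)
    hr = hr_floor + (hr_max - hr_floor) / (
        1.0 + np.exp((loads[None, :] - mid[:, None]) / steepness)
    )
    hr = hr + rng.normal(0.0, noise_sd, size=hr.shape)
    return StudyBehavior(hit_rate=np.clip(hr, 0.0, 1.0))


# ---------------------------------------------------------------------------
# study assembly


def _coupling_profile(config: StudyConfig, spec: CouplingSpec) -> np.ndarray:
    """Per-sample coupling-strength multiplier (before the load factor)."""
    t = config.times
    if not spec.retention_only:
        return np.ones_like(t)
    ramp = 0.1
    on, off = 0.1, config.trial_stop - 0.05
    prof = np.zeros_like(t)
    prof[(t >= on + ramp) & (t <= off - ramp)] = 1.0
    rise = (t > on) & (t < on + ramp)
    prof[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp))
    fall = (t > off - ramp) & (t < off)
    prof[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - (off - ramp)) / ramp))
    return prof


def _component_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def generate_study(config: StudyConfig, truth: list[CouplingSpec]) -> SyntheticStudy:
    """Assemble a full synthetic study from a design and planted truth.

    Every parcel receives an independent oscillation at each analysis
    band (the union of the planted components' bands and
    ``config.background_frequencies``), band-matched noise at the
    configured SNR and a pink-noise floor; planted couplings replace the
    independent components of their endpoint parcels.  Linear mixing is
    applied last.  The per-subject coupling gain (lognormal, sd 0.2)
    scales all planted coupling factors and can be linked to behavior.
    """
    P = config.n_parcels
    for spec in truth:
        if not (0 <= spec.source_parcel < P and 0 <= spec.target_parcel < P):
            raise ValueError(f"coupling spec references parcel outside 0..{P - 1}")
        if spec.source_parcel == spec.target_parcel:
            raise ValueError("coupling spec endpoints must differ")

    fs = config.sampling_rate
    n_samp = config.n_samples
    master = np.random.default_rng([config.seed, 0xBEEF])
    subject_gain = np.exp(master.normal(0.0, 0.2, size=config.n_subjects))

    # bands every parcel oscillates in
    band_set: list[float] = []
    for spec in truth:
        for f in (spec.f_low, spec.f_high):
            if not any(np.isclose(f, g) for g in band_set):
                band_set.append(float(f))
    for f in config.background_frequencies:
        if not any(np.isclose(f, g) for g in band_set):
            band_set.append(float(f))
    if not band_set:
        band_set = [10.0]
    band_set.sort()

    # planted component lookup: (parcel, band index) -> coupling spec role
    planted: dict[tuple[int, int], tuple[CouplingSpec, str]] = {}
    for spec in truth:
        bi_low = int(np.argmin([abs(b - spec.f_low) for b in band_set]))
        bi_high = int(np.argmin([abs(b - spec.f_high) for b in band_set]))
        planted[(spec.source_parcel, bi_low)] = (spec, "low")
        planted[(spec.target_parcel, bi_high)] = (spec, "high")

    series = np.empty(
        (config.n_subjects, config.n_loads, config.n_trials_per_load, P, n_samp),
        dtype=np.float32,
    )
    shape_tr = (config.n_trials_per_load, n_samp)

    for s in range(config.n_subjects):
        for li in range(config.n_loads):
            load = li + 1
            # raw independent components per (parcel, band)
            raw: dict[tuple[int, int], np.ndarray] = {}
            for p in range(P):
                for bi, f in enumerate(band_set):
                    rng = _component_rng(config.seed, 1, s, li, p, bi)
                    x = _filtered_noise(shape_tr, f, fs, rng)
                    raw[(p, bi)] = x / np.mean(np.abs(x))
            # apply planted couplings (in place on raw components)
            for spec in truth:
                bi_low = int(np.argmin([abs(b - spec.f_low) for b in band_set]))
                bi_high = int(np.argmin([abs(b - spec.f_high) for b in band_set]))
                c_eff = spec.strength_at_load(load) * subject_gain[s]
                c_eff = float(np.clip(c_eff, 0.0, 1.0))
                prof = _coupling_profile(config, spec) * c_eff
                x = raw[(spec.source_parcel, bi_low)]
                y = raw[(spec.target_parcel, bi_high)]
                if spec.kind in {"cfs", "one_to_one"}:
                    xc, yc = inject_cfs(x, y, prof, spec.ratio_m)
                elif spec.kind == "pac":
                    xc = _unit_amplitude(x)
                    mod = 1.0 + prof * np.cos(np.angle(x))
                    yc = _unit_amplitude(y) * mod
                    yc = yc / np.mean(np.abs(yc))
                else:  # amp_corr: shared slow amplitude modulation
                    rng = _component_rng(config.seed, 2, s, li, spec.source_parcel)
                    g = _filtered_noise(shape_tr, spec.f_low / 2.0, fs, rng).real
                    g = g / (3.0 * np.std(g))
                    mod = 1.0 + prof * np.clip(g, -1.0, 1.0)
                    xc = _unit_amplitude(x) * mod
                    yc = _unit_amplitude(y) * mod
                    xc = xc / np.mean(np.abs(xc))
                    yc = yc / np.mean(np.abs(yc))
                raw[(spec.source_parcel, bi_low)] = xc
                raw[(spec.target_parcel, bi_high)] = yc
            # assemble broadband parcels
            gain_prof = 1.0
            if config.retention_amplitude_gain != 1.0:
                ramp = _coupling_profile(
                    config, CouplingSpec(0, 1, band_set[0], retention_only=True)
                )
                gain_prof = 1.0 + (config.retention_amplitude_gain - 1.0) * ramp
            block = np.zeros((P,) + shape_tr)
            for p in range(P):
                acc = np.zeros(shape_tr)
                for bi, f in enumerate(band_set):
                    comp = raw[(p, bi)] * gain_prof
                    noise_rng = _component_rng(config.seed, 3, s, li, p, bi)
                    comp = add_noise(comp, config.snr, f, fs, noise_rng)
                    acc += comp.real
                pink_rng = _component_rng(config.seed, 4, s, li, p)
                acc += config.pink_floor * _pink_noise(shape_tr, pink_rng)
                block[p] = acc
            if config.mixing_width > 0:
                mix = mixing_matrix(P, config.mixing_width)
                block = apply_mixing(np.moveaxis(block, 0, -2), mix)
                block = np.moveaxis(block, -2, 0)
            series[s, li] = np.moveaxis(block, 0, 1).astype(np.float32)

    behavior = generate_behavior(
        config, subject_gain, np.random.default_rng([config.seed, 0xFACE])
    )
    mix = mixing_matrix(P, config.mixing_width)
    meta = meta_from_mixing(mix)
    if not np.all(np.isfinite(series)):
        raise FloatingPointError("generated series contains non-finite values")
    return SyntheticStudy(
        series=series,
        truth=list(truth),
        behavior=behavior,
        parcel_meta=meta,
        config=config,
        subject_gain=subject_gain,
    )


def _pink_noise(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        scale = np.where(freqs > 0, 1.0 / np.sqrt(np.where(freqs > 0, freqs, 1.0)), 0.0)
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    sd = np.std(pink, axis=-1, keepdims=True)
    return pink / np.where(sd > 0, sd, 1.0)


def generate_noise_reference(
    config: StudyConfig,
    n_trials: int = 40,
    bands: list[float] | None = None,
) -> np.ndarray:
    """Noise-only trials matched to a study ("empty-room" analog).

    Returns (n_trials, n_parcels, n_samples) broadband series containing
    only the band-matched noise terms and the pink floor — the reference
    against which apparent SNR is estimated.  ``bands`` should list the
    study's oscillation bands; defaults to the configured background
    frequencies.
    """
    fs = config.sampling_rate
    band_set = list(bands) if bands else (list(config.background_frequencies) or [10.0])
    out = np.zeros((n_trials, config.n_parcels, config.n_samples))
    for p in range(config.n_parcels):
        acc = np.zeros((n_trials, config.n_samples))
        for bi, f in enumerate(band_set):
            rng = _component_rng(config.seed, 5, p, bi)
            noise = _filtered_noise((n_trials, config.n_samples), f, fs, rng)
            acc += (1.0 / config.snr) * _unit_amplitude(noise).real
        rng = _component_rng(config.seed, 6, p)
        acc += config.pink_floor * _pink_noise((n_trials, config.n_samples), rng)
        out[:, p] = acc
    return out


def scaled_config(base: StudyConfig | None = None, **overrides) -> StudyConfig:
    """Convenience: a copy of the default (or given) config with overrides."""
    cfg = base if base is not None else StudyConfig()
    return replace(cfg, **overrides)
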