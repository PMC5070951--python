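"""Morlet wavelet filtering into narrow-band complex analytic series.

A real broadband signal x(t) is convolved with complex Morlet wavelets

    w(t, f) = A * exp(-t^2 / (2 sigma_t^2)) * exp(2 i pi f t)

where sigma_f = f / m, sigma_t = 1 / (2 pi sigma_f) and the Morlet
parameter m (time-frequency trade-off, cycles of the carrier under the
Gaussian) defaults to 5.  The filtered series X(t, f) is complex and
decomposes into an amplitude envelope |X| and a phase arg(X); these are
the inputs of all phase-synchrony estimators in :mod:`crossfreq.coupling`.

Samples closer to a trial edge than the kernel half-width carry
convolution transients; they are flagged invalid rather than padded, and
downstream window statistics must exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "WaveletBank",
    "FilteredSeries",
    "default_frequencies",
    "morlet_kernel",
    "filter_series",
    "envelope_phase",
]

#: truncation of the Gaussian envelope, in units of sigma_t
KERNEL_TRUNCATION_SIGMAS = 5.0


def default_frequencies(n: int = 25, f_min: float = 3.0, f_max: float = 90.0) -> np.ndarray:
    """Log-spaced analysis frequencies, f_i = f_min * (f_max/f_min)**(i/(n-1)).

    Defaults give 25 frequencies from 3 to 90 Hz with a constant
    consecutive ratio of 30**(1/24) ~ 1.152.
    """
    if n < 2:
        raise ValueError("need at least 2 frequencies")
    return f_min * (f_max / f_min) ** (np.arange(n) / (n - 1))


@dataclass(frozen=True)
class WaveletBank:
    """A family of Morlet wavelets sharing a time-frequency parameter.

    Parameters
    ----------
    sampling_rate
        Sampling rate of the signals to be filtered, in Hz.
    frequencies
        Strictly increasing center frequencies in Hz (default: 25
        log-spaced values from 3 to 90 Hz).
    morlet_m
        Morlet parameter m = f / sigma_f (default 5).
    """

    sampling_rate: float
    frequencies: np.ndarray = field(default_factory=default_frequencies)
    morlet_m: float = 5.0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if self.morlet_m <= 0:
            raise ValueError("morlet_m must be positive")
        if freqs.ndim != 1 or np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    def sigma_f(self, f: float) -> float:
        return f / self.morlet_m

    def sigma_t(self, f: float) -> float:
        return 1.0 / (2.0 * np.pi * self.sigma_f(f))

    def half_width_samples(self, f: float) -> int:
        """Kernel half-width in samples (edge-invalid margin)."""
        return int(np.ceil(KERNEL_TRUNCATION_SIGMAS * self.sigma_t(f) * self.sampling_rate))

    def index_of(self, f: float) -> int:
        """Index of the bank frequency closest to ``f`` (log distance)."""
        return int(np.argmin(np.abs(np.log(self.frequencies) - np.log(f))))


def morlet_kernel(f: float, bank: WaveletBank) -> np.ndarray:
    """Complex Morlet kernel at center frequency ``f``.

    Symmetric (zero-phase) support truncated at +-5 sigma_t; normalized
    to unit energy so band amplitudes are comparable across frequencies.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f >= bank.sampling_rate / 2.0:
        raise ValueError(
            f"frequency {f} Hz is at or above Nyquist ({bank.sampling_rate / 2.0} Hz)"
        )
    sigma_t = bank.sigma_t(f)
    half = bank.half_width_samples(f)
    t = np.arange(-half, half + 1) / bank.sampling_rate
    kern = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * f * t)
    kern /= np.sqrt(np.sum(np.abs(kern) ** 2))
    return kern


@dataclass
class FilteredSeries:
    """Narrow-band complex analytic series with an edge-validity mask.

    ``values`` has shape (..., n_samples) for a single frequency or a
    frequency axis second-to-last when produced by :func:`filter_series`
    with several bank frequencies.  ``valid`` marks samples outside the
    kernel half-width of either trial edge.
    """

    values: np.ndarray
    valid: np.ndarray
    frequencies: np.ndarray
    sampling_rate: float

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def at(self, f: float) -> "FilteredSeries":
        """Single-frequency view (frequency axis dropped)."""
        i = int(np.argmin(np.abs(self.frequencies - f)))
        return FilteredSeries(
            values=self.values[..., i, :],
            valid=self.valid[..., i, :],
            frequencies=np.asarray([self.frequencies[i]]),
            sampling_rate=self.sampling_rate,
        )


def _convolve_same(x: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """'same'-mode complex convolution along the last axis."""
    if x.shape[-1] < kern.shape[0]:
        raise ValueError(
            f"series length {x.shape[-1]} shorter than kernel length {kern.shape[0]}"
        )
    return fftconvolve(x.astype(complex), kern[(np.newaxis,) * (x.ndim - 1)], mode="same", axes=-1)


def filter_series(x: np.ndarray, bank: WaveletBank) -> FilteredSeries:
    """Filter a real series into the bank's narrow bands.

    Parameters
    ----------
    x
        Real array, time along the last axis; leading axes (trials,
        parcels, ...) are preserved.

    Returns
    -------
    FilteredSeries with shape ``x.shape[:-1] + (n_freq, n_samples)`` and
    an edge-validity mask per frequency.
    """
    x = np.asarray(x)
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (len(bank.frequencies), n), dtype=complex)
    valid = np.zeros((len(bank.frequencies), n), dtype=bool)
    for i, f in enumerate(bank.frequencies):
        kern = morlet_kernel(f, bank)
        out[..., i, :] = _convolve_same(x, kern)
        half = bank.half_width_samples(f)
        if 2 * half < n:
            valid[i, half : n - half] = True
    valid = np.broadcast_to(valid, out.shape).copy()
    return FilteredSeries(out, valid, bank.frequencies, bank.sampling_rate)


def envelope_phase(x_high: FilteredSeries, f_low: float, bank: WaveletBank) -> FilteredSeries:
    """Phase of the amplitude envelope of a fast band, re-filtered at f_low.

    The envelope E(t, f_low, f_high) = A(t, f_high) (x) w(t, f_low) is the
    convolution of the fast band's amplitude with the slow wavelet; its
    phase is the quantity phase-amplitude coupling locks to the slow
    oscillation's phase.
    """
    if x_high.frequencies.size != 1:
        raise ValueError("x_high must be a single-frequency FilteredSeries (use .at(f))")
    f_high = float(x_high.frequencies[0])
    if f_low >= f_high:
        raise ValueError(f"f_low ({f_low}) must be below f_high ({f_high})")
    kern = morlet_kernel(f_low, bank)
    env = _convolve_same(x_high.amplitude, kern)
    half = bank.half_width_samples(f_low)
    n = env.shape[-1]
    valid = np.zeros(n, dtype=bool)
    if 2 * half < n:
        valid[half : n - half] = True
    valid = np.broadcast_to(valid, env.shape) & x_high.valid
    return FilteredSeries(env, valid.copy(), np.asarray([f_low]), x_high.sampling_rate)
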