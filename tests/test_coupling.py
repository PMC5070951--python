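"""PLV/PAC/amplitude-correlation estimators and surrogate nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossfreq import synth
from crossfreq.coupling import (
    amp_correlation,
    pac,
    plv_nm,
    ratio_pairs,
    sliding_plv,
    timeshift_null,
    timeshift_null_plv,
)
from crossfreq.spectral import FilteredSeries, default_frequencies


def plv_loop_oracle(theta_low, theta_high, n, m):
    """Literal sum-based evaluation of the n:m PLV definition."""
    acc = 0j
    count = 0
    for tl, th in zip(np.ravel(theta_low), np.ravel(theta_high)):
        acc += np.exp(1j * (m * tl - n * th))
        count += 1
    return abs(acc) / count


class TestPlvNm:
    def test_perfect_harmonic_locking(self, rng):
        theta = rng.uniform(-np.pi, np.pi, size=500)
        est = plv_nm(theta, 3 * theta, n=1, m=3)
        assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        tl = rng.uniform(-np.pi, np.pi, size=(4, 25))
        th = rng.uniform(-np.pi, np.pi, size=(4, 25))
        est = plv_nm(tl, th, n=2, m=5)
        assert est.value == pytest.approx(plv_loop_oracle(tl, th, 2, 5), abs=1e-12)
        assert est.n_observations == 100

    def test_null_expectation_scales_as_inverse_sqrt_n(self, rng):
        # |mean of N random unit phasors| has expectation ~ sqrt(pi)/2 / sqrt(N)
        for n_obs in (64, 256):
            vals = [
                plv_nm(rng.uniform(-np.pi, np.pi, n_obs),
                       rng.uniform(-np.pi, np.pi, n_obs)).value
                for _ in range(400)
            ]
            expected = np.sqrt(np.pi) / 2 / np.sqrt(n_obs)
            assert np.mean(vals) == pytest.approx(expected, rel=0.1)

    def test_constant_offset_invariance(self, rng):
        tl = rng.uniform(-np.pi, np.pi, size=300)
        th = rng.uniform(-np.pi, np.pi, size=300)
        a = plv_nm(tl, th, 1, 4).value
        b = plv_nm(tl + 0.7, th, 1, 4).value
        c = plv_nm(tl, th - 1.2, 1, 4).value
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 200))
    def test_bounds_and_self_locking(self, seed, n_obs):
        r = np.random.default_rng(seed)
        tl = r.uniform(-np.pi, np.pi, n_obs)
        th = r.uniform(-np.pi, np.pi, n_obs)
        v = plv_nm(tl, th, 1, 2).value
        assert 0.0 <= v <= 1.0
        assert plv_nm(tl, tl, 1, 1).value == pytest.approx(1.0, abs=1e-12)

    def test_valid_mask_and_empty_error(self, rng):
        tl = rng.uniform(-np.pi, np.pi, size=50)
        th = 2 * tl
        valid = np.zeros(50, dtype=bool)
        valid[:20] = True
        est = plv_nm(tl, th, 1, 2, valid=valid)
        assert est.n_observations == 20
        with pytest.raises(ValueError, match="no valid"):
            plv_nm(tl, th, 1, 2, valid=np.zeros(50, dtype=bool))

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError, match="shape"):
            plv_nm(np.zeros(10), np.zeros(11))


class TestPac:
    def test_identical_phases_give_unity(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 200)
        assert pac(theta, theta).value == pytest.approx(1.0, abs=1e-12)

    def test_unmodulated_amplitude_at_chance(self, rng):
        n_obs = 400
        null = [
            pac(rng.uniform(-np.pi, np.pi, n_obs),
                rng.uniform(-np.pi, np.pi, n_obs)).value
            for _ in range(300)
        ]
        expected = np.sqrt(np.pi) / 2 / np.sqrt(n_obs)
        assert np.mean(null) == pytest.approx(expected, rel=0.15)


class TestAmpCorrelation:
    def test_affine_relation_gives_unity(self, rng):
        a = rng.uniform(0.5, 2.0, size=300)
        est = amp_correlation(a, 2.0 * a + 1.0)
        assert est.value == pytest.approx(1.0, abs=1e-12)

    def test_matches_pearson_oracle(self, rng):
        a = rng.uniform(0, 2, size=200)
        b = rng.uniform(0, 2, size=200)
        r = np.corrcoef(a, b)[0, 1]
        assert amp_correlation(a, b).value == pytest.approx(r, abs=1e-12)

    def test_independent_amplitudes_bounded(self, rng):
        n_obs = 900
        count = 0
        for _ in range(200):
            v = amp_correlation(rng.uniform(0, 1, n_obs), rng.uniform(0, 1, n_obs)).value
            count += abs(v) > 3 / np.sqrt(n_obs)
        assert count / 200 < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            amp_correlation(np.ones(50), np.arange(50.0))


class TestSlidingPlv:
    @staticmethod
    def _series(values, valid, fs=600.0, f=10.0):
        return FilteredSeries(values, valid, np.asarray([f]), fs)

    def test_window_count_on_one_second_span(self):
        fs = 600.0
        n = 1200
        valid = np.zeros(n, dtype=bool)
        valid[300:900] = True  # exactly 1.0 s of valid samples
        theta = np.linspace(0, 40 * np.pi, n)
        x = self._series(np.exp(1j * theta), valid)
        y = self._series(np.exp(4j * theta), valid, f=40.0)
        ests = sliding_plv(x, y, n=1, m=4, window_len=0.3, step=0.05)
        assert len(ests) == 15
        assert all(e.value == pytest.approx(1.0, abs=1e-10) for e in ests)

    def test_step_change_detected(self, rng):
        fs = 600.0
        n = 2400
        valid = np.ones(n, dtype=bool)
        theta = np.cumsum(rng.normal(0.1, 0.05, n))
        noise = rng.uniform(-np.pi, np.pi, n)
        th_high = np.where(np.arange(n) < n // 2, noise, 4 * theta)
        x = self._series(np.exp(1j * theta), valid)
        y = self._series(np.exp(1j * th_high), valid, f=40.0)
        ests = sliding_plv(x, y, n=1, m=4)
        vals = np.array([e.value for e in ests])
        windows = np.array([e.window for e in ests])
        early = vals[windows < len(windows) // 3]
        late = vals[windows > 2 * len(windows) // 3]
        assert late.min() > early.max()


class TestTimeshiftNull:
    def test_median_percentile(self, rng):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        est = lambda a, b: float(np.corrcoef(a, b)[0, 1])
        null = timeshift_null(x, y, est, sampling_rate=600.0, n_surrogates=101,
                              percentile=50.0, rng=1)
        assert null.threshold_value == pytest.approx(np.median(null.values))

    def test_fast_path_matches_rolled_estimates(self, rng):
        tl = rng.uniform(-np.pi, np.pi, 2048)
        th = rng.uniform(-np.pi, np.pi, 2048)
        null = timeshift_null_plv(tl, th, n=1, m=3, sampling_rate=600.0,
                                  n_surrogates=50, rng=7)
        # recompute the full-lag PLV curve by explicit rolling
        zl = np.exp(3j * tl)
        for lag in (0, 5, 99, 180):
            direct = abs(np.mean(zl * np.conj(np.exp(1j * np.roll(th, lag)))))
            corr = np.fft.ifft(np.fft.fft(zl) * np.conj(np.fft.fft(np.exp(1j * th))))
            assert abs(corr[lag]) / tl.size == pytest.approx(direct, abs=1e-12)

    def test_coupled_inputs_exceed_threshold(self, rng):
        x = synth.generate_oscillation(4096, 10.0, 600.0, seed=3)
        y = synth.generate_oscillation(4096, 40.0, 600.0, seed=4)
        xc, yc = synth.inject_cfs(x, y, 0.9, 4)
        tl, th = np.angle(xc), np.angle(yc)
        observed = plv_nm(tl, th, 1, 4).value
        null = timeshift_null_plv(tl, th, 1, 4, 600.0, n_surrogates=500, rng=5)
        assert observed > null.threshold_value

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            timeshift_null_plv(np.zeros(100), np.zeros(100), 1, 1, 600.0)


class TestRatioPairs:
    def test_pairs_respect_frequency_ceiling(self):
        pairs = ratio_pairs(default_frequencies())
        assert all(f_high <= 90.0 for (_, _, f_high) in pairs)
        assert all(m * f_low <= 90.0 for (f_low, m, _) in pairs)

    def test_high_frequency_is_nearest_grid_point(self):
        freqs = default_frequencies()
        pairs = ratio_pairs(freqs, ratios=(4,))
        for f_low, m, f_high in pairs:
            target = m * f_low
            best = freqs[np.argmin(np.abs(np.log(freqs) - np.log(target)))]
            assert f_high == best
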