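"""Synthetic-study generator: oscillations, injections, noise, mixing."""

import numpy as np
import pytest
from scipy.signal import periodogram

from crossfreq import synth
from crossfreq.coupling import plv_nm
from crossfreq.synth import (
    CouplingSpec,
    OscillatorSpec,
    StudyConfig,
    add_noise,
    apply_mixing,
    generate_oscillation,
    generate_study,
    inject_cfs,
    mixing_matrix,
)

FS = 600.0


class TestGenerateOscillation:
    def test_spectral_peak_near_center(self):
        x = generate_oscillation(100_000, 10.0, FS, seed=1)
        freqs, power = periodogram(x.real, fs=FS)
        peak = freqs[np.argmax(power)]
        assert abs(peak - 10.0) < 10.0 / 5  # within sigma_f = f/m

    def test_deterministic_under_seed(self):
        a = generate_oscillation(5000, 10.0, FS, seed=9)
        b = generate_oscillation(5000, 10.0, FS, seed=9)
        assert np.array_equal(a, b)

    def test_mean_phase_increment_matches_frequency(self):
        x = generate_oscillation(100_000, 10.0, FS, seed=2)
        dphi = np.angle(np.exp(1j * np.diff(np.angle(x))))
        assert np.mean(dphi) == pytest.approx(2 * np.pi * 10.0 / FS, rel=0.02)

    def test_unit_mean_amplitude(self):
        x = generate_oscillation(20_000, 25.0, FS, seed=3)
        assert np.mean(np.abs(x)) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_frequency(self):
        with pytest.raises(ValueError, match="Nyquist"):
            generate_oscillation(1000, 400.0, FS)


class TestInjectCfs:
    def setup_method(self):
        self.x = generate_oscillation(100_000, 10.0, FS, seed=1)
        self.y = generate_oscillation(100_000, 40.0, FS, seed=2)

    def test_zero_coupling_returns_normalized_inputs(self):
        xc, yc = inject_cfs(self.x, self.y, 0.0, 4)
        assert np.allclose(xc, self.x / np.abs(self.x))
        assert np.allclose(yc, self.y / np.abs(self.y))

    def test_full_coupling_locks(self):
        xc, yc = inject_cfs(self.x, self.y, 1.0, 4)
        assert plv_nm(np.angle(xc), np.angle(yc), 1, 4).value > 0.9

    def test_monotone_in_coupling_factor(self):
        v = []
        for c in (0.2, 0.5, 1.0):
            xc, yc = inject_cfs(self.x, self.y, c, 4)
            v.append(plv_nm(np.angle(xc), np.angle(yc), 1, 4).value)
        assert v[0] < v[1] < v[2]

    def test_unit_output_amplitude(self):
        xc, yc = inject_cfs(self.x, self.y, 0.5, 4)
        assert np.allclose(np.abs(xc), 1.0)
        assert np.allclose(np.abs(yc), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            inject_cfs(self.x[:100], self.y, 0.5, 4)


class TestAddNoise:
    def test_infinite_snr_identity(self):
        x = generate_oscillation(5000, 10.0, FS, seed=4)
        assert np.array_equal(add_noise(x, np.inf, 10.0, FS, 0), x)

    def test_unit_snr_amplitude_ratio(self):
        x = generate_oscillation(50_000, 10.0, FS, seed=4)
        x = x / np.abs(x)
        noisy = add_noise(x, 1.0, 10.0, FS, 5)
        added = noisy - x
        assert np.mean(np.abs(added)) == pytest.approx(np.mean(np.abs(x)), rel=1e-6)

    def test_deterministic(self):
        x = generate_oscillation(5000, 10.0, FS, seed=4)
        a = add_noise(x, 2.0, 10.0, FS, 11)
        b = add_noise(x, 2.0, 10.0, FS, 11)
        assert np.array_equal(a, b)

    def test_invalid_snr(self):
        with pytest.raises(ValueError, match="snr"):
            add_noise(np.zeros(10, complex), 0.0, 10.0, FS)


class TestMixing:
    def test_identity_matrix_is_noop(self, rng):
        series = rng.standard_normal((3, 4, 100))
        assert np.allclose(apply_mixing(series, np.eye(4)), series)

    def test_mixing_inflates_one_to_one_plv(self):
        x = generate_oscillation(50_000, 10.0, FS, seed=6)
        y = generate_oscillation(50_000, 10.0, FS, seed=7)
        series = np.stack([x.real, y.real])  # (parcel, time)
        mixed = apply_mixing(series, np.array([[0.8, 0.2], [0.2, 0.8]]))
        from crossfreq.spectral import WaveletBank, filter_series

        bank = WaveletBank(sampling_rate=FS, frequencies=np.asarray([10.0]))
        def plv11(s):
            f = filter_series(s, bank)
            v = f.valid[0, 0]
            return plv_nm(f.phase[0, 0][v], f.phase[1, 0][v]).value

        assert plv11(mixed) > plv11(series)

    def test_equal_rows_make_parcels_identical(self, rng):
        series = rng.standard_normal((4, 200))
        mixed = apply_mixing(series, np.full((4, 4), 0.25))
        assert np.allclose(mixed, mixed[0])

    def test_non_square_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            apply_mixing(rng.standard_normal((4, 100)), np.ones((3, 4)))

    def test_mixing_matrix_rows_normalized_and_dominant(self):
        m = mixing_matrix(10, width=0.8)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert all(m[i, i] >= m[i].max() for i in range(10))
        assert np.array_equal(mixing_matrix(5, 0.0), np.eye(5))


class TestSpecs:
    def test_oscillator_bounds(self):
        with pytest.raises(ValueError):
            OscillatorSpec(center_frequency=2.0)
        with pytest.raises(ValueError):
            OscillatorSpec(center_frequency=10.0, amplitude=0.0)

    def test_coupling_spec_validation(self):
        with pytest.raises(ValueError, match="one_to_one"):
            CouplingSpec(0, 1, 10.0, 2, kind="one_to_one")
        with pytest.raises(ValueError, match="exceeds"):
            CouplingSpec(0, 1, 30.0, 4)
        with pytest.raises(ValueError, match="kind"):
            CouplingSpec(0, 1, 10.0, 2, kind="nope")

    def test_load_dependence_clipped_and_warned(self, caplog):
        spec = CouplingSpec(0, 1, 10.0, 2, coupling_factor=0.8, load_slope=0.1)
        with caplog.at_level("WARNING"):
            assert spec.strength_at_load(6) == 1.0
        assert "clipped" in caplog.text

    def test_config_window_validation(self):
        with pytest.raises(ValueError, match="windows"):
            StudyConfig(windows=((-0.5, -0.1), (-0.2, 0.1), (0.4, 0.7), (0.7, 1.0)))
        with pytest.raises(ValueError, match="snr"):
            StudyConfig(snr=0.0)


class TestGenerateStudy:
    @staticmethod
    def _tiny_config(**kw):
        base = dict(n_subjects=2, n_loads=2, n_trials_per_load=4, n_parcels=3,
                    snr=2.0, seed=5)
        base.update(kw)
        return StudyConfig(**base)

    def test_bit_identical_under_fixed_seed(self):
        cfg = self._tiny_config()
        truth = [CouplingSpec(0, 1, 10.0, 2, 0.7)]
        a = synth.generate_study(cfg, truth)
        b = synth.generate_study(cfg, truth)
        assert np.array_equal(a.series, b.series)
        assert np.array_equal(a.behavior.hit_rate, b.behavior.hit_rate)

    def test_series_shape_and_finiteness(self):
        cfg = self._tiny_config()
        study = generate_study(cfg, [CouplingSpec(0, 2, 10.0, 3, 0.5)])
        assert study.series.shape == (2, 2, 4, 3, cfg.n_samples)
        assert np.all(np.isfinite(study.series))

    def test_invalid_truth_rejected(self):
        cfg = self._tiny_config()
        with pytest.raises(ValueError, match="parcel"):
            generate_study(cfg, [CouplingSpec(0, 5, 10.0, 2, 0.5)])
        with pytest.raises(ValueError, match="differ"):
            generate_study(cfg, [CouplingSpec(1, 1, 10.0, 2, 0.5)])

    def test_hit_rates_decline_and_stay_above_chance(self):
        cfg = StudyConfig(n_subjects=12, n_loads=6, n_trials_per_load=1, n_parcels=1,
                          seed=8)
        gain = np.ones(12)
        beh = synth.generate_behavior(cfg, gain, np.random.default_rng(0))
        hr = beh.hit_rate
        assert np.all(hr >= 0) and np.all(hr <= 1)
        assert np.all(hr.mean(axis=0)[:-1] > hr.mean(axis=0)[1:])  # declining
        assert hr[:, -1].mean() > 0.5  # above chance at the highest load
        cap = beh.capacity
        assert np.all(cap <= np.arange(1, 7))
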