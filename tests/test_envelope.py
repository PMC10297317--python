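"""Envelope extraction: Doppler mapping, binarization, despeckling and
maximal-velocity tracing, including parameter recovery on synthetic
spectrograms built from a known velocity curve."""

import numpy as np
import pytest

from tcdonn.envelope import (BinarySpectrogram, Spectrogram, VelocityEnvelope,
                             binarize_spectrogram, despeckle,
                             doppler_shift_to_velocity, doppler_spectrogram,
                             envelope_from_csv, envelope_to_csv,
                             spectrogram_from_hdf5, spectrogram_to_hdf5,
                             trace_envelope)
from tcdonn.synthetic import (HEALTHY_PARAMS, generate_velocity_waveform,
                              synth_doppler_spectrogram)


class TestDopplerSpectrogram:
    def test_pure_tone_maps_to_predicted_velocity(self):
        fs = 10_000.0
        f_d = 1500.0  # Doppler shift in Hz
        t = np.arange(int(fs)) / fs
        spec = doppler_spectrogram(np.sin(2 * np.pi * f_d * t), fs)
        v_expected = float(doppler_shift_to_velocity(f_d))  # 1540*f_d/(2*1.75e6)
        ridge_bins = spec.magnitude.argmax(axis=0)
        v_ridge = spec.velocity_axis[ridge_bins]
        assert np.all(np.abs(v_ridge - v_expected) <= spec.bin_width)

    def test_zero_signal_gives_zero_magnitude(self):
        spec = doppler_spectrogram(np.zeros(2000), 1000.0)
        assert np.all(spec.magnitude == 0)

    @pytest.mark.parametrize("L,window_s,hop_s,fs", [
        (1000, 0.05, 0.01, 1000.0), (777, 0.1, 0.02, 500.0)])
    def test_frame_count_arithmetic(self, L, window_s, hop_s, fs):
        spec = doppler_spectrogram(np.ones(L), fs, window_s=window_s, hop_s=hop_s)
        nwin, nhop = round(window_s * fs), round(hop_s * fs)
        assert spec.magnitude.shape[1] == (L - nwin) // nhop + 1

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError):
            doppler_spectrogram(np.array([]), 1000.0)


def _spec(mag, bin_width=1.0, hop=0.01):
    n_v, n_t = mag.shape
    return Spectrogram(mag, np.arange(n_v) * bin_width, np.arange(n_t) * hop)


class TestBinarize:
    def test_two_level_image(self):
        mag = np.zeros((6, 6))
        mag[2:4, 2:4] = 1.0
        mask = binarize_spectrogram(_spec(mag)).mask
        np.testing.assert_array_equal(mask, mag > 0)

    def test_constant_image_falls_back_to_all_false(self):
        mask = binarize_spectrogram(_spec(np.full((4, 4), 3.0))).mask
        assert not mask.any()

    def test_ridge_separated_from_noise_floor(self, rng):
        # ridge at unit magnitude, floor 40 dB down with mild variation
        mag = 10 ** (-40 / 20) * (1 + 0.1 * rng.random((50, 40)))
        ridge = np.zeros((50, 40), dtype=bool)
        ridge[20:25] = True
        mag[ridge] = 1.0
        mask = binarize_spectrogram(_spec(mag)).mask
        assert mask[ridge].all() and not mask[~ridge].any()


class TestDespeckle:
    def _binary(self, mask, bin_width=1.0, hop=0.01):
        n_v, n_t = mask.shape
        return BinarySpectrogram(mask, np.arange(n_v) * bin_width,
                                 np.arange(n_t) * hop)

    def test_kernel_size_rule(self):
        # hop 0.01 s, bin 1 cm/s -> 0.03 s x 5 cm/s = 3 x 5 bins
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 10] = True  # isolated: erased by any kernel >= 3x3
        out = despeckle(self._binary(mask))
        assert not out.mask.any()

    def test_isolated_pixel_removed_solid_block_kept(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[2, 2] = True
        mask[10:24, 10:24] = True
        out = despeckle(self._binary(mask)).mask
        assert not out[2, 2]
        assert out[14:20, 14:20].all()

    def test_idempotent_on_smooth_regions(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:20] = True  # half-plane: already median-stable
        once = despeckle(self._binary(mask))
        twice = despeckle(once)
        np.testing.assert_array_equal(once.mask, twice.mask)


class TestTraceEnvelope:
    def _filled(self, v_of_t, n_v=120):
        """Mask true for all bins <= V(c), the clean filled-spectrum case."""
        mask = np.arange(n_v)[:, None] <= v_of_t[None, :]
        return BinarySpectrogram(mask, np.arange(n_v, dtype=float),
                                 np.arange(len(v_of_t)) * 0.01)

    def test_clean_filled_spectrum_traced_exactly(self, rng):
        v = rng.integers(30, 90, size=200).astype(float)
        v = np.convolve(v, np.ones(9) / 9, mode="same")  # keep jumps < 30 cm/s
        binary = self._filled(v)
        env = trace_envelope(binary, target_fs=100.0)
        # at 100 Hz output on a 100 Hz frame grid the trace aligns frame-wise
        assert env.valid_mask.all()
        np.testing.assert_allclose(env.samples, np.floor(v), atol=1.0)

    def test_empty_column_is_invalid(self):
        v = np.full(200, 50.0)
        binary = self._filled(v)
        binary.mask[:, 100] = False
        env = trace_envelope(binary, target_fs=100.0)
        assert not env.valid_mask[100]
        assert env.valid_mask[:99].all()

    def test_range_check_invalidates_superphysiological(self):
        v = np.full(50, 80.0)
        binary = self._filled(v, n_v=400)
        binary.mask[:350, 10] = True  # column spikes to 349 cm/s
        env = trace_envelope(binary, v_max_physio=300.0, target_fs=100.0)
        assert not env.valid_mask[10]

    def test_continuity_check_carries_forward(self):
        v = np.full(50, 60.0)
        v[20:] = 140.0  # implausible 80 cm/s jump between frames
        env = trace_envelope(self._filled(v, n_v=200), jump_max=30.0,
                             target_fs=100.0)
        assert not env.valid_mask[20]
        assert env.samples[19] == pytest.approx(60.0, abs=1.0)

    def test_speckle_above_spectrum_is_ignored_after_despeckle(self):
        v = np.full(200, 60.0)
        binary = self._filled(v)
        clean = trace_envelope(despeckle(binary), target_fs=100.0)
        binary.mask[100, 50] = True  # speckle 40 bins above the envelope
        speckled = trace_envelope(despeckle(binary), target_fs=100.0)
        np.testing.assert_allclose(speckled.samples, clean.samples, atol=1e-9)


class TestParameterRecovery:
    def _recover(self, speckle_rate, seed=0):
        from dataclasses import replace
        params = replace(HEALTHY_PARAMS, noise_sd=0.0)  # noise-free curve
        env = generate_velocity_waveform(params, 8.0, seed=3)
        spec = synth_doppler_spectrogram(env, speckle_rate=speckle_rate, seed=seed)
        traced = trace_envelope(despeckle(binarize_spectrogram(spec)))
        n = min(len(traced), len(env))
        ok = traced.valid_mask[:n]
        err = traced.samples[:n][ok] - env.samples[:n][ok]
        return float(np.sqrt(np.mean(err ** 2))), spec.bin_width

    def test_noise_free_rmse_within_two_bins(self):
        rmse, bin_width = self._recover(0.0)
        assert rmse <= 2.0 * bin_width

    def test_robust_to_sparse_speckle(self):
        rmse_clean, bin_width = self._recover(0.0)
        rmse_speckle, _ = self._recover(0.001, seed=11)
        assert abs(rmse_speckle - rmse_clean) <= 1.0 * bin_width

    def test_zero_envelope_gives_all_invalid(self):
        flat = VelocityEnvelope(np.full(1000, 1e-3), sample_rate=217.0)
        spec = synth_doppler_spectrogram(flat)
        traced = trace_envelope(despeckle(binarize_spectrogram(spec)))
        assert not traced.valid_mask.any()


class TestEnvelopeType:
    def test_invalid_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            VelocityEnvelope(np.ones(10), sample_rate=0.0)

    def test_nan_must_be_masked(self):
        with pytest.raises(ValueError):
            VelocityEnvelope(np.array([1.0, np.nan]),
                             valid_mask=np.array([True, True]))

    def test_envelope_never_exceeds_velocity_axis(self, rng):
        v = rng.uniform(20, 80, size=300)
        v = np.convolve(v, np.ones(15) / 15, mode="same")
        mask = np.arange(100)[:, None] <= v[None, :]
        binary = BinarySpectrogram(mask, np.arange(100, dtype=float),
                                   np.arange(300) * 0.01)
        env = trace_envelope(binary)
        valid = env.samples[env.valid_mask]
        assert valid.max() <= 99.0 and valid.min() >= 0.0


def test_envelope_csv_roundtrip(tmp_path):
    env = VelocityEnvelope(np.array([10.0, np.nan, 30.0]), sample_rate=217.0)
    path = tmp_path / "env.csv"
    envelope_to_csv(env, path)
    back = envelope_from_csv(path)
    np.testing.assert_array_equal(back.valid_mask, [True, False, True])
    np.testing.assert_allclose(back.samples[back.valid_mask], [10.0, 30.0])


def test_spectrogram_hdf5_roundtrip(tmp_path, rng):
    spec = _spec(rng.random((8, 9)))
    path = tmp_path / "spec.h5"
    spectrogram_to_hdf5(spec, path)
    back = spectrogram_from_hdf5(path)
    np.testing.assert_array_equal(back.magnitude, spec.magnitude)
    np.testing.assert_array_equal(back.time_axis, spec.time_axis)
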