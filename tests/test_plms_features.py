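import numpy as np
import pytest

from insound.audio_io import AudioClip
from insound.plms_features import (
    DegenerateFilterError,
    PatchConfig,
    build_mel_filterbank,
    extract_plms,
    frame_signal,
    inverse_mel_scale,
    log_frequency_remap,
    log_scale,
    mel_scale,
    mel_spectrum,
    render_image,
    stft,
)
from tests.conftest import make_tone

FS = 2500.0
REF_CONFIG = PatchConfig(num_frames=10, sample_rate=FS)


class TestFraming:
    def test_reference_frame_count(self):
        # L=6250, N=250, shift=125 -> floor((6250-250)/125)+1 = 49
        assert REF_CONFIG.window_samples == 250
        assert REF_CONFIG.shift_samples == 125
        assert REF_CONFIG.n_frames(6250) == 49

    def test_consecutive_frames_overlap_by_window_minus_shift(self):
        y = np.arange(1000, dtype=float)
        cfg = PatchConfig(num_frames=4, base_hop_ms=10, sample_rate=2500.0)
        frames = frame_signal(y, cfg)
        N, shift = cfg.window_samples, cfg.shift_samples
        np.testing.assert_array_equal(frames[0, shift:], frames[1, : N - shift])

    def test_doubling_patch_size_halves_frame_count(self):
        n10 = PatchConfig(num_frames=10, sample_rate=FS).n_frames(6250)
        n20 = PatchConfig(num_frames=20, sample_rate=FS).n_frames(6250)
        assert n20 <= n10 / 2 + 1
        assert n20 >= n10 / 2 - 1

    def test_doubling_patch_size_halves_bin_spacing(self):
        g10 = stft(np.random.default_rng(0).normal(size=6250), PatchConfig(10, sample_rate=FS))
        g20 = stft(np.random.default_rng(0).normal(size=6250), PatchConfig(20, sample_rate=FS))
        assert g20.bin_hz == pytest.approx(g10.bin_hz / 2)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            frame_signal(np.zeros(100), REF_CONFIG)


class TestStft:
    def test_tone_at_bin_center_peaks_at_that_bin(self):
        k = 30  # bin-center frequency k * fs / N = 300 Hz
        clip = make_tone(k * FS / 250, FS, 6250)
        gram = stft(clip.samples[0], REF_CONFIG)
        assert (gram.P.argmax(axis=1) == k).all()

    def test_zero_signal_gives_zero_power(self):
        gram = stft(np.zeros(6250), REF_CONFIG)
        assert gram.P.max() == 0.0

    def test_parseval_identity_per_frame(self):
        """One-sided power, with non-DC/non-Nyquist bins doubled, equals N times
        the windowed frame energy (direct time-domain sum oracle)."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=6250)
        gram = stft(y, REF_CONFIG)
        frames = frame_signal(y, REF_CONFIG)
        from insound.preprocess import hamming_window

        w = hamming_window(250)
        weights = np.full(gram.n_bins, 2.0)
        weights[0] = 1.0
        if 250 % 2 == 0:
            weights[-1] = 1.0
        lhs = (gram.P * weights).sum(axis=1)
        rhs = 250 * ((frames * w) ** 2).sum(axis=1)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-6)


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert mel_scale(0.0) == 0.0

    def test_closed_form_at_700(self):
        assert mel_scale(700.0) == pytest.approx(2595.0 * np.log10(2.0))

    @pytest.mark.parametrize("f", [10.0, 440.0, 1250.0])
    def test_round_trip(self, f):
        assert inverse_mel_scale(mel_scale(f)) == pytest.approx(f, rel=1e-9)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            mel_scale(-1.0)


class TestFilterbank:
    def test_centers_uniform_on_mel_axis(self):
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        spacings = np.diff(mel_scale(fb.centers))
        assert np.all(np.diff(fb.centers) > 0)
        np.testing.assert_allclose(spacings, spacings[0], rtol=1e-9)

    def test_unit_response_at_exact_center(self):
        fb = build_mel_filterbank(40, 0.0, 1250.0, 250, FS)
        for m in (0, 10, 39):
            assert fb.evaluate(fb.centers[m])[m] == pytest.approx(1.0)

    def test_adjacent_filters_sum_to_one_between_centers(self):
        fb = build_mel_filterbank(40, 0.0, 1250.0, 250, FS)
        for m in (3, 20):
            for frac in (0.25, 0.5, 0.9):
                f = fb.centers[m] + frac * (fb.centers[m + 1] - fb.centers[m])
                resp = fb.evaluate(f)
                assert resp[m] + resp[m + 1] == pytest.approx(1.0)

    def test_row_maximum_near_center_bin(self):
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        bin_hz = FS / 250
        for m in range(fb.M):
            peak_bin = fb.weights[m].argmax()
            nearest = round(fb.centers[m] / bin_hz)
            assert abs(peak_bin - nearest) <= 1

    def test_degenerate_band_count_raises_with_guidance(self):
        with pytest.raises(DegenerateFilterError, match="lower M"):
            build_mel_filterbank(128, 0.0, 1250.0, 125, FS)  # patch size 5 window


class TestMelSpectrum:
    def test_zero_power_gives_zero_mel(self):
        gram = stft(np.zeros(6250), REF_CONFIG)
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        assert mel_spectrum(gram, fb).max() == 0.0

    def test_nonnegativity(self):
        gram = stft(np.random.default_rng(0).normal(size=6250), REF_CONFIG)
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        assert mel_spectrum(gram, fb).min() >= 0.0

    def test_tone_lands_in_band_nearest_its_frequency(self):
        f0 = 300.0
        gram = stft(make_tone(f0, FS, 6250).samples[0], REF_CONFIG)
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        S = mel_spectrum(gram, fb)
        nearest = np.abs(fb.centers - f0).argmin()
        assert np.all(np.abs(S.argmax(axis=1) - nearest) <= 1)

    def test_shape_mismatch_rejected(self):
        gram = stft(np.zeros(6250), REF_CONFIG)
        fb = build_mel_filterbank(64, 0.0, 1250.0, 500, FS)
        with pytest.raises(ValueError):
            mel_spectrum(gram, fb)


class TestLogScale:
    def test_max_cell_is_zero_db(self):
        S = np.array([[1.0, 10.0], [0.5, 2.0]])
        out = log_scale(S)
        assert out.S_db.max() == 0.0

    def test_decade_below_ref_is_minus_ten_db(self):
        S = np.array([[10.0, 1.0]])
        out = log_scale(S)
        assert out.S_db[0, 1] == pytest.approx(-10.0)

    def test_all_equal_input_is_all_zero_db(self):
        out = log_scale(np.full((3, 4), 7.0))
        np.testing.assert_array_equal(out.S_db, 0.0)

    def test_floor_clipping(self):
        out = log_scale(np.array([[1.0, 1e-30]]), floor_db=-80.0)
        assert out.S_db[0, 1] == -80.0

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError):
            log_scale(np.zeros((2, 2)))


class TestLogFrequencyRemap:
    @staticmethod
    def _fb():
        return build_mel_filterbank(64, 0.0, 1250.0, 250, FS)

    def test_decade_spacing_on_axis(self):
        # rows uniform in log10(f): positions of 10x frequencies differ by a
        # fixed number of rows (one decade of axis)
        fb = self._fb()
        n_rows, fmin = 256, 10.0
        row_logf = np.linspace(np.log10(fmin), np.log10(fb.f_max), n_rows)
        rows_per_decade = 1.0 / (row_logf[1] - row_logf[0])
        r10 = np.argmin(np.abs(row_logf - 1.0))
        r100 = np.argmin(np.abs(row_logf - 2.0))
        assert r100 - r10 == pytest.approx(rows_per_decade, abs=1)

    def test_constant_input_stays_constant(self):
        fb = self._fb()
        logmel = log_scale(np.full((5, fb.M), 3.0))
        out = log_frequency_remap(logmel, fb, n_rows=128, f_render_min=20.0)
        np.testing.assert_allclose(out, 0.0)

    def test_single_active_band_renders_stripe_at_log_position(self):
        fb = self._fb()
        m = 40
        S = np.full((5, fb.M), 1e-8)
        S[:, m] = 1.0
        out = log_frequency_remap(log_scale(S), fb, n_rows=256, f_render_min=20.0)
        row_logf = np.linspace(np.log10(20.0), np.log10(fb.f_max), 256)
        expected_row = np.argmin(np.abs(row_logf - np.log10(fb.centers[m])))
        assert np.all(np.abs(out.argmax(axis=0) - expected_row) <= 1)

    def test_invalid_render_floor(self):
        fb = self._fb()
        logmel = log_scale(np.ones((2, fb.M)))
        with pytest.raises(ValueError):
            log_frequency_remap(logmel, fb, f_render_min=2000.0)


class TestRenderImage:
    def test_shape_and_dtype(self):
        img = render_image(np.random.default_rng(0).uniform(-80, 0, (49, 64)))
        assert img.pixels.shape == (256, 256, 3)
        assert img.pixels.dtype == np.uint8

    def test_byte_determinism(self):
        vals = np.random.default_rng(1).uniform(-80, 0, (49, 64))
        a = render_image(vals.copy())
        b = render_image(vals.copy())
        assert np.array_equal(a.pixels, b.pixels)

    def test_all_floor_input_is_uniform_low_color(self):
        img = render_image(np.full((10, 10), -80.0))
        assert len(np.unique(img.pixels.reshape(-1, 3), axis=0)) == 1

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            render_image(np.array([[np.nan, 0.0]]))


class TestExtractPlms:
    def test_reference_config_yields_256_image(self, tone_2500):
        img = extract_plms(tone_2500, REF_CONFIG)
        assert img.pixels.shape == (256, 256, 3)
        assert img.feature_kind == "plms"

    def test_gain_invariance_byte_exact(self, tone_2500):
        half = AudioClip(0.5 * tone_2500.samples, FS)
        a = extract_plms(tone_2500, REF_CONFIG)
        b = extract_plms(half, REF_CONFIG)
        assert np.array_equal(a.pixels, b.pixels)

    def test_repeat_extraction_byte_identical(self, tone_2500):
        a = extract_plms(tone_2500, REF_CONFIG)
        b = extract_plms(tone_2500, REF_CONFIG)
        assert np.array_equal(a.pixels, b.pixels)

    def test_time_shift_translates_feature_frames(self):
        """Shifting the signal by one hop shifts the log-mel frames by one
        (framing algebra: frame n of the shifted signal is frame n+1)."""
        rng = np.random.default_rng(5)
        y = rng.normal(size=6250 + 125)
        cfg = REF_CONFIG
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        S_full = mel_spectrum(stft(y[:6250], cfg), fb)
        S_shift = mel_spectrum(stft(y[125 : 6250 + 125], cfg), fb)
        np.testing.assert_allclose(S_shift[:-1], S_full[1:], rtol=1e-10)

    def test_low_frequency_emphasis_two_tone(self):
        """A strong 150 Hz tone must out-shine a weak 900 Hz tone in dB."""
        t = np.arange(6250) / FS
        y = 0.8 * np.sin(2 * np.pi * 150 * t) + 0.08 * np.sin(2 * np.pi * 900 * t)
        gram = stft(y, REF_CONFIG)
        fb = build_mel_filterbank(64, 0.0, 1250.0, 250, FS)
        db = log_scale(mel_spectrum(gram, fb)).S_db
        band_150 = np.abs(fb.centers - 150).argmin()
        band_900 = np.abs(fb.centers - 900).argmin()
        assert db[:, band_150].max() > db[:, band_900].max()

    def test_mel_band_half_widths_shrink_with_longer_window(self):
        """At fixed f_t, doubling the window halves the achievable frequency
        granularity: the filterbank on the finer bin grid resolves bands whose
        nearest-bin quantization error halves."""
        fb_coarse = build_mel_filterbank(40, 0.0, 1250.0, 250, FS)
        fb_fine = build_mel_filterbank(40, 0.0, 1250.0, 500, FS)
        # same triangles, but twice the bin density under each
        assert fb_fine.weights.shape[1] == 2 * (fb_coarse.weights.shape[1] - 1) + 1
        assert (fb_fine.weights > 0).sum() > (fb_coarse.weights > 0).sum()

    def test_multichannel_clip_rejected(self, four_channel_clip):
        with pytest.raises(ValueError):
            extract_plms(four_channel_clip)
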