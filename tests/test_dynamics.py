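import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal

from doct import (
    AcquisitionMeta,
    PowerSpectrum,
    TimeSeriesStack,
    WelchParams,
    compute_dynamics_maps,
    frequency_std,
    intensity_std,
    mean_frequency,
    normalize_frames,
    pixel_psd,
    smooth_map,
)


def brute_force_moments(freqs, psd):
    """Independent oracle: explicit weighted-moment sums."""
    w = psd / psd.sum()
    m1 = float(np.sum(w * freqs))
    m2 = float(np.sum(w * freqs**2))
    return m1, float(np.sqrt(m2 - m1**2))


class TestNormalizeFrames:
    def test_constant_stack_becomes_ones(self, small_meta):
        stack = TimeSeriesStack(np.full((128, 32, 32), 3.7), small_meta)
        out = normalize_frames(stack)
        np.testing.assert_allclose(out.values, 1.0)

    def test_scale_invariance_across_frames(self):
        meta = AcquisitionMeta(n_frames=2, n_axial=4, n_lateral=4)
        pattern = np.arange(16, dtype=float).reshape(4, 4) + 1.0
        stack = TimeSeriesStack(np.stack([2 * pattern, 4 * pattern]), meta)
        out = normalize_frames(stack)
        np.testing.assert_allclose(out.values[0], out.values[1])

    def test_every_output_frame_has_unit_mean(self, random_stack):
        out = normalize_frames(random_stack)
        np.testing.assert_allclose(out.values.mean(axis=(1, 2)), 1.0, atol=1e-12)

    def test_nonpositive_frame_mean_names_frame(self, small_meta):
        values = np.ones((128, 32, 32))
        values[5] = 0.0
        with pytest.raises(ValueError, match="frame 5"):
            normalize_frames(TimeSeriesStack(values, small_meta))


class TestPixelPsd:
    def test_constant_series_with_detrend_is_zero(self, small_meta):
        spec = pixel_psd(np.full(128, 4.2), small_meta)
        np.testing.assert_allclose(spec.psd, 0.0, atol=1e-20)

    def test_sinusoid_peaks_at_its_frequency(self):
        # oracle: location of the direct-DFT magnitude peak
        meta = AcquisitionMeta(n_frames=512, frame_rate=56.0)
        t = np.arange(512) / 56.0
        series = np.sin(2 * np.pi * 10.0 * t)
        spec = pixel_psd(series, meta)
        peak_f = spec.freqs[np.argmax(spec.psd)]
        dft = np.abs(np.fft.rfft(series))
        dft[0] = 0.0
        oracle_f = np.fft.rfftfreq(512, 1 / 56.0)[np.argmax(dft)]
        assert abs(peak_f - 10.0) <= 56.0 / 256  # within one Welch bin
        assert abs(peak_f - oracle_f) <= 56.0 / 256

    def test_white_noise_parseval(self):
        # integrated PSD approximates the sample variance
        meta = AcquisitionMeta(n_frames=256, frame_rate=56.0)
        rng = np.random.default_rng(3)
        series = rng.normal(size=256)
        spec = pixel_psd(series, meta, WelchParams(segment_length=256))
        df = spec.freqs[1] - spec.freqs[0]
        integrated = np.sum(spec.psd) * df
        assert integrated == pytest.approx(np.var(series), rel=0.05)

    def test_welch_equals_periodogram_at_full_segment(self):
        meta = AcquisitionMeta(n_frames=256, frame_rate=56.0)
        rng = np.random.default_rng(4)
        series = rng.normal(size=256)
        params = WelchParams(segment_length=256, overlap_fraction=0.0,
                             window="boxcar", detrend=True)
        spec = pixel_psd(series, meta, params)
        f_ref, p_ref = signal.periodogram(
            series - series.mean(), fs=56.0, window="boxcar", detrend=False
        )
        np.testing.assert_allclose(spec.freqs, f_ref)
        np.testing.assert_allclose(spec.psd, p_ref, rtol=1e-10, atol=1e-15)

    def test_grid_ends_at_nyquist(self, small_meta):
        spec = pixel_psd(np.random.default_rng(0).normal(size=128), small_meta,
                         WelchParams(segment_length=64))
        assert spec.freqs[0] == 0.0
        assert spec.freqs[-1] == small_meta.frame_rate / 2

    def test_series_shorter_than_segment_fails(self, small_meta):
        with pytest.raises(ValueError):
            pixel_psd(np.ones(128), small_meta, WelchParams(segment_length=512))


class TestSpectralMoments:
    def test_single_bin_delta(self):
        freqs = np.array([0.0, 5.0, 10.0, 15.0])
        psd = np.array([0.0, 0.0, 2.0, 0.0])
        spec = PowerSpectrum(freqs, psd)
        assert mean_frequency(spec) == pytest.approx(10.0)
        assert frequency_std(spec) == pytest.approx(0.0)

    def test_symmetric_two_point_centroid_and_spread(self):
        freqs = np.array([0.0, 8.0, 12.0, 14.0])
        psd = np.array([0.0, 1.0, 1.0, 0.0])
        spec = PowerSpectrum(freqs, psd)
        assert mean_frequency(spec) == pytest.approx(10.0)
        assert frequency_std(spec) == pytest.approx(2.0)

    def test_flat_psd_centroid_is_mid_nyquist(self):
        freqs = np.linspace(0.0, 28.0, 129)
        spec = PowerSpectrum(freqs, np.ones(129))
        assert mean_frequency(spec) == pytest.approx(14.0)

    def test_zero_power_degenerate_convention(self):
        spec = PowerSpectrum(np.array([0.0, 1.0]), np.zeros(2))
        assert mean_frequency(spec) == 0.0
        assert frequency_std(spec) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_spectra(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.sort(rng.uniform(0, 28, size=64))
        freqs[0] = 0.0
        psd = rng.random(64)
        spec = PowerSpectrum(freqs, psd)
        m1, s = brute_force_moments(freqs, psd)
        assert mean_frequency(spec) == pytest.approx(m1, rel=1e-10)
        assert frequency_std(spec) == pytest.approx(s, rel=1e-10, abs=1e-10)

    def test_ar1_series_centroid_matches_full_dft_oracle(self):
        # the Welch centroid of an AR(1) series agrees with the centroid
        # of the plain full-series periodogram within a few bins
        meta = AcquisitionMeta(n_frames=512, frame_rate=56.0)
        rng = np.random.default_rng(9)
        x = np.zeros(512)
        for i in range(1, 512):
            x[i] = 0.7 * x[i - 1] + rng.normal()
        spec = pixel_psd(x, meta)
        x0 = x - x.mean()
        dft_psd = np.abs(np.fft.rfft(x0)) ** 2
        dft_freqs = np.fft.rfftfreq(512, 1 / 56.0)
        oracle, _ = brute_force_moments(dft_freqs, dft_psd)
        assert mean_frequency(spec) == pytest.approx(oracle, abs=1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        psd=hnp.arrays(np.float64, 33, elements=st.floats(0, 1e6)),
    )
    def test_centroid_bounded_by_grid(self, psd):
        freqs = np.linspace(0.0, 28.0, 33)
        spec = PowerSpectrum(freqs, psd)
        m1 = mean_frequency(spec)
        s = frequency_std(spec)
        assert 0.0 <= m1 <= 28.0
        assert 0.0 <= s <= 28.0


class TestIntensityStd:
    def test_constant_pixel_is_zero(self, small_meta):
        stack = TimeSeriesStack(np.full((128, 32, 32), 2.0), small_meta)
        np.testing.assert_allclose(intensity_std(stack), 0.0)

    def test_two_level_closed_form(self):
        meta = AcquisitionMeta(n_frames=2)
        a, b = 1.0, 5.0
        stack = TimeSeriesStack(
            np.stack([np.full((3, 3), a), np.full((3, 3), b)]), meta
        )
        np.testing.assert_allclose(intensity_std(stack), abs(a - b) / 2)

    def test_population_normalization_matches_brute_force(self, random_stack):
        out = intensity_std(random_stack)
        v = random_stack.values
        oracle = np.sqrt(((v - v.mean(axis=0)) ** 2).mean(axis=0))
        np.testing.assert_allclose(out, oracle, rtol=1e-12)


class TestDynamicsMaps:
    def test_constant_stack_degenerates_to_zero(self):
        meta = AcquisitionMeta(n_frames=64, n_axial=8, n_lateral=8)
        stack = TimeSeriesStack(np.full((64, 8, 8), 5.0), meta)
        maps = compute_dynamics_maps(stack, WelchParams(segment_length=32),
                                     smooth=False)
        np.testing.assert_allclose(maps.fmean, 0.0)
        np.testing.assert_allclose(maps.std, 0.0)

    @pytest.mark.parametrize("n_chunks", [4, 9])
    def test_chunking_is_bitwise_invariant(self, random_stack, n_chunks):
        params = WelchParams(segment_length=64)
        ref = compute_dynamics_maps(random_stack, params, n_chunks=1)
        out = compute_dynamics_maps(random_stack, params, n_chunks=n_chunks)
        np.testing.assert_array_equal(ref.fmean, out.fmean)
        np.testing.assert_array_equal(ref.fstd, out.fstd)
        np.testing.assert_array_equal(ref.std, out.std)

    def test_invalid_chunk_count_rejected(self, random_stack):
        with pytest.raises(ValueError):
            compute_dynamics_maps(random_stack, n_chunks=2)

    def test_maps_bounded_by_nyquist(self, random_stack):
        maps = compute_dynamics_maps(random_stack, WelchParams(segment_length=64))
        ny = random_stack.meta.frame_rate / 2
        assert np.all(maps.fmean >= 0) and np.all(maps.fmean <= ny)
        assert np.all(maps.fstd >= 0) and np.all(maps.fstd <= ny)

    def test_scale_invariance_of_frequency_maps(self, random_stack):
        params = WelchParams(segment_length=64)
        a = compute_dynamics_maps(random_stack, params, smooth=False)
        scaled = random_stack.with_values(random_stack.values * 37.0)
        b = compute_dynamics_maps(scaled, params, smooth=False)
        np.testing.assert_allclose(a.fmean, b.fmean, rtol=1e-9)
        np.testing.assert_allclose(a.fstd, b.fstd, rtol=1e-9)

    def test_phantom_layers_recover_analytic_fmean(self, phantom, phantom_maps):
        _, labels, expected = phantom
        for label, name in ((1, "viable"), (2, "necrotic")):
            measured = phantom_maps.fmean[labels == label].mean()
            assert measured == pytest.approx(expected[name], abs=0.3)

    def test_smoothing_only_touches_fmean(self, random_stack):
        params = WelchParams(segment_length=64)
        raw = compute_dynamics_maps(random_stack, params, smooth=False)
        sm = compute_dynamics_maps(random_stack, params, smooth=True)
        np.testing.assert_array_equal(raw.fstd, sm.fstd)
        np.testing.assert_array_equal(raw.std, sm.std)
        assert not np.array_equal(raw.fmean, sm.fmean)


class TestSmoothMap:
    def test_constant_map_unchanged(self):
        np.testing.assert_allclose(smooth_map(np.full((9, 9), 3.0)), 3.0)

    def test_sigma3_3x3_kernel_is_nearly_uniform_average(self):
        # a sigma-3 Gaussian truncated to 3x3 support has near-equal taps;
        # oracle: explicit normalised 3x3 Gaussian convolution at the centre
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = smooth_map(img)
        g = np.exp(-np.array([1, 0, 1]) ** 2 / (2 * 9.0))
        kernel = np.outer(g, g)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[1:4, 1:4], kernel, rtol=1e-12)
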