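import numpy as np
import pytest

from oscimap import (
    ConfigurationError,
    coherence_image,
    cross_psd,
    dff,
    prepost_spectrum_ratio,
    shuffle_null,
    sliding_autocorrelogram,
    sliding_crosscorrelogram,
    timepoint_correlation_matrix,
    welch_psd,
    windowed_covariance,
)
from oscimap.clustering import cluster_trace
from oscimap.synthetic import StimSpec, generate_sto_movie, random_scene
from conftest import make_movie

FS = 120.0
T = np.arange(0, 10, 1 / FS)


class TestSlidingAutocorrelogram:
    def test_pure_sinusoid_period_and_peak(self):
        corr = sliding_autocorrelogram(np.sin(2 * np.pi * 5 * T), FS)
        assert corr.dominant_period_s == pytest.approx(0.200, abs=1 / FS)
        assert corr.peak_value == pytest.approx(1.0, abs=0.01)

    def test_zero_lag_is_one_and_bounded(self):
        rng = np.random.default_rng(0)
        corr = sliding_autocorrelogram(rng.normal(size=1200), FS)
        mid = corr.values.size // 2
        assert corr.values[mid] == pytest.approx(1.0)
        assert np.all(np.abs(corr.window_stack) <= 1.0 + 1e-12)

    def test_white_noise_peak_small(self):
        """Null oracle: i.i.d. noise correlations are O(1/sqrt(n))."""
        rng = np.random.default_rng(1)
        corr = sliding_autocorrelogram(rng.normal(size=2400), FS)
        assert abs(corr.peak_value) < 3 / np.sqrt(FS)

    def test_shuffle_destroys_structure(self):
        x = np.sin(2 * np.pi * 5 * T)
        orig = sliding_autocorrelogram(x, FS)
        shuf = sliding_autocorrelogram(shuffle_null(x, seed=0), FS)
        assert orig.peak_value > 10 * abs(shuf.peak_value)

    def test_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            sliding_autocorrelogram(np.zeros(100), FS, window_s=1.0)


class TestShuffleNull:
    def test_histogram_preserved_exactly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        s = shuffle_null(x, seed=7)
        np.testing.assert_array_equal(np.sort(x), np.sort(s))

    def test_moments_invariant(self):
        x = np.random.default_rng(3).normal(2.0, 3.0, 1000)
        s = shuffle_null(x, seed=1)
        assert s.mean() == pytest.approx(x.mean())
        assert s.var() == pytest.approx(x.var())

    def test_autocorrelation_destroyed(self):
        """i.i.d. null oracle: non-zero-lag autocorrelation within 3/sqrt(n)."""
        x = np.sin(2 * np.pi * 5 * T)
        s = shuffle_null(x, seed=4)
        s = s - s.mean()
        n = s.size
        for lag in (1, 5, 24):
            r = np.dot(s[:-lag], s[lag:]) / (np.dot(s, s))
            assert abs(r) < 3 / np.sqrt(n)

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            shuffle_null(np.array([]))


class TestSlidingCrosscorrelogram:
    def test_self_correlation_peak_one_at_zero(self):
        x = np.sin(2 * np.pi * 5 * T)
        corr = sliding_crosscorrelogram(x, x, FS)
        assert corr.peak_lag_s == 0.0
        assert corr.peak_value == pytest.approx(1.0)

    def test_quarter_period_shift(self):
        a = np.sin(2 * np.pi * 5 * T)
        b = np.sin(2 * np.pi * 5 * (T - 0.05))  # delayed by T/4 = 50 ms
        corr = sliding_crosscorrelogram(a, b, FS)
        assert corr.peak_lag_s == pytest.approx(0.05, abs=1 / FS)

    def test_length_mismatch_points_to_resampling(self):
        with pytest.raises(ConfigurationError, match="resample"):
            sliding_crosscorrelogram(np.zeros(100), np.zeros(99), FS)

    def test_paired_beats_unpaired(self):
        """Movie cluster trace vs paired (same phase) and unpaired ephys."""
        from oscimap.preprocess import downsample_ephys
        from oscimap.synthetic import ClusterSpec, SceneConfig, generate_paired_ephys

        cl = ClusterSpec(center=(12, 12), frequency_hz=5.0, amplitude_mv=8.0,
                         phase_rad=0.7)
        scene = SceneConfig(frame_size=(24, 24), frame_rate=40.0,
                            duration_s=5.0, clusters=(cl,), noise_sd=2.0,
                            seed=0)
        fx = generate_sto_movie(scene)
        movie = dff(fx.movie)
        trace = cluster_trace(movie, np.argwhere(fx.labels == 0))
        paired = downsample_ephys(
            generate_paired_ephys(cl, 10_000.0, 5.0), 40.0).samples
        rng = np.random.default_rng(9)
        unpaired = rng.normal(size=trace.size)
        n = min(trace.size, paired.size)
        c_paired = sliding_crosscorrelogram(trace[:n], paired[:n], 40.0)
        c_unpaired = sliding_crosscorrelogram(trace[:n], unpaired[:n], 40.0)
        assert c_paired.peak_value > c_unpaired.peak_value
        assert c_paired.peak_lag_s == pytest.approx(0.0, abs=1 / 40.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 600))
        c1 = sliding_crosscorrelogram(a, b, FS)
        c2 = sliding_crosscorrelogram(3.0 * a + 7.0, 0.5 * b - 2.0, FS)
        np.testing.assert_allclose(c1.values, c2.values, atol=1e-9)

    @pytest.mark.parametrize("freq", [4.0, 6.0, 10.0])
    @pytest.mark.parametrize("phi", [0.0, np.pi / 2, np.pi])
    def test_phase_lag_recovery(self, freq, phi):
        """Injected phase offsets map to peak lags phi/(2 pi f) modulo the
        period, within one frame period at 120 fps."""
        a = np.sin(2 * np.pi * freq * T)
        b = np.sin(2 * np.pi * freq * T + phi)
        corr = sliding_crosscorrelogram(a, b, FS)
        period = 1 / freq
        expected = phi / (2 * np.pi * freq)
        residual = (abs(corr.peak_lag_s) - expected) % period
        err = min(residual, period - residual)
        assert err <= 1 / FS + 1e-9


class TestWindowedCovariance:
    def test_identical_pixels(self):
        t = np.arange(200) / 40.0
        tr = np.sin(2 * np.pi * 5 * t)
        data = np.tile(tr[:, None, None], (1, 2, 2))
        movie = make_movie(data)
        ana = windowed_covariance(movie, np.array([[0, 0], [1, 1]]),
                                  [(0.0, 5.0)])
        m = ana.matrices[0]
        assert m[0, 1] == pytest.approx(m[0, 0], rel=1e-9)

    def test_antiphase_negative(self):
        t = np.arange(200) / 40.0
        data = np.zeros((200, 1, 2))
        data[:, 0, 0] = np.sin(2 * np.pi * 5 * t)
        data[:, 0, 1] = -np.sin(2 * np.pi * 5 * t)
        ana = windowed_covariance(make_movie(data),
                                  np.array([[0, 0], [0, 1]]), [(0.0, 5.0)])
        assert ana.matrices[0][0, 1] < 0

    def test_independent_noise_off_diagonal_small(self):
        """Sampling-distribution oracle: cov of independent sequences has
        sd ~= sigma_a sigma_b / sqrt(n)."""
        rng = np.random.default_rng(6)
        data = rng.normal(0, 1, (2000, 1, 2))
        ana = windowed_covariance(make_movie(data, frame_rate=100.0),
                                  np.array([[0, 0], [0, 1]]), [(0.0, 20.0)],
                                  detrend_window_s=0.25)
        n = 2000
        assert abs(ana.matrices[0][0, 1]) < 3 / np.sqrt(n)

    def test_window_outside_recording_rejected(self):
        movie = make_movie(np.zeros((40, 2, 2)))
        with pytest.raises(ConfigurationError):
            windowed_covariance(movie, np.array([[0, 0], [1, 1]]),
                                [(0.0, 100.0)])

    def test_symmetry_and_diagonal(self, noisy_fixture):
        movie = dff(noisy_fixture.movie)
        pix = np.argwhere(noisy_fixture.labels >= 0)[:10]
        ana = windowed_covariance(movie, pix, [(0.0, 2.0), (2.0, 4.0)])
        for m in ana.matrices:
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            assert (np.diag(m) >= 0).all()

    def test_normalized_modes(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(100, 2, 2))
        ana = windowed_covariance(make_movie(data),
                                  np.array([[0, 0], [1, 1]]),
                                  [(0.0, 1.0), (1.0, 2.0)])
        joint = ana.normalized("joint")
        assert np.abs(joint).max() == pytest.approx(1.0)
        per = ana.normalized("per-window")
        for w in per:
            assert np.abs(w).max() == pytest.approx(1.0)


class TestCoherenceImage:
    def test_all_noise_flat_low(self):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 0.01, (400, 6, 6))
        movie = make_movie(data)
        pix = np.argwhere(np.ones((6, 6), bool))
        ana = windowed_covariance(movie, pix, [(0.0, 10.0)])
        img = coherence_image(ana)
        assert img.max() < 0.01**2  # well below per-pixel variance

    def test_coherent_cluster_maxima_inside_footprint(self, noisy_fixture):
        movie = dff(noisy_fixture.movie)
        labels = noisy_fixture.labels
        pix = np.concatenate([np.argwhere(labels == 0),
                              np.argwhere(labels == -1)[:30]])
        ana = windowed_covariance(movie, pix, [(0.0, 2.5), (2.5, 5.0)])
        img = coherence_image(ana)
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert labels[peak] == 0

    def test_max_over_windows(self):
        t = np.arange(400) / 40.0
        sig = np.where(t >= 5.0, np.sin(2 * np.pi * 5 * t), 0.0)
        data = np.tile(sig[:, None, None], (1, 1, 2))
        movie = make_movie(data)
        pix = np.array([[0, 0], [0, 1]])
        ana2 = windowed_covariance(movie, pix, [(0.0, 5.0), (5.0, 10.0)])
        only2 = windowed_covariance(movie, pix, [(5.0, 10.0)])
        np.testing.assert_allclose(coherence_image(ana2),
                                   coherence_image(only2), atol=1e-12)

    def test_single_pixel_rejected(self):
        movie = make_movie(np.zeros((40, 2, 2)))
        with pytest.raises(ConfigurationError):
            windowed_covariance(movie, np.array([[0, 0]]), [(0.0, 1.0)])


class TestCrossPsd:
    def test_self_csd_equals_psd_zero_phase(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=1200)
        freqs, mag, phase = cross_psd(x, x, FS)
        f2, psd = welch_psd(x, FS)
        np.testing.assert_allclose(mag, psd, rtol=1e-10)
        np.testing.assert_allclose(phase, 0.0, atol=1e-10)

    def test_antiphase_tone(self):
        a = np.sin(2 * np.pi * 5 * T)
        b = -a
        freqs, mag, phase = cross_psd(a, b, FS)
        k = np.argmin(np.abs(freqs - 5.0))
        assert abs(phase[k]) == pytest.approx(np.pi, abs=1e-6)

    def test_different_tones_csd_near_floor(self):
        """Direct FFT cross-spectrum oracle: tones at different frequencies
        share no power."""
        a = np.sin(2 * np.pi * 4 * T)
        b = np.sin(2 * np.pi * 9 * T)
        freqs, mag, _ = cross_psd(a, b, FS)
        _, psd_a = welch_psd(a, FS)
        k4 = np.argmin(np.abs(freqs - 4.0))
        assert mag[k4] < 1e-3 * psd_a[k4]
        # oracle: plain rFFT cross-spectrum at the tone bins is ~0 too
        fa, fb = np.fft.rfft(a), np.fft.rfft(b)
        cross = fa * np.conj(fb)
        bin4 = np.argmin(np.abs(np.fft.rfftfreq(a.size, 1 / FS) - 4.0))
        assert np.abs(cross[bin4]) < 1e-6 * np.abs(fa[bin4]) ** 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_psd(np.zeros(100), np.zeros(101), FS)


class TestPrepostSpectrumRatio:
    def test_stationary_tone_ratio_one(self):
        x = np.sin(2 * np.pi * 5 * T)
        freqs, ratio, peak, peak_f = prepost_spectrum_ratio(x, FS, (4.0, 6.0))
        k = np.argmin(np.abs(freqs - 5.0))
        assert ratio[k] == pytest.approx(1.0, rel=0.05)

    def test_doubled_amplitude_ratio_four(self):
        x = np.sin(2 * np.pi * 5 * T).copy()
        x[T >= 6.0] *= 2
        freqs, ratio, peak, peak_f = prepost_spectrum_ratio(x, FS, (4.0, 6.0))
        assert peak_f == pytest.approx(5.0)
        assert peak == pytest.approx(4.0, rel=0.05)

    def test_frequency_shift_pattern(self):
        """4 -> 6 Hz shift: ratio > 1 at 6 Hz, < 1 at 4 Hz."""
        x = np.where(T < 5.0, np.sin(2 * np.pi * 4 * T),
                     np.sin(2 * np.pi * 6 * T))
        freqs, ratio, _, _ = prepost_spectrum_ratio(x, FS, (4.5, 5.5))
        k6 = np.argmin(np.abs(freqs - 6.0))
        k4 = np.argmin(np.abs(freqs - 4.0))
        assert ratio[k6] > 1.0
        assert ratio[k4] < 1.0

    def test_insufficient_data_rejected(self):
        with pytest.raises(ConfigurationError):
            prepost_spectrum_ratio(np.zeros(600), FS, (1.0, 2.0))

    def test_entrainment_fixture_peaks_at_entrained_frequency(self):
        stim = StimSpec(onset_s=4.0, entrained_frequency_hz=6.0,
                        power_gain=2.0, post_phases_rad=(0.3, 0.3))
        scene = random_scene(seed=2, n_clusters=2, frame_rate=40.0,
                            duration_s=10.0, frequencies=(4.0, 5.0), stim=stim)
        fx = generate_sto_movie(scene)
        movie = dff(fx.movie)
        for gid in range(2):
            trace = cluster_trace(movie, np.argwhere(fx.labels == gid))
            _, _, _, peak_f = prepost_spectrum_ratio(
                trace, 40.0, (stim.onset_s, stim.end_s))
            assert peak_f == pytest.approx(6.0, abs=1.0)


class TestTimepointCorrelationMatrix:
    def test_in_phase_pair(self):
        a = np.sin(2 * np.pi * 5 * T)
        m = timepoint_correlation_matrix([a, 2 * a + 1])
        assert m[0, 1] == pytest.approx(1.0)

    def test_antiphase_pair(self):
        a = np.sin(2 * np.pi * 5 * T)
        m = timepoint_correlation_matrix([a, -a])
        assert m[0, 1] == pytest.approx(-1.0)

    def test_quadrature_pair_zero(self):
        a = np.sin(2 * np.pi * 5 * T)
        b = np.cos(2 * np.pi * 5 * T)
        m = timepoint_correlation_matrix([a, b])
        assert m[0, 1] == pytest.approx(0.0, abs=0.01)

    def test_zero_variance_reported_missing(self):
        a = np.sin(2 * np.pi * 5 * T)
        m = timepoint_correlation_matrix([a, np.zeros_like(a)])
        assert np.isnan(m[0, 1]) and np.isnan(m[1, 0])
        assert m[0, 0] == 1.0

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(11)
        m = timepoint_correlation_matrix(rng.normal(size=(4, 500)))
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_entrainment_raises_correlation(self):
        """Uncorrelated pre-stim clusters become correlated after
        entrainment to a common frequency and phase."""
        stim = StimSpec(onset_s=4.0, entrained_frequency_hz=6.0,
                        power_gain=2.0, post_phases_rad=(0.5, 0.5))
        scene = random_scene(seed=3, n_clusters=2, frame_rate=40.0,
                            duration_s=10.0, frequencies=(4.0, 5.0), stim=stim)
        fx = generate_sto_movie(scene)
        movie = dff(fx.movie)
        traces = np.asarray([
            cluster_trace(movie, np.argwhere(fx.labels == g)) for g in range(2)])
        pre = timepoint_correlation_matrix(traces, (1.0, 3.0), 40.0)
        post = timepoint_correlation_matrix(traces, (6.0, 8.0), 40.0)
        assert abs(pre[0, 1]) < 0.3
        assert post[0, 1] > 0.8
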