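import numpy as np
import pytest

import fishbeat as fb
from fishbeat.motion import MotionMask
from fishbeat.spectral import circular_distance, phase_map, snr_of_peak


def brute_force_dft_argmax(series, fps):
    """Independent oracle: dominant nonzero bin by direct DFT summation."""
    n = len(series)
    x = series - series.mean()
    amps = []
    for k in range(1, n // 2 + 1):
        coeff = sum(x[j] * np.exp(-2j * np.pi * k * j / n) for j in range(n))
        amps.append(abs(coeff))
    k = 1 + int(np.argmax(amps))
    return k, k * fps / n


def _stack_from_series(series_map, shape=(4, 4), fps=13.0):
    """FrameStack whose pixel (r, c) follows the given time series."""
    n = len(next(iter(series_map.values())))
    frames = np.zeros((n, *shape))
    for (r, c), series in series_map.items():
        frames[:, r, c] = series
    mask = np.zeros(shape, dtype=bool)
    for r, c in series_map:
        mask[r, c] = True
    stack = fb.FrameStack(frames=frames, fps=fps)
    return stack, MotionMask(mask=mask)


class TestPixelSpectra:
    def test_exact_bin_sinusoid_has_single_bin_mass(self):
        t = np.arange(130) / 13.0
        series = 0.3 + 0.1 * np.sin(2 * np.pi * 2.0 * t)
        stack, mask = _stack_from_series({(1, 1): series})
        spec = fb.pixel_spectra(stack, mask)
        assert spec.dominant_bin[0] == 20  # 20 * 13 / 130 = 2.0 Hz
        assert spec.dominant_freq[0] == pytest.approx(2.0)
        other = np.delete(spec.amplitude[0], [0, 20])
        assert other.max() < 1e-9 * spec.amplitude[0, 20]

    def test_constant_pixel_has_zero_spectrum(self):
        stack, mask = _stack_from_series({(0, 0): np.full(130, 0.4)})
        spec = fb.pixel_spectra(stack, mask)
        assert np.all(spec.amplitude[0, 1:] < 1e-12)
        assert spec.snr[0] == 0.0

    def test_off_bin_sinusoid_within_half_bin(self):
        t = np.arange(130) / 13.0
        series = np.sin(2 * np.pi * 2.05 * t)
        stack, mask = _stack_from_series({(2, 3): series})
        spec = fb.pixel_spectra(stack, mask)
        assert spec.dominant_freq[0] in (2.0, pytest.approx(2.1))
        k, f = brute_force_dft_argmax(series, 13.0)
        assert spec.dominant_bin[0] == k

    def test_frequency_resolution(self):
        stack, mask = _stack_from_series({(0, 0): np.random.default_rng(0).random(240)}, fps=24.0)
        spec = fb.pixel_spectra(stack, mask)
        assert spec.bin_width_hz == pytest.approx(0.1)
        np.testing.assert_allclose(np.diff(spec.freqs), 0.1)

    def test_too_few_frames_rejected(self):
        stack, mask = _stack_from_series({(0, 0): np.ones(8)})
        with pytest.raises(ValueError):
            fb.pixel_spectra(stack, mask)

    def test_dominant_bin_matches_brute_force_dft_100_series(self):
        """FFT path vs direct-summation DFT on random series."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            series = rng.random(32)
            stack, mask = _stack_from_series({(0, 0): series}, fps=13.0)
            spec = fb.pixel_spectra(stack, mask)
            k, _ = brute_force_dft_argmax(series, 13.0)
            assert spec.dominant_bin[0] == k

    def test_parseval_identity(self):
        """Sum of squared FFT amplitudes equals n * sum of squared samples
        (checks the transform convention, including the rfft folding)."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = int(rng.integers(16, 200))
            series = rng.random(n)
            stack, mask = _stack_from_series({(0, 0): series}, fps=13.0)
            spec = fb.pixel_spectra(stack, mask)
            amp2 = spec.amplitude[0] ** 2
            power = amp2[0] + 2 * amp2[1:].sum()
            if n % 2 == 0:
                power -= amp2[-1]  # the Nyquist bin is not duplicated
            x = series - series.mean()
            assert power == pytest.approx(n * (x**2).sum(), rel=1e-6)


class TestSnr:
    def test_pure_tone_has_huge_snr(self):
        t = np.arange(130) / 13.0
        series = np.sin(2 * np.pi * 2.0 * t)
        stack, mask = _stack_from_series({(0, 0): series})
        spec = fb.pixel_spectra(stack, mask)
        assert spec.snr[0] > 1e6

    def test_flat_spectrum_is_one(self):
        amp = np.ones(20)
        assert snr_of_peak(amp, 5) == pytest.approx(1.0)

    def test_all_zero_spectrum_is_zero(self):
        assert snr_of_peak(np.zeros(20), 3) == 0.0

    def test_tone_plus_noise_matches_direct_formula(self):
        rng = np.random.default_rng(8)
        t = np.arange(130) / 13.0
        series = np.sin(2 * np.pi * 2.0 * t) + 0.1 * rng.standard_normal(130)
        stack, mask = _stack_from_series({(0, 0): series})
        spec = fb.pixel_spectra(stack, mask)
        # independent computation straight from the definition
        amp = np.abs(np.fft.rfft(series - series.mean()))
        peak = int(np.argmax(amp[1:])) + 1
        oracle = amp[peak] / np.delete(amp[1:], peak - 1).mean()
        assert spec.snr[0] == pytest.approx(oracle, rel=0.2)
        assert snr_of_peak(amp, peak) == pytest.approx(oracle)


class TestPeriodicMask:
    def _spec_with(self, freq_snr_map, shape=(8, 8)):
        t = np.arange(130) / 13.0
        rng = np.random.default_rng(0)
        series_map = {}
        for (r, c), (freq, noisy) in freq_snr_map.items():
            s = np.sin(2 * np.pi * freq * t)
            if noisy:
                # tone still dominant (in band) but buried enough that the
                # peak-to-background ratio drops to a few
                s = s + 2.0 * rng.standard_normal(130)
            series_map[(r, c)] = s
        stack, mask = _stack_from_series(series_map, shape=shape)
        return fb.pixel_spectra(stack, mask)

    def test_out_of_band_pixel_excluded(self):
        spec = self._spec_with({(0, 0): (0.3, False), (4, 4): (2.0, False)})
        pmask = fb.periodic_mask(spec, band_hz=(0.5, 5.0))
        assert pmask.mask[4, 4] and not pmask.mask[0, 0]

    def test_low_snr_pixel_excluded(self):
        spec = self._spec_with({(0, 0): (2.0, True), (4, 4): (2.0, False)})
        assert spec.snr[0] < 5.0 < spec.snr[1] if spec.coords[0, 0] == 0 else True
        pmask = fb.periodic_mask(spec, snr_range=(5.0, np.inf))
        assert pmask.mask[4, 4] and not pmask.mask[0, 0]

    def test_nothing_survives_is_no_periodic_region(self):
        spec = self._spec_with({(0, 0): (0.3, False)})
        with pytest.raises(fb.NoCallError) as err:
            fb.periodic_mask(spec)
        assert err.value.error_code == "no_periodic_region"

    def test_largest_component_selected(self):
        t = np.arange(130) / 13.0
        s = np.sin(2 * np.pi * 2.0 * t)
        big = {(r, c): s for r in range(0, 4) for c in range(0, 4)}
        small = {(r, c): s for r in range(6, 8) for c in range(6, 8)}
        stack, mask = _stack_from_series({**big, **small}, shape=(8, 8))
        spec = fb.pixel_spectra(stack, mask)
        pmask = fb.periodic_mask(spec)
        assert pmask.region_area == 16
        assert pmask.mask[0, 0] and not pmask.mask[7, 7]


class TestEstimateHeartRate:
    def _estimate(self, series_map, **kwargs):
        stack, mask = _stack_from_series(series_map)
        spec = fb.pixel_spectra(stack, mask)
        pmask = fb.periodic_mask(spec)
        return fb.estimate_heart_rate(spec, pmask, **kwargs)

    def test_shared_frequency_gives_exact_bpm(self):
        t = np.arange(130) / 13.0
        s = np.sin(2 * np.pi * 2.0 * t)
        series_map = {(r, c): s for r in range(3) for c in range(3)}
        est = self._estimate(series_map)
        assert est.bpm == 120.0
        assert est.n_pixels == 9

    def test_modal_component_wins(self):
        # 90% of pixels at 2.0 Hz, 10% at 4.0 Hz -> the mode, not the mean
        t = np.arange(130) / 13.0
        series_map = {}
        for i in range(10):
            freq = 4.0 if i == 0 else 2.0
            series_map[(i // 4, i % 4)] = np.sin(2 * np.pi * freq * t)
        est = self._estimate(series_map)
        assert est.bpm == pytest.approx(120.0)

    def test_amplitude_weighting_promotes_strong_minority(self):
        # 8 weak pixels at 2 Hz vs 2 strong ones at 4 Hz: the unweighted
        # mode follows the majority, the weighted mode the strong signal
        t = np.arange(130) / 13.0
        series_map = {}
        for i in range(10):
            strong = i < 2
            amp, freq = (10.0, 4.0) if strong else (0.1, 2.0)
            series_map[(i // 4, i % 4)] = amp * np.sin(2 * np.pi * freq * t)
        stack, mask = _stack_from_series(series_map)
        spec = fb.pixel_spectra(stack, mask)
        pmask = fb.periodic_mask(spec)
        assert fb.estimate_heart_rate(spec, pmask).bpm == pytest.approx(120.0)
        weighted = fb.estimate_heart_rate(spec, pmask, amplitude_weighted=True)
        assert weighted.bpm == pytest.approx(240.0)

    def test_band_contract(self):
        t = np.arange(130) / 13.0
        s = np.sin(2 * np.pi * 2.0 * t)
        est = self._estimate({(0, 0): s, (0, 1): s})
        assert 0.5 <= est.freq_hz <= 5.0
        assert est.bpm == pytest.approx(est.freq_hz * 60)


class TestPhaseMap:
    def _spec_with_phases(self, phases, freq=2.0):
        t = np.arange(130) / 13.0
        series_map = {
            (i // 12, i % 12): np.sin(2 * np.pi * freq * t + p)
            for i, p in enumerate(phases)
        }
        stack, mask = _stack_from_series(series_map, shape=(12, 12))
        spec = fb.pixel_spectra(stack, mask)
        pmask = fb.periodic_mask(spec)
        return spec, pmask

    def test_uniform_phase_is_one_cluster(self):
        spec, pmask = self._spec_with_phases([np.pi / 2] * 12)  # FT phase 0
        clusters, spread = phase_map(spec, pmask)
        assert len(clusters) == 1
        assert clusters[0][0] == pytest.approx(0.0, abs=1e-6)
        assert spread == 0.0

    def test_two_groups_pi_apart(self):
        phases = [0.0] * 24 + [np.pi] * 24
        spec, pmask = self._spec_with_phases(phases)
        clusters, spread = phase_map(spec, pmask)
        assert len(clusters) == 2
        assert spread == pytest.approx(np.pi, abs=0.05)
        assert clusters[0][1] == clusters[1][1] == 24

    def test_three_phase_groups_recovered(self):
        phases = [0.0] * 20 + [np.pi / 2] * 8 + [np.pi] * 20
        spec, pmask = self._spec_with_phases(phases)
        clusters, spread = phase_map(spec, pmask)
        assert len(clusters) == 3
        assert spread == pytest.approx(np.pi, abs=0.05)

    def test_circular_distance_wraps(self):
        assert circular_distance(3.0, -3.0) == pytest.approx(2 * np.pi - 6.0)
        assert circular_distance(0.5, 0.5) == 0.0
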