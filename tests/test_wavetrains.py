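"""Wave-train detection: maxima conditions, half-height measurement."""

import math

import numpy as np
import pytest

from wtea import DetectionParams, detect_wave_trains, find_local_maxima, \
    measure_wave_train
from wtea.cwt import Spectrogram, wavelet_half_height_bandwidth, wavelet_time_std
from wtea.types import Fragment

FS = 500.0


def synthetic_spectrogram(power, dt=0.01, df=0.5, f0=1.0):
    nf, nt = power.shape
    return Spectrogram(
        power=power.astype(float),
        phase=np.zeros_like(power, dtype=float),
        freqs=f0 + df * np.arange(nf),
        times=dt * np.arange(nt),
    )


def gaussian_bump(nf, nt, fi, ti, sf=3.0, st=10.0, amp=100.0):
    f = np.arange(nf)[:, None]
    t = np.arange(nt)[None, :]
    return amp * np.exp(-0.5 * ((f - fi) / sf) ** 2 - 0.5 * ((t - ti) / st) ** 2)


class TestFindLocalMaxima:
    def test_all_zero_spectrogram_empty(self):
        spec = synthetic_spectrogram(np.zeros((20, 50)))
        assert find_local_maxima(spec, floor=0.0) == []

    def test_single_bump_single_maximum(self):
        """Exhaustive-scan oracle: the only maximum is the global one."""
        power = gaussian_bump(40, 200, fi=14, ti=100)
        spec = synthetic_spectrogram(power)
        peaks = find_local_maxima(spec, floor=1.0)
        assert peaks == [(14, 100)]
        assert peaks[0] == np.unravel_index(np.argmax(power), power.shape)

    def test_two_separated_bumps_two_maxima(self):
        power = gaussian_bump(40, 900, fi=10, ti=200) + \
            gaussian_bump(40, 900, fi=25, ti=600, amp=80.0)
        spec = synthetic_spectrogram(power)
        peaks = find_local_maxima(spec, floor=1.0)
        assert len(peaks) == 2
        assert set(peaks) == {(10, 200), (25, 600)}

    def test_floor_excludes_weak_maxima(self):
        power = gaussian_bump(40, 900, fi=10, ti=200) + \
            gaussian_bump(40, 900, fi=25, ti=600, amp=10.0)
        spec = synthetic_spectrogram(power)
        assert len(find_local_maxima(spec, floor=50.0)) == 1

    def test_coi_exclusion(self):
        power = gaussian_bump(40, 200, fi=14, ti=100)
        spec = synthetic_spectrogram(power)
        spec.coi[:] = True
        assert find_local_maxima(spec, floor=0.0) == []


class TestMeasureWaveTrain:
    def test_gaussian_burst_characteristics(self):
        """Half-height duration matches the Gaussian x wavelet closed form."""
        t = np.arange(0, 10, 1 / FS)
        sigma_env = 0.25
        x = 100 * np.exp(-0.5 * ((t - 5) / sigma_env) ** 2) * np.cos(2 * np.pi * 8 * (t - 5))
        trains = detect_wave_trains(Fragment(x, FS, id="burst"),
                                    DetectionParams(floor=1.0))
        assert len(trains) == 1
        wt = trains[0]
        assert wt.central_frequency == pytest.approx(8.0, abs=0.2)
        sigma_conv = math.sqrt(sigma_env ** 2 + wavelet_time_std(8.0) ** 2)
        analytic_fwhm = 2 * sigma_conv * math.sqrt(math.log(2))
        assert wt.duration_s == pytest.approx(analytic_fwhm, rel=0.15)
        assert wt.duration_periods == pytest.approx(wt.duration_s * wt.central_frequency)
        assert wt.phase == pytest.approx(0.0, abs=0.1)
        assert wt.peak_time == pytest.approx(5.0, abs=0.05)

    def test_stationary_tone_bandwidth_is_wavelet_limited(self):
        t = np.arange(0, 12, 1 / FS)
        x = 100 * np.cos(2 * np.pi * 8 * t)
        trains = detect_wave_trains(Fragment(x, FS, id="tone"),
                                    DetectionParams(floor=1.0, include_truncated=True))
        wt = max(trains, key=lambda w: w.max_psd)
        assert wt.bandwidth == pytest.approx(wavelet_half_height_bandwidth(8.0), rel=0.1)
        assert wt.duration_s > 10.0   # ridge spans nearly the whole fragment

    def test_border_peak_flagged(self):
        power = gaussian_bump(40, 100, fi=0, ti=50)   # peak on frequency border
        spec = synthetic_spectrogram(power)
        wt = measure_wave_train(spec, (0, 50))
        assert wt.truncated


class TestDetectWaveTrains:
    def test_two_tone_bursts_recovered(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.zeros_like(t)
        for c, f in ((4.0, 6.0), (6.0, 12.0)):
            x += 100 * np.exp(-0.5 * ((t - c) / 0.3) ** 2) * np.cos(2 * np.pi * f * (t - c))
        trains = detect_wave_trains(Fragment(x, FS, id="two"), DetectionParams(floor=1.0))
        freqs = sorted(w.central_frequency for w in trains)
        assert len(trains) == 2
        assert freqs[0] == pytest.approx(6.0, abs=0.3)
        assert freqs[1] == pytest.approx(12.0, abs=0.3)

    def test_noise_produces_wave_trains(self, gen_cfg):
        from wtea import gen_background
        frag = gen_background(10, gen_cfg)
        assert len(detect_wave_trains(frag)) >= 1

    def test_zero_signal_empty(self):
        frag = Fragment(np.zeros(5000), FS, id="z")
        assert detect_wave_trains(frag) == []

    def test_amplitude_equivariance(self, gen_cfg):
        """Scaling input by c scales max_psd by c^2, all else unchanged."""
        from wtea import gen_background
        frag = gen_background(8, gen_cfg)
        base = detect_wave_trains(frag, DetectionParams(floor=500.0))
        scaled = detect_wave_trains(frag.with_samples(3.0 * frag.samples),
                                    DetectionParams(floor=9 * 500.0))
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert b.max_psd == pytest.approx(9.0 * a.max_psd, rel=1e-6)
            assert b.central_frequency == a.central_frequency
            assert b.peak_time == a.peak_time
            assert b.duration_s == a.duration_s
            assert b.bandwidth == a.bandwidth
            assert b.phase == pytest.approx(a.phase, abs=1e-9)

    def test_detection_is_deterministic(self, gen_cfg):
        from wtea import gen_background
        frag = gen_background(6, gen_cfg)
        assert detect_wave_trains(frag) == detect_wave_trains(frag)

    def test_dedupe_keeps_stronger_of_overlapping_peaks(self, make_train):
        from wtea.wavetrains import _dedupe
        strong = make_train(central_frequency=10.0, max_psd=100.0, peak_time=1.0,
                            duration_s=0.4, bandwidth=3.0)
        weak = make_train(central_frequency=10.4, max_psd=50.0, peak_time=1.05,
                          duration_s=0.4, bandwidth=3.0)
        far = make_train(central_frequency=30.0, max_psd=40.0, peak_time=5.0)
        kept = _dedupe([strong, weak, far], threshold=0.5)
        assert strong in kept and far in kept and weak not in kept
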