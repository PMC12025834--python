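"""Wave-train detection: local spectrogram maxima and their six characteristics.

A wave train is a local maximum of the wavelet power spectrogram together
with its half-height time and frequency extents.  The six characteristics
are: central frequency (Hz), maximum PSD (uV^2/Hz), duration at half
height in seconds and in periods, bandwidth at half height (Hz), and the
instantaneous phase at the peak (radians).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as _ndimage

from .cwt import Spectrogram, cwt_spectrogram, default_freq_grid
from .types import Fragment, WaveTrain

__all__ = ["DetectionParams", "find_local_maxima", "measure_wave_train",
           "detect_wave_trains", "median_power_floor"]


@dataclass(frozen=True)
class DetectionParams:
    """Knobs reconstructing the conditions a candidate maximum must meet.

    floor : absolute power floor in uV^2/Hz, or None to derive one as
        ``floor_factor`` times the median spectrogram power (of the fragment
        for single-fragment detection; of the pooled dataset in the group
        pipeline, which preserves between-group count differences).
    floor_factor : multiplier for the median-based floor.
    overlap_dedupe : drop the weaker of two maxima whose half-height boxes
        overlap by at least ``overlap_threshold`` (intersection / smaller).
    include_truncated : keep trains whose half-height run hits the fragment
        edge (they are flagged; excluded from characteristic-space searches
        by default).
    """

    floor: float | None = None
    floor_factor: float = 5.0
    overlap_dedupe: bool = True
    overlap_threshold: float = 0.5
    include_truncated: bool = False


def median_power_floor(spectrograms, floor_factor: float = 5.0) -> float:
    """Power floor = factor x median power pooled over one or more spectrograms."""
    if isinstance(spectrograms, Spectrogram):
        spectrograms = [spectrograms]
    med = np.median(np.concatenate([s.power.ravel() for s in spectrograms]))
    return floor_factor * float(med)


def find_local_maxima(spec: Spectrogram, floor: float = 0.0) -> list[tuple[int, int]]:
    """Grid points strictly greater than all 8 neighbours and >= floor.

    Points inside the cone of influence are excluded.  Returns (frequency
    index, time index) pairs ordered by descending power.
    """
    p = spec.power
    if p.size == 0:
        raise ValueError("empty spectrogram")
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = _ndimage.maximum_filter(p, footprint=footprint, mode="constant", cval=-np.inf)
    is_max = (p > neigh_max) & (p >= floor) & ~spec.coi
    fi, ti = np.nonzero(is_max)
    order = np.argsort(p[fi, ti])[::-1]
    return [(int(fi[k]), int(ti[k])) for k in order]


def _half_height_run(values: np.ndarray, peak_idx: int, half: float) -> tuple[int, int, bool]:
    """Contiguous run of indices around peak_idx with values >= half.

    Returns (lo, hi) inclusive and whether the run hit either border.
    """
    lo = peak_idx
    while lo > 0 and values[lo - 1] >= half:
        lo -= 1
    hi = peak_idx
    n = values.size
    while hi < n - 1 and values[hi + 1] >= half:
        hi += 1
    truncated = (lo == 0 and values[0] >= half) or (hi == n - 1 and values[n - 1] >= half)
    return lo, hi, truncated


def measure_wave_train(spec: Spectrogram, peak: tuple[int, int],
                       fragment_id: str = "") -> WaveTrain:
    """Measure the six characteristics of the wave train peaking at *peak*.

    Half-height extents are one-dimensional runs along the peak's frequency
    row (duration) and time column (bandwidth); a run that reaches the
    matrix border is measured one-sided and the train flagged truncated.
    """
    fi, ti = peak
    p0 = float(spec.power[fi, ti])
    if p0 <= 0:
        raise ValueError("peak power must be positive")
    half = p0 / 2.0

    row = spec.power[fi, :]
    t_lo, t_hi, t_trunc = _half_height_run(row, ti, half)
    col = spec.power[:, ti]
    f_lo, f_hi, f_trunc = _half_height_run(col, fi, half)

    dt = spec.dt if spec.dt > 0 else 1.0 / max(spec.times.size, 1)
    df = spec.df if spec.df > 0 else 1.0

    central = float(spec.freqs[fi])
    duration_s = (t_hi - t_lo + 1) * dt
    bandwidth = (f_hi - f_lo + 1) * df
    return WaveTrain(
        peak_time=float(spec.times[ti]),
        central_frequency=central,
        max_psd=p0,
        duration_s=duration_s,
        duration_periods=duration_s * central,
        bandwidth=bandwidth,
        phase=float(spec.phase[fi, ti]),
        fragment_id=fragment_id,
        truncated=bool(t_trunc or f_trunc),
    )


def _overlap_fraction(a: WaveTrain, b: WaveTrain) -> float:
    """Intersection of half-height boxes over the smaller box area."""
    t_lo = max(a.peak_time - a.duration_s / 2, b.peak_time - b.duration_s / 2)
    t_hi = min(a.peak_time + a.duration_s / 2, b.peak_time + b.duration_s / 2)
    f_lo = max(a.central_frequency - a.bandwidth / 2, b.central_frequency - b.bandwidth / 2)
    f_hi = min(a.central_frequency + a.bandwidth / 2, b.central_frequency + b.bandwidth / 2)
    if t_hi <= t_lo or f_hi <= f_lo:
        return 0.0
    inter = (t_hi - t_lo) * (f_hi - f_lo)
    smaller = min(a.duration_s * a.bandwidth, b.duration_s * b.bandwidth)
    return inter / smaller if smaller > 0 else 0.0


def _dedupe(trains: list[WaveTrain], threshold: float) -> list[WaveTrain]:
    """Keep the higher-power train of any pair overlapping >= threshold.

    Input must be ordered by descending max_psd.
    """
    kept: list[WaveTrain] = []
    for t in trains:
        if all(_overlap_fraction(t, k) < threshold for k in kept):
            kept.append(t)
    return kept


def detect_wave_trains(
    fragment: Fragment,
    params: DetectionParams = DetectionParams(),
    freqs: np.ndarray | None = None,
    spec: Spectrogram | None = None,
) -> list[WaveTrain]:
    """Full chain: spectrogram -> local maxima -> dedupe -> measurement.

    A precomputed spectrogram may be passed to avoid recomputation.  Trains
    are returned ordered by descending max_psd.
    """
    if spec is None:
        spec = cwt_spectrogram(fragment, freqs if freqs is not None else default_freq_grid())
    if not np.any(spec.power > 0):
        return []
    floor = params.floor
    if floor is None:
        floor = median_power_floor(spec, params.floor_factor)
    peaks = find_local_maxima(spec, floor=floor)
    trains = [measure_wave_train(spec, p, fragment_id=fragment.id) for p in peaks]
    if params.overlap_dedupe:
        trains = _dedupe(trains, params.overlap_threshold)
    if not params.include_truncated:
        trains = [t for t in trains if not t.truncated]
    return trains
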