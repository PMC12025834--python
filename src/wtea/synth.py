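"""Synthetic single-channel EEG emulating the four fragment classes.

The generator produces labeled fragments of the signal classes analyzed in
the WAG/Rij absence-epilepsy model:

* ``background`` — 1/f-type broadband noise, band-limited 0.1-120 Hz;
* ``mature`` — spike-and-wave discharges (SWD): sharp, asymmetric,
  high-amplitude spike-wave complexes lasting > 2 s, starting at 11-12 Hz
  and chirping down to a stable 7-8 Hz within ~0.5 s, with a harmonic
  Fourier structure;
* ``immature`` — precursor discharges: irregular, nearly symmetric
  spike-wave sequences at an unstable (random-walk) cycle frequency, lower
  amplitude, no harmonic structure;
* ``spindle`` — 7-14 Hz waxing-waning wave packets of roughly twice the
  background amplitude, with occasional sharp-wave insertions.

During any event the broadband background is attenuated by a configurable
factor, emulating the event-locked suppression of noise-type activity that
makes broadband ("blue") wave trains rarer inside discharges than in the
background EEG.

Amplitude convention: amplitude ratios are stated as seen by an expert on
the trace, i.e. relative to the visual peak excursion of the background.
Events are therefore scaled so that their peak-to-peak amplitude equals
``ratio * 2 * PEAK_FACTOR * background_rms``, where ``PEAK_FACTOR`` = 3.5
approximates the peak/RMS ratio of Gaussian noise over a few-second
window.  This satisfies the peak-to-peak ratios and the RMS ordering
background < spindle ~ immature < mature simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import fft as _fft

from .types import Fragment

__all__ = [
    "GenConfig",
    "PEAK_FACTOR",
    "gen_background",
    "gen_mature_swd",
    "gen_immature_discharge",
    "gen_sleep_spindle",
    "gen_dataset",
]

#: Typical peak/RMS excursion factor of band-limited Gaussian noise over a
#: few-second window; converts the paper's visual amplitude ratios to an
#: event scaling.
PEAK_FACTOR = 3.5


@dataclass(frozen=True)
class GenConfig:
    """Generator parameters; defaults reproduce the documented morphology.

    All amplitudes are in uV, frequencies in Hz, durations in seconds.
    ``background_rms`` sets the absolute scale: 200 uV places the
    calibrated wavelet PSD of immature-discharge wave trains above the
    50,000 uV^2/Hz criterion and background noise maxima safely below it
    (see docs/methods.md for the calibration argument).
    """

    sampling_rate: float = 500.0
    background_rms: float = 200.0
    background_slope: float = 1.0           # 1/f^alpha spectral exponent
    background_band: tuple[float, float] = (0.1, 120.0)
    swd_amp_ratio: float = 3.0
    spindle_amp_ratio: float = 2.0
    immature_amp_ratio: float = 2.2
    swd_onset_freq: float = 11.5
    swd_stable_freq: float = 7.5
    swd_chirp_time: float = 0.5
    swd_asymmetry: float = 1.8              # spike/wave amplitude ratio (mature)
    immature_asymmetry: float = 0.7         # nearly symmetric spikes
    immature_freq_band: tuple[float, float] = (5.5, 8.5)
    immature_freq_step: float = 0.6         # per-cycle random-walk step, Hz
    immature_skip_prob: float = 0.3         # chance a cycle lacks its spike
    immature_spike_width: float = 0.12      # cycle fraction; blunter than mature
    spindle_band: tuple[float, float] = (7.0, 14.0)
    spindle_freq_step: float = 0.8
    spindle_sharp_rate: float = 0.5         # sharp waves per second
    event_background_attenuation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        hi = max(self.background_band[1], self.swd_onset_freq, self.spindle_band[1])
        if self.sampling_rate <= 2 * hi:
            raise ValueError("sampling_rate must exceed twice the highest generated frequency")
        for name in ("swd_amp_ratio", "spindle_amp_ratio", "immature_amp_ratio",
                     "background_rms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.event_background_attenuation <= 1.0:
            raise ValueError("event_background_attenuation must lie in [0, 1]")

    def child(self, stream: int) -> "GenConfig":
        """Config with a counter-derived seed, for independent fragments."""
        mixed = int(np.random.SeedSequence([self.seed, stream]).generate_state(1)[0] % (2 ** 31))
        return replace(self, seed=mixed)


def _rng(cfg: GenConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def _check_duration(duration: float) -> int:
    if duration <= 0:
        raise ValueError("duration must be positive")
    return 1


def _background_noise(n: int, cfg: GenConfig, rng: np.random.Generator) -> np.ndarray:
    """Spectrally shaped (1/f^alpha) Gaussian noise, exact-RMS normalized."""
    rate = cfg.sampling_rate
    white = rng.standard_normal(n)
    spec = _fft.rfft(white)
    f = _fft.rfftfreq(n, 1.0 / rate)
    lo, hi = cfg.background_band
    shape = np.zeros_like(f)
    inside = (f >= lo) & (f <= hi)
    shape[inside] = f[inside] ** (-cfg.background_slope / 2.0)
    x = _fft.irfft(spec * shape, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x * (cfg.background_rms / rms)


def _spike_wave_cycles(
    n: int,
    cfg: GenConfig,
    rng: np.random.Generator,
    freq_fn,
    asymmetry: float,
    spike_jitter: float = 0.0,
    skip_prob: float = 0.0,
    spike_width: float = 0.045,
) -> np.ndarray:
    """Phase-accumulated spike-wave train.

    One cycle = a slow half-wave (sine fundamental) plus a sharp biphasic
    spike (Gaussian derivative) at a fixed phase; ``asymmetry`` is the
    spike/wave amplitude ratio.  ``freq_fn(t, cycle_index)`` supplies the
    instantaneous cycle frequency.
    """
    rate = cfg.sampling_rate
    t = np.arange(n) / rate
    # Instantaneous frequency is piecewise per cycle; accumulate phase.
    phase = np.empty(n)
    freq = np.empty(n)
    ph = 0.0
    cycle = 0
    for i in range(n):
        f = freq_fn(t[i], cycle)
        freq[i] = f
        phase[i] = ph
        ph += f / rate
        if ph >= cycle + 1:
            cycle += 1
    wave = np.sin(2 * np.pi * phase)

    # Spikes: one per cycle at phase 0.25 (on the rising wave), width a
    # fixed fraction of the cycle.
    spikes = np.zeros(n)
    frac = np.mod(phase, 1.0)
    cyc_idx = np.floor(phase).astype(int)
    n_cycles = cyc_idx.max() + 1 if n else 0
    amp = np.ones(n_cycles)
    if skip_prob > 0:
        amp *= rng.random(n_cycles) >= skip_prob
    if spike_jitter > 0:
        amp *= 1.0 + spike_jitter * rng.standard_normal(n_cycles)
    center = 0.25 + (spike_jitter * rng.standard_normal(n_cycles) * 0.1
                     if spike_jitter > 0 else np.zeros(n_cycles))
    width = spike_width  # in cycle-phase units
    d = frac - center[cyc_idx]
    g = d / width
    spikes = amp[cyc_idx] * (-g) * np.exp(0.5) * np.exp(-0.5 * g * g)  # unit-peak derivative-of-Gaussian
    return wave + asymmetry * spikes


def _scale_event(event: np.ndarray, ratio: float, cfg: GenConfig) -> np.ndarray:
    # Match peak-to-peak excursions: background noise spans ~2*PEAK_FACTOR*rms.
    p2p = float(event.max() - event.min())
    if p2p == 0:
        return event
    return event * (ratio * 2.0 * PEAK_FACTOR * cfg.background_rms / p2p)


def _compose(event: np.ndarray, cfg: GenConfig, rng: np.random.Generator,
             label: str, rate: float, frag_id: str) -> Fragment:
    bg = _background_noise(event.size, cfg, rng)
    atten = cfg.event_background_attenuation
    samples = event + atten * bg
    return Fragment(samples=samples, sampling_rate=rate, label=label, id=frag_id,
                    parts={"event": event, "background": atten * bg})


def gen_background(duration: float, cfg: GenConfig = GenConfig(),
                   frag_id: str = "background") -> Fragment:
    """Background EEG: band-limited 1/f^alpha noise with the configured RMS."""
    _check_duration(duration)
    n = int(round(duration * cfg.sampling_rate))
    rng = _rng(cfg)
    x = _background_noise(n, cfg, rng)
    return Fragment(samples=x, sampling_rate=cfg.sampling_rate, label="background",
                    id=frag_id, parts={"event": np.zeros(n), "background": x})


def gen_mature_swd(duration: float, cfg: GenConfig = GenConfig(),
                   frag_id: str = "mature") -> Fragment:
    """Mature SWD: asymmetric spike-wave train with an 11-12 -> 7-8 Hz chirp.

    Requires duration > 2 s (the defining criterion of a mature discharge).
    """
    if duration <= 2:
        raise ValueError("a mature SWD lasts more than 2 s")
    n = int(round(duration * cfg.sampling_rate))
    rng = _rng(cfg)

    f0, f1, tau = cfg.swd_onset_freq, cfg.swd_stable_freq, cfg.swd_chirp_time
    jitter = 0.1 * rng.standard_normal(int(duration * f0) + 8)

    def freq(t, cycle):
        base = f1 + (f0 - f1) * np.exp(-3.0 * t / tau)
        return base + jitter[min(cycle, jitter.size - 1)]

    ev = _spike_wave_cycles(n, cfg, rng, freq, cfg.swd_asymmetry, spike_jitter=0.05)
    ev = _scale_event(ev, cfg.swd_amp_ratio, cfg)
    return _compose(ev, cfg, rng, "mature", cfg.sampling_rate, frag_id)


def gen_immature_discharge(duration: float, cfg: GenConfig = GenConfig(),
                           frag_id: str = "immature") -> Fragment:
    """Immature discharge: irregular, nearly symmetric spike-wave sequence.

    The cycle frequency performs a reflected random walk inside
    ``cfg.immature_freq_band`` (no stable fundamental, hence no harmonic
    peaks); a fraction of cycles lack their spike, leaving plain wave-like
    oscillations in between.
    """
    _check_duration(duration)
    n = int(round(duration * cfg.sampling_rate))
    rng = _rng(cfg)

    lo, hi = cfg.immature_freq_band
    n_cycles = int(duration * hi) + 8
    steps = rng.uniform(-cfg.immature_freq_step, cfg.immature_freq_step, n_cycles)
    f = np.empty(n_cycles)
    f[0] = rng.uniform(lo, hi)
    for k in range(1, n_cycles):
        nxt = f[k - 1] + steps[k]
        # reflect at the band edges
        if nxt > hi:
            nxt = 2 * hi - nxt
        elif nxt < lo:
            nxt = 2 * lo - nxt
        f[k] = min(max(nxt, lo), hi)

    def freq(t, cycle):
        return f[min(cycle, n_cycles - 1)]

    ev = _spike_wave_cycles(n, cfg, rng, freq, cfg.immature_asymmetry,
                            spike_jitter=0.25, skip_prob=cfg.immature_skip_prob,
                            spike_width=cfg.immature_spike_width)
    # Mild amplitude irregularity from cycle to cycle.
    env = 1.0 + 0.15 * np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * np.arange(n) / cfg.sampling_rate
                              + rng.uniform(0, 2 * np.pi))
    ev = _scale_event(ev * env, cfg.immature_amp_ratio, cfg)
    return _compose(ev, cfg, rng, "immature", cfg.sampling_rate, frag_id)


def gen_sleep_spindle(duration: float, cfg: GenConfig = GenConfig(),
                      frag_id: str = "spindle") -> Fragment:
    """Sleep spindle: waxing-waning 7-14 Hz packet with occasional sharp waves."""
    _check_duration(duration)
    n = int(round(duration * cfg.sampling_rate))
    rng = _rng(cfg)
    rate = cfg.sampling_rate
    t = np.arange(n) / rate

    lo, hi = cfg.spindle_band
    n_cycles = int(duration * hi) + 8
    f = np.empty(n_cycles)
    f[0] = rng.uniform(lo + 1, hi - 1)
    steps = rng.uniform(-cfg.spindle_freq_step, cfg.spindle_freq_step, n_cycles)
    for k in range(1, n_cycles):
        nxt = f[k - 1] + steps[k]
        if nxt > hi:
            nxt = 2 * hi - nxt
        elif nxt < lo:
            nxt = 2 * lo - nxt
        f[k] = min(max(nxt, lo), hi)

    phase = np.empty(n)
    ph = 0.0
    cycle = 0
    for i in range(n):
        phase[i] = ph
        ph += f[min(cycle, n_cycles - 1)] / rate
        if ph >= cycle + 1:
            cycle += 1
    carrier = np.sin(2 * np.pi * phase)

    # Waxing-waning envelope: Hann bump over the fragment (symmetric packet).
    env = np.sin(np.pi * np.clip(t / duration, 0, 1)) ** 2
    ev = carrier * env

    # Occasional small sharp waves riding on the packet.
    n_sharp = rng.poisson(cfg.spindle_sharp_rate * duration)
    sharp = np.zeros(n)
    for _ in range(n_sharp):
        c = rng.uniform(0.15, 0.85) * duration
        w = 0.02  # s
        g = (t - c) / w
        sharp += 0.5 * (-g) * np.exp(0.5) * np.exp(-0.5 * g * g)
    ev = ev + sharp * env
    ev = _scale_event(ev, cfg.spindle_amp_ratio, cfg)
    return _compose(ev, cfg, rng, "spindle", cfg.sampling_rate, frag_id)


_GENERATORS = {
    "background": gen_background,
    "mature": gen_mature_swd,
    "immature": gen_immature_discharge,
    "spindle": gen_sleep_spindle,
}


def gen_dataset(
    n_per_class: dict[str, int],
    durations: dict[str, float] | float = 8.0,
    cfg: GenConfig = GenConfig(),
) -> tuple[list[Fragment], pd.DataFrame]:
    """Generate an annotated set of independent fragments.

    Parameters
    ----------
    n_per_class : mapping class name -> count (>= 1)
    durations : seconds per class (scalar, mapping, or mapping to (lo, hi)
        ranges sampled per fragment)
    cfg : master config; per-fragment seeds are derived with a counter-based
        scheme so the dataset is a pure function of (cfg, seed) and fragments
        are independent.

    Returns the fragments and an annotation table (id, label, start_s,
    duration_s).
    """
    for name, cnt in n_per_class.items():
        if name not in _GENERATORS:
            raise ValueError(f"unknown class {name!r}; expected one of {sorted(_GENERATORS)}")
        if cnt < 1:
            raise ValueError(f"need at least one fragment of class {name!r}")

    dur_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xD0]).generate_state(1))
    fragments: list[Fragment] = []
    rows = []
    stream = 1
    for name in sorted(n_per_class):
        for k in range(n_per_class[name]):
            if isinstance(durations, dict):
                d = durations[name]
            else:
                d = durations
            if isinstance(d, (tuple, list)):
                d = float(dur_rng.uniform(d[0], d[1]))
            frag_id = f"{name}_{k:02d}"
            sub = cfg.child(stream)
            stream += 1
            frag = _GENERATORS[name](d, sub, frag_id=frag_id)
            fragments.append(frag)
            rows.append({"id": frag_id, "label": name, "start_s": 0.0,
                         "duration_s": frag.duration})
    table = pd.DataFrame(rows, columns=["id", "label", "start_s", "duration_s"])
    return fragments, table
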