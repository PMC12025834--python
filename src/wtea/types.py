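"""Core value types shared across the wave-train analysis pipeline.

A :class:`Fragment` is a labeled, contiguous stretch of single-channel EEG —
the unit on which groups are compared.  A :class:`WaveTrain` is one detected
spectrogram event together with its six characteristics.  A
:class:`ConstraintBox` is a set of per-characteristic min/max bounds selecting
a subspace of wave-train space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

#: The four fragment classes.
LABELS = ("background", "mature", "immature", "spindle")

#: The six wave-train characteristics, in canonical order.
CHARACTERISTICS = (
    "central_frequency",
    "max_psd",
    "duration_s",
    "duration_periods",
    "bandwidth",
    "phase",
)


@dataclass
class Fragment:
    """A labeled contiguous EEG segment.

    Parameters
    ----------
    samples : ndarray
        Signal amplitudes in microvolts.
    sampling_rate : float
        Samples per second.
    label : str
        One of ``background``, ``mature``, ``immature``, ``spindle``.
    start_time : float
        Offset in seconds within the parent recording (0 if standalone).
    id : str
        Fragment identifier.
    parts : dict, optional
        Named additive components of the signal (e.g. ``"event"``,
        ``"background"``) kept by the synthetic generator for diagnostics.
    """

    samples: np.ndarray
    sampling_rate: float
    label: str = "background"
    start_time: float = 0.0
    id: str = ""
    parts: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("fragment samples must be a nonempty 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")

    @property
    def duration(self) -> float:
        """Fragment duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "Fragment":
        """Return a copy carrying *samples* and the same metadata."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class WaveTrain:
    """One detected spectrogram event and its six characteristics.

    ``duration_periods`` equals ``duration_s * central_frequency`` by
    construction; half-height extents are one-dimensional runs along the
    peak's spectrogram row (time) and column (frequency).
    """

    peak_time: float
    central_frequency: float
    max_psd: float
    duration_s: float
    duration_periods: float
    bandwidth: float
    phase: float
    fragment_id: str = ""
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.bandwidth <= 0 or self.max_psd <= 0:
            raise ValueError("duration_s, bandwidth and max_psd must be positive")
        if not (-math.pi < self.phase <= math.pi + 1e-12):
            raise ValueError("phase must lie in (-pi, pi]")
        if not math.isclose(
            self.duration_periods, self.duration_s * self.central_frequency,
            rel_tol=1e-9, abs_tol=1e-12,
        ):
            raise ValueError("duration_periods must equal duration_s * central_frequency")

    def characteristic(self, name: str) -> float:
        if name not in CHARACTERISTICS:
            raise KeyError(f"unknown characteristic {name!r}")
        return getattr(self, name)


def trains_to_array(trains: Iterable[WaveTrain]) -> np.ndarray:
    """Stack wave trains into an (n, 6) array in canonical characteristic order."""
    rows = [[t.characteristic(c) for c in CHARACTERISTICS] for t in trains]
    if not rows:
        return np.empty((0, len(CHARACTERISTICS)))
    return np.asarray(rows, dtype=float)


class ConstraintBox(Mapping):
    """Per-characteristic [min, max] bounds defining a subspace of wave trains.

    Absent bounds are unbounded; membership is inclusive on both ends.
    Behaves as a read-only mapping from characteristic name to ``(lo, hi)``
    with ``None`` for an absent bound.
    """

    __slots__ = ("_bounds",)

    def __init__(self, **bounds):
        clean: dict[str, tuple[float | None, float | None]] = {}
        for name, bnd in bounds.items():
            if name not in CHARACTERISTICS:
                raise KeyError(f"unknown characteristic {name!r}")
            if bnd is None:
                continue
            lo, hi = bnd
            lo = None if lo is None else float(lo)
            hi = None if hi is None else float(hi)
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
            if name == "phase":
                for v in (lo, hi):
                    if v is not None and not (-math.pi - 1e-9 <= v <= math.pi + 1e-9):
                        raise ValueError("phase bounds must lie within [-pi, pi]")
            if lo is not None or hi is not None:
                clean[name] = (lo, hi)
        self._bounds = clean

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, name):
        if name not in CHARACTERISTICS:
            raise KeyError(name)
        return self._bounds.get(name, (None, None))

    def __iter__(self):
        return iter(self._bounds)

    def __len__(self):
        return len(self._bounds)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v}" for k, v in self._bounds.items())
        return f"ConstraintBox({inner})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ConstraintBox) and self._bounds == other._bounds

    def __hash__(self):
        return hash(tuple(sorted(self._bounds.items())))

    # Behaviour -------------------------------------------------------------
    def contains(self, train: WaveTrain) -> bool:
        """True if *train* satisfies every bound (inclusive)."""
        for name, (lo, hi) in self._bounds.items():
            v = train.characteristic(name)
            if lo is not None and v < lo:
                return False
            if hi is not None and v > hi:
                return False
        return True

    def mask(self, values: np.ndarray) -> np.ndarray:
        """Vectorized membership for an (n, 6) canonical characteristic array."""
        values = np.asarray(values, dtype=float)
        keep = np.ones(values.shape[0], dtype=bool)
        for name, (lo, hi) in self._bounds.items():
            col = values[:, CHARACTERISTICS.index(name)]
            if lo is not None:
                keep &= col >= lo
            if hi is not None:
                keep &= col <= hi
        return keep

    def filter(self, trains: list[WaveTrain]) -> list[WaveTrain]:
        return [t for t in trains if self.contains(t)]

    def to_dict(self) -> dict:
        """JSON-friendly representation (only the present bounds)."""
        return {k: list(v) for k, v in self._bounds.items()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConstraintBox":
        return cls(**{k: tuple(v) for k, v in d.items()})
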