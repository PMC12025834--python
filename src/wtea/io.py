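"""Readers and writers: signals, annotations, wave-train tables, configs.

Conventions fixed here: times in seconds from recording start, intervals
half-open ``[start, start + duration)``, sample indices 0-based.  The
delimited signal format is two columns ``time_s, amplitude_uV`` with a
header; EDF files are read through mne when available.  Analysis is
single-channel (pick with ``channel=``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LABELS, Fragment, WaveTrain

__all__ = [
    "Recording", "read_signal", "write_signal_delimited",
    "read_annotations", "write_annotations", "cut_fragments",
    "write_wavetrains", "read_wavetrains",
    "load_config", "save_config", "write_manifest",
]

_WT_COLUMNS = [
    "fragment_id", "peak_time_s", "central_frequency_hz", "max_psd_uv2hz",
    "duration_s", "duration_periods", "bandwidth_hz", "phase_rad", "truncated",
]


@dataclass
class Recording:
    """Multi-channel signal in uV with uniform sampling."""

    samples: np.ndarray            # (n_channels, n_samples)
    sampling_rate: float
    channels: list[str]
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel labels inconsistent with sample matrix")

    def channel(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            if name_or_index not in self.channels:
                raise KeyError(f"no channel {name_or_index!r}; have {self.channels}")
            return self.samples[self.channels.index(name_or_index)]
        return self.samples[int(name_or_index)]


def read_signal(path, format: str | None = None) -> Recording:
    """Read a recording from delimited text or EDF.

    The format is inferred from the suffix when not given.  Delimited files
    must have a header row ``time_s,amplitude_uV`` (separator comma, tab or
    whitespace); EDF physical-dimension scaling is applied by the reader.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited(path)
    raise ValueError(f"unknown signal format {format!r}")


def _read_delimited(path: Path) -> Recording:
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in table.columns]
    if len(cols) < 2 or "time" not in cols[0]:
        raise ValueError(
            f"{path}: expected header 'time_s, amplitude_uV', got {list(table.columns)}")
    if "uv" not in cols[1].replace("_", ""):
        import warnings
        warnings.warn(f"{path}: amplitude column {table.columns[1]!r} does not "
                      "declare uV units; passing values through unscaled")
    t = table.iloc[:, 0].to_numpy(dtype=float)
    x = table.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time column is not uniformly increasing "
                         f"(first bad record near line {int(np.argmax(dt <= 0)) + 2})")
    return Recording(samples=x[None, :], sampling_rate=1.0 / dt[0],
                     channels=["ch0"], source=str(path))


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts
    return Recording(samples=data * 1e6, sampling_rate=float(raw.info["sfreq"]),
                     channels=list(raw.ch_names), source=str(path))


def write_signal_delimited(fragment_or_samples, path, sampling_rate: float | None = None) -> None:
    """Write a single-channel signal as ``time_s,amplitude_uV`` text."""
    if isinstance(fragment_or_samples, Fragment):
        x = fragment_or_samples.samples
        rate = fragment_or_samples.sampling_rate
    else:
        x = np.asarray(fragment_or_samples, dtype=float)
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
        rate = sampling_rate
    t = np.arange(x.size) / rate
    pd.DataFrame({"time_s": t, "amplitude_uV": x}).to_csv(path, index=False)


def read_annotations(path) -> pd.DataFrame:
    """Annotation table: id, label, start_s, duration_s[, channel]."""
    table = pd.read_csv(path)
    required = {"id", "label", "start_s", "duration_s"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    bad = ~table.label.isin(LABELS)
    if bad.any():
        raise ValueError(f"{path}: unknown labels {sorted(table.label[bad].unique())}")
    if (table.duration_s <= 0).any():
        raise ValueError(f"{path}: durations must be positive")
    return table


def write_annotations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def cut_fragments(rec: Recording, annot: pd.DataFrame, channel=0) -> list[Fragment]:
    """Sample-accurate slices: start = round(start_s*rate), half-open end."""
    x = rec.channel(channel)
    rate = rec.sampling_rate
    out = []
    for row in annot.itertuples(index=True):
        start = int(round(row.start_s * rate))
        stop = start + int(round(row.duration_s * rate))
        if start < 0 or stop > x.size:
            raise ValueError(
                f"annotation row {row.Index} (id={row.id}) spans [{row.start_s}, "
                f"{row.start_s + row.duration_s}) s, outside the recording")
        out.append(Fragment(samples=x[start:stop], sampling_rate=rate,
                            label=row.label, start_time=float(row.start_s),
                            id=str(row.id)))
    return out


def write_wavetrains(trains: list[WaveTrain], path) -> None:
    """Wave-train table as CSV; round-trips bit-exactly through the reader."""
    rows = [{
        "fragment_id": t.fragment_id,
        "peak_time_s": t.peak_time,
        "central_frequency_hz": t.central_frequency,
        "max_psd_uv2hz": t.max_psd,
        "duration_s": t.duration_s,
        "duration_periods": t.duration_periods,
        "bandwidth_hz": t.bandwidth,
        "phase_rad": t.phase,
        "truncated": t.truncated,
    } for t in trains]
    pd.DataFrame(rows, columns=_WT_COLUMNS).to_csv(path, index=False)


def read_wavetrains(path) -> list[WaveTrain]:
    table = pd.read_csv(path, float_precision="round_trip")
    missing = set(_WT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing wave-train columns {sorted(missing)}")
    return [
        WaveTrain(
            peak_time=row.peak_time_s,
            central_frequency=row.central_frequency_hz,
            max_psd=row.max_psd_uv2hz,
            duration_s=row.duration_s,
            duration_periods=row.duration_periods,
            bandwidth=row.bandwidth_hz,
            phase=row.phase_rad,
            fragment_id=str(row.fragment_id),
            truncated=bool(row.truncated),
        )
        for row in table.itertuples(index=False)
    ]


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(out_dir, cfg: dict, seed: int | None) -> Path:
    """Record config hash and seed so a run can be reproduced exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config_hash(cfg), "seed": seed, "config": cfg}
    path = out_dir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
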