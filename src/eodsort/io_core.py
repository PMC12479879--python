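"""Data model and file containers for recordings, EOD events and waveforms.

A *recording* is a two-channel voltage time series (volts) from a pair of
bipolar electrode dipoles in the tank; an *event* is one detected electric
organ discharge (EOD); a *waveform* is the 31-sample normalized snippet
around an event's absolute-maximum peak.

Containers
----------
* recordings: float32 WAV (RIFF) or raw interleaved float32 with a JSON
  sidecar holding ``fs``, ``n_channels`` and a volt scale factor,
* events: plain CSV with header ``t_s,channel,peak_amp_V,label,truth``,
* waveforms: an ``.npz`` array container with the n x 31 matrix plus the
  parallel event table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError, OrderingError, ShapeError

WAVEFORM_LEN = 31

EVENT_COLUMNS = ("t_s", "channel", "peak_amp_V", "label", "truth")


@dataclass
class Recording:
    """Two-channel voltage time series.

    Parameters
    ----------
    samples : ndarray, shape (2, n)
        Per-channel voltages in volts.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Free-form metadata (tank, date, fish ids, simulation truth, ...).
    """

    samples: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != 2:
            raise ShapeError(
                f"recording must be 2 x n, got shape {self.samples.shape}"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EODEvent:
    """One detected discharge.

    ``t_s`` is the time of the absolute-maximum sample, ``channel`` the index
    of the channel carrying the larger amplitude, ``peak_amp_V`` the signed
    voltage at that extremum. ``label`` is an assigned cluster/fish identity;
    ``truth`` is the ground-truth identity (synthetic data only).
    """

    t_s: float
    channel: int
    peak_amp_V: float
    label: str | None = None
    truth: str | None = None


@dataclass
class EODWaveform:
    """31-sample normalized pulse snippet tied to an event.

    Invariants: ``max(|y|) == 1`` and the canonical-orientation extremum is
    positive (polarity-flipped during extraction when needed).
    """

    y: np.ndarray
    event: EODEvent

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.y.ndim != 1:
            raise ShapeError("waveform must be 1-D")


# ---------------------------------------------------------------------------
# recordings


def write_recording(recording: Recording, path: str | Path,
                    format: str = "wav") -> Path:
    """Write a recording as float32 WAV or raw+JSON.

    Raw container: channel-interleaved float32 with a ``<path>.json`` sidecar
    carrying ``fs``, ``n_channels`` and ``volt_scale`` (samples on disk are
    volts / volt_scale; scale 1.0 by default).
    """
    path = Path(path)
    if format == "wav":
        data = np.ascontiguousarray(recording.samples.T.astype(np.float32))
        wavfile.write(path, int(round(recording.fs)), data)
    elif format == "raw":
        interleaved = np.ascontiguousarray(
            recording.samples.T.astype(np.float32)
        ).ravel()
        interleaved.tofile(path)
        sidecar = {
            "fs": recording.fs,
            "n_channels": 2,
            "volt_scale": 1.0,
            "n_samples": recording.n_samples,
            "meta": {k: v for k, v in recording.meta.items()
                     if isinstance(v, (str, int, float, bool))},
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise FormatError(f"unknown recording format {format!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from a 2-channel WAV or raw+JSON container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "wav" if path.suffix.lower() == ".wav" else "raw"
    if format == "wav":
        try:
            fs, data = wavfile.read(path)
        except ValueError as exc:
            raise FormatError(f"not a readable WAV file: {path}") from exc
        if data.ndim != 2 or data.shape[1] != 2:
            raise ShapeError(
                f"expected 2 channels, got shape {data.shape}"
            )
        if data.dtype.kind == "i":  # PCM: restore to [-1, 1] full scale
            data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
        return Recording(samples=data.T.astype(np.float64), fs=float(fs))
    if format == "raw":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing JSON sidecar for raw container: {path}")
        try:
            sidecar = json.loads(sidecar_path.read_text())
            fs = float(sidecar["fs"])
            n_channels = int(sidecar["n_channels"])
            scale = float(sidecar.get("volt_scale", 1.0))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise FormatError(f"garbled sidecar {sidecar_path}") from exc
        if n_channels != 2:
            raise ShapeError(f"expected 2 channels, sidecar says {n_channels}")
        flat = np.fromfile(path, dtype=np.float32).astype(np.float64) * scale
        if flat.size % 2:
            raise FormatError("raw container length is not a multiple of 2")
        return Recording(samples=flat.reshape(-1, 2).T, fs=fs,
                         meta=dict(sidecar.get("meta", {})))
    raise FormatError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# events


def events_to_frame(events: Sequence[EODEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": [e.t_s for e in events],
            "channel": [e.channel for e in events],
            "peak_amp_V": [e.peak_amp_V for e in events],
            "label": [e.label for e in events],
            "truth": [e.truth for e in events],
        },
        columns=list(EVENT_COLUMNS),
    )


def frame_to_events(frame: pd.DataFrame) -> list[EODEvent]:
    events = []
    for row in frame.itertuples(index=False):
        events.append(
            EODEvent(
                t_s=float(row.t_s),
                channel=int(row.channel),
                peak_amp_V=float(row.peak_amp_V),
                label=None if pd.isna(row.label) else str(row.label),
                truth=None if pd.isna(row.truth) else str(row.truth),
            )
        )
    return events


def write_events_csv(events: Sequence[EODEvent], path: str | Path) -> Path:
    """Write events to CSV (header ``t_s,channel,peak_amp_V,label,truth``).

    Events must already be sorted by time.
    """
    times = [e.t_s for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        raise OrderingError("events must be sorted by t_s before writing")
    path = Path(path)
    # %.17g keeps the round-trip lossless for float64 times and amplitudes
    events_to_frame(events).to_csv(path, index=False, float_format="%.17g")
    return path


def read_events_csv(path: str | Path) -> list[EODEvent]:
    path = Path(path)
    frame = pd.read_csv(path, dtype={"label": "string", "truth": "string"},
                        float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"events CSV missing columns {sorted(missing)}")
    if len(frame) and not np.issubdtype(frame["t_s"].dtype, np.number):
        raise FormatError("non-numeric t_s column in events CSV")
    return frame_to_events(frame)


# ---------------------------------------------------------------------------
# waveforms


def write_waveforms(waveforms: Sequence[EODWaveform], path: str | Path) -> Path:
    """Write waveforms as an ``.npz`` container (n x 31 matrix + event table)."""
    for w in waveforms:
        if w.y.shape != (WAVEFORM_LEN,):
            raise ShapeError(
                f"waveforms must have length {WAVEFORM_LEN}, got {w.y.shape}"
            )
    path = Path(path)
    y = (np.stack([w.y for w in waveforms])
         if waveforms else np.empty((0, WAVEFORM_LEN)))
    none_to_empty = lambda v: "" if v is None else str(v)  # noqa: E731
    np.savez(
        path,
        y=y,
        t_s=np.array([w.event.t_s for w in waveforms], dtype=np.float64),
        channel=np.array([w.event.channel for w in waveforms], dtype=np.int64),
        peak_amp_V=np.array([w.event.peak_amp_V for w in waveforms],
                            dtype=np.float64),
        label=np.array([none_to_empty(w.event.label) for w in waveforms],
                       dtype="U32"),
        truth=np.array([none_to_empty(w.event.truth) for w in waveforms],
                       dtype="U32"),
    )
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def read_waveforms(path: str | Path) -> list[EODWaveform]:
    with np.load(path) as data:
        y = data["y"]
        if y.ndim != 2 or (y.size and y.shape[1] != WAVEFORM_LEN):
            raise ShapeError(f"waveform matrix has shape {y.shape}")
        out = []
        for i in range(y.shape[0]):
            event = EODEvent(
                t_s=float(data["t_s"][i]),
                channel=int(data["channel"][i]),
                peak_amp_V=float(data["peak_amp_V"][i]),
                label=str(data["label"][i]) or None,
                truth=str(data["truth"][i]) or None,
            )
            out.append(EODWaveform(y=y[i].copy(), event=event))
    return out
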