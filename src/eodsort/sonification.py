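"""Sonification of labeled EOD event trains.

Two schemes render a dyad's discharge activity as audio:

* pulse-wise: one brief enveloped sinusoid burst per EOD, with a distinct
  frequency per fish, optionally amplitude-scaled by the recorded peak
  voltage (so approach/retreat relative to the electrodes is audible),
* FM: one continuous tone per fish whose pitch follows the smoothed
  discharge rate, exponentially mapped so equal rate ratios sound as equal
  musical intervals and the two voices weave consonant or dissonant
  intervals as the fish synchronize or diverge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .errors import ConfigError, DomainError, OrderingError
from .io_core import EODEvent


@dataclass(frozen=True)
class SonifyConfig:
    """Synthesis parameters (all non-canonical defaults, fully exposed)."""

    audio_fs_hz: int = 44_100
    # pulse-wise mode
    f_a_hz: float = 440.0
    f_b_hz: float = 660.0
    burst_ms: float = 12.0
    amplitude_mode: str = "fixed"  # or "from_peak_amp"
    # FM mode
    carrier_a_hz: float = 220.0
    carrier_b_hz: float = 330.0
    rate_smoothing_s: float = 0.25
    max_deviation_octaves: float = 1.0

    def __post_init__(self) -> None:
        if self.burst_ms * 1e-3 * self.audio_fs_hz < 8:
            raise ConfigError("burst must span at least 8 audio samples")
        worst = max(self.carrier_a_hz, self.carrier_b_hz) * \
            2.0 ** self.max_deviation_octaves
        if worst >= self.audio_fs_hz / 2:
            raise ConfigError("FM deviation can exceed the Nyquist frequency")


def _split_by_fish(events: list[EODEvent]) -> dict[str, list[EODEvent]]:
    labels = sorted({e.label for e in events})
    if len(labels) > 2 or any(lab is None for lab in labels):
        raise DomainError("events must carry binary labels")
    return {lab: [e for e in events if e.label == lab] for lab in labels}


def pulsewise_audio(events: list[EODEvent], duration_s: float,
                    config: SonifyConfig = SonifyConfig()) -> np.ndarray:
    """Mono audio with one enveloped sinusoid burst per event.

    Bursts use a raised-cosine (Hann) envelope at the fish-specific
    frequency; overlaps sum; the output is peak-normalized to 0.9 full
    scale. ``amplitude_mode="from_peak_amp"`` scales each burst by its
    event's |peak_amp_V| relative to the session maximum.
    """
    fs = config.audio_fs_hz
    n = int(round(duration_s * fs))
    audio = np.zeros(n)
    if any(not 0 <= e.t_s <= duration_s for e in events):
        raise DomainError("event beyond the requested duration")
    by_fish = _split_by_fish(events) if events else {}
    freqs = dict(zip(sorted(by_fish), (config.f_a_hz, config.f_b_hz)))
    burst_n = int(round(config.burst_ms * 1e-3 * fs))
    t = np.arange(burst_n) / fs
    envelope = 0.5 * (1 - np.cos(2 * np.pi * np.arange(burst_n) / burst_n))
    max_amp = max((abs(e.peak_amp_V) for e in events), default=1.0) or 1.0
    for fish, fish_events in by_fish.items():
        burst = envelope * np.sin(2 * np.pi * freqs[fish] * t)
        for e in fish_events:
            start = int(round(e.t_s * fs))
            stop = min(start + burst_n, n)
            gain = (abs(e.peak_amp_V) / max_amp
                    if config.amplitude_mode == "from_peak_amp" else 1.0)
            audio[start:stop] += gain * burst[: stop - start]
    peak = np.max(np.abs(audio))
    return audio * (0.9 / peak) if peak > 0 else audio


def instantaneous_rate(event_times: np.ndarray, smoothing_s: float,
                       duration_s: float,
                       audio_fs_hz: int = 44_100) -> np.ndarray:
    """Smoothed discharge rate (Hz) sampled on the audio grid.

    The raw rate is 1/IPI between consecutive events, zero before the first
    event and after a 2 s decay window following the last. Smoothing is a
    causal first-order exponential filter with time constant ``smoothing_s``
    initialized at the first defined rate value, so a perfectly regular
    train reads out its exact rate.
    """
    times = np.asarray(event_times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise OrderingError("event times must be sorted")
    n = int(round(duration_s * audio_fs_hz))
    raw = np.zeros(n)
    if times.size >= 2:
        for t0, t1 in zip(times[:-1], times[1:]):
            i0 = int(round(t0 * audio_fs_hz))
            i1 = int(round(t1 * audio_fs_hz))
            if t1 > t0:
                raw[i0:i1] = 1.0 / (t1 - t0)
        last = int(round(times[-1] * audio_fs_hz))
        raw[last:] = 0.0
    alpha = float(np.exp(-1.0 / (smoothing_s * audio_fs_hz)))
    out = np.zeros(n)
    if times.size >= 2:
        start = int(round(times[0] * audio_fs_hz))
        acc = raw[min(start, n - 1)]
        for i in range(start, n):
            acc = alpha * acc + (1 - alpha) * raw[i]
            out[i] = acc
        cutoff = int(round((times[-1] + 2.0) * audio_fs_hz))
        out[min(cutoff, n):] = 0.0
    return out


def fm_audio(events: list[EODEvent], duration_s: float,
             config: SonifyConfig = SonifyConfig(),
             stereo: bool = False) -> np.ndarray:
    """Two rate-modulated tones, mixed (mono) or on separate stereo channels.

    Fish i's instantaneous frequency is
    ``carrier_i * 2**(max_deviation_octaves * (rate(t) - r_ref)/r_ref)``
    with ``r_ref`` the fish's session-median rate; phase is accumulated by
    integration so the tone is phase-continuous. Peak-normalized to 0.9.
    """
    fs = config.audio_fs_hz
    n = int(round(duration_s * fs))
    if any(not 0 <= e.t_s <= duration_s for e in events):
        raise DomainError("event beyond the requested duration")
    by_fish = _split_by_fish(events) if events else {}
    carriers = dict(zip(sorted(by_fish),
                        (config.carrier_a_hz, config.carrier_b_hz)))
    tones = []
    for fish, fish_events in by_fish.items():
        times = np.array(sorted(e.t_s for e in fish_events))
        rate = instantaneous_rate(times, config.rate_smoothing_s, duration_s,
                                  fs)
        ipis = np.diff(times)
        r_ref = float(np.median(1.0 / ipis[ipis > 0])) if ipis.size else 1.0
        dev = config.max_deviation_octaves * (rate - r_ref) / max(r_ref, 1e-9)
        freq = carriers[fish] * 2.0 ** dev
        if np.max(freq) >= fs / 2:
            raise ConfigError("instantaneous frequency reached Nyquist")
        phase = 2 * np.pi * np.cumsum(freq) / fs
        tones.append(np.sin(phase))
    if not tones:
        tones = [np.zeros(n)]
    if stereo and len(tones) == 2:
        audio = np.stack(tones, axis=1)
    else:
        audio = np.sum(tones, axis=0)
    peak = np.max(np.abs(audio))
    return audio * (0.9 / peak) if peak > 0 else audio


def write_wav(audio: np.ndarray, path: str | Path, audio_fs: int = 44_100,
              subtype: str = "float32", allow_clip: bool = False) -> Path:
    """Write audio in [-1, 1] as a standard RIFF/WAV file."""
    audio = np.asarray(audio, dtype=np.float64)
    if not allow_clip and np.max(np.abs(audio)) > 1.0:
        raise DomainError("samples exceed [-1, 1]; pass allow_clip to force")
    path = Path(path)
    clipped = np.clip(audio, -1.0, 1.0)
    if subtype == "float32":
        wavfile.write(path, audio_fs, clipped.astype(np.float32))
    elif subtype == "pcm16":
        wavfile.write(path, audio_fs,
                      np.round(clipped * 32767).astype(np.int16))
    else:
        raise ConfigError(f"unknown WAV subtype {subtype!r}")
    return path
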