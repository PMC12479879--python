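"""Baseline removal, EOD detection, waveform extraction and normalization.

The detection chain mirrors standard offline pulse-fish preprocessing:

1. subtract the signal isoline (running median) per channel,
2. square the signal so the threshold catches the absolute-maximum phase
   regardless of pulse polarity (orientation of the fish relative to the
   electrodes flips the recorded sign),
3. find squared-signal peaks above threshold**2 with a 400 us refractory
   spacing, per channel,
4. merge cross-channel coincidences, keeping the channel with the larger
   amplitude,
5. cut a +/-300 us window around each absolute-maximum peak (31 samples at
   50 kHz), peak-normalize, and flip polarity so the dominant extremum is
   positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError
from .io_core import EODEvent, EODWaveform, Recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds and windows for EOD detection.

    threshold_V is in original amplitude units and applied as threshold**2
    on the squared trace. window_us is the half-window around the peak
    (300 us -> 31 samples at 50 kHz). noise_rms_mV documents the estimated
    recording noise floor; it is metadata, not an adaptive threshold.
    """

    threshold_V: float = 0.005
    min_dist_us: float = 400.0
    window_us: float = 300.0
    baseline_kernel_ms: float = 5.0
    merge_tol_us: float = 200.0
    noise_rms_mV: float = 0.2

    def __post_init__(self) -> None:
        if self.threshold_V <= 0:
            raise ConfigError("threshold_V must be positive")
        if 2 * self.window_us < 400.0:
            raise ConfigError(
                "extraction window must span the 200-400 us pulse range"
            )


def window_half_samples(window_us: float, fs: float) -> int:
    """Half-window in samples; 300 us at 50 kHz -> 15 (31-sample snippets)."""
    return int(round(window_us * 1e-6 * fs))


def remove_baseline(recording: Recording,
                    baseline_kernel_ms: float = 5.0) -> Recording:
    """Subtract a running-median isoline from each channel.

    The kernel (default 5 ms, i.e. 251 samples at 50 kHz) must be much wider
    than a pulse so the median tracks drift without eating the pulses.
    """
    kernel = int(round(baseline_kernel_ms * 1e-3 * recording.fs))
    if kernel % 2 == 0:
        kernel += 1
    # must be >= 3x the 400 us maximum pulse width or it erases pulses
    if kernel < 3 * int(round(400e-6 * recording.fs)) or kernel < 3:
        raise ConfigError(
            f"baseline kernel {baseline_kernel_ms} ms is shorter than 3 pulse "
            "widths and would erase pulses"
        )
    out = np.empty_like(recording.samples)
    for ch in range(2):
        med = (
            pd.Series(recording.samples[ch])
            .rolling(kernel, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        out[ch] = recording.samples[ch] - med
    return Recording(samples=out, fs=recording.fs, meta=dict(recording.meta))


def detect_eods(recording: Recording,
                config: DetectionConfig = DetectionConfig()) -> list[EODEvent]:
    """Detect EODs on both channels and merge cross-channel coincidences.

    Peaks of the squared signal above ``threshold_V**2`` with spacing
    >= ``min_dist_us`` are found per channel; detections coincident across
    channels within ``merge_tol_us`` collapse to one event on the channel
    with the larger absolute amplitude. Events are returned sorted by time
    with the signed voltage at the extremum.
    """
    fs = recording.fs
    min_dist = int(round(config.min_dist_us * 1e-6 * fs))
    if min_dist < 2:
        raise ConfigError("sampling rate too low to honor min_dist_us")
    candidates: list[tuple[int, int, float]] = []  # (sample, channel, signed V)
    for ch in range(2):
        x = recording.samples[ch]
        peaks, _ = find_peaks(x ** 2, height=config.threshold_V ** 2,
                              distance=min_dist)
        candidates.extend((int(p), ch, float(x[p])) for p in peaks)
    candidates.sort()

    tol = int(round(config.merge_tol_us * 1e-6 * fs))
    events: list[EODEvent] = []
    i = 0
    while i < len(candidates):
        best = candidates[i]
        j = i + 1
        while j < len(candidates) and candidates[j][0] - candidates[i][0] <= tol:
            if abs(candidates[j][2]) > abs(best[2]):
                best = candidates[j]
            j += 1
        events.append(
            EODEvent(t_s=best[0] / fs, channel=best[1], peak_amp_V=best[2])
        )
        i = j
    return events


def extract_waveforms(recording: Recording, events: list[EODEvent],
                      config: DetectionConfig = DetectionConfig(),
                      ) -> list[EODWaveform]:
    """Cut, normalize and polarity-canonicalize the snippet of each event.

    31 samples at 50 kHz (in general ``2*round(window_us*fs/1e6) + 1``) from
    the event's channel, divided by the absolute maximum, and multiplied by
    -1 when the global extremum is negative so every stored waveform has a
    positive dominant peak. Events too close to a recording edge are dropped
    with a logged warning.
    """
    half = window_half_samples(config.window_us, recording.fs)
    out: list[EODWaveform] = []
    dropped = 0
    for event in events:
        idx = int(round(event.t_s * recording.fs))
        if idx - half < 0 or idx + half + 1 > recording.n_samples:
            dropped += 1
            continue
        y = recording.samples[event.channel, idx - half: idx + half + 1].copy()
        extremum = y[np.argmax(np.abs(y))]
        if extremum == 0:
            dropped += 1
            continue
        y /= abs(extremum)
        if extremum < 0:
            y = -y
        out.append(EODWaveform(y=y, event=event))
    if dropped:
        log.warning("dropped %d events at recording edges or with empty "
                    "windows", dropped)
    return out


def detect_and_extract(recording: Recording,
                       config: DetectionConfig = DetectionConfig(),
                       ) -> tuple[list[EODEvent], list[EODWaveform]]:
    """remove_baseline -> detect_eods -> extract_waveforms in one call."""
    clean = remove_baseline(recording, config.baseline_kernel_ms)
    events = detect_eods(clean, config)
    waveforms = extract_waveforms(clean, events, config)
    kept = {id(w.event) for w in waveforms}
    events = [e for e in events if id(e) in kept]
    return events, waveforms
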