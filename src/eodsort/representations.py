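"""EOD feature representations: time waveform, FFT spectrum, Morse scalogram.

The time-frequency representation is a continuous wavelet transform with a
generalized Morse wavelet. Morse wavelets are analytic (zero at negative
frequencies) and parameterized by a symmetry parameter gamma and a
time-bandwidth product P^2 (beta = P^2 / gamma); gamma = 3, P^2 = 60 gives
a nearly symmetric, well-localized wavelet suited to the ~300 us biphasic
pulses analyzed here. The transform runs in the frequency domain on the
zero-padded snippet (15 zeros per side, 31 -> 61 samples) on a logarithmic
scale grid with 12 voices per octave; magnitudes are cropped back to the
central 31 columns and normalized by the maximal coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, ShapeError
from .io_core import EODWaveform


@dataclass(frozen=True)
class MorseParams:
    """Morse CWT configuration.

    gamma : symmetry parameter (3 = "airline" wavelet, nearly symmetric)
    p2 : time-bandwidth product P^2; beta = p2 / gamma
    voices_per_octave : scales per frequency octave
    pad : zeros appended on each side of the snippet before the CWT
    freq_lo_hz, freq_hi_hz : analyzed pseudo-frequency band
    """

    gamma: float = 3.0
    p2: float = 60.0
    voices_per_octave: int = 12
    pad: int = 15
    freq_lo_hz: float = 1_000.0
    freq_hi_hz: float = 25_000.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.p2 <= 0 or self.voices_per_octave < 1:
            raise ConfigError("gamma, p2 > 0 and voices_per_octave >= 1")
        if not self.freq_lo_hz < self.freq_hi_hz:
            raise ConfigError("freq_lo_hz must be below freq_hi_hz")

    @property
    def beta(self) -> float:
        return self.p2 / self.gamma

    def frequencies(self) -> np.ndarray:
        """Pseudo-frequency grid (Hz), descending, 12 voices per octave."""
        n_octaves = np.log2(self.freq_hi_hz / self.freq_lo_hz)
        k = np.arange(int(np.floor(n_octaves * self.voices_per_octave)) + 1)
        return self.freq_hi_hz * 2.0 ** (-k / self.voices_per_octave)


@dataclass(frozen=True)
class Scalogram:
    """CWT magnitudes, scales x time, normalized so max == 1."""

    coeffs: np.ndarray
    scales_hz: np.ndarray


def _morse_filter_bank(params: MorseParams, n: int, fs: float) -> np.ndarray:
    """Frequency-domain Morse wavelets, one row per pseudo-frequency.

    The wavelet is psi_hat(w) = 2 (e*gamma/beta)^(beta/gamma) w^beta
    exp(-w^gamma) for w > 0, peak-normalized at w_p = (beta/gamma)^(1/gamma);
    each row is evaluated on the length-n DFT grid scaled so the wavelet's
    peak sits at the row's pseudo-frequency.
    """
    beta, gamma = params.beta, params.gamma
    w_peak = (beta / gamma) ** (1.0 / gamma)
    freqs = params.frequencies()
    w = 2.0 * np.pi * np.fft.fftfreq(n, d=1.0 / fs)  # rad/s, signed
    bank = np.zeros((freqs.size, n))
    pos = w > 0
    log_norm = (beta / gamma) * (1.0 + np.log(gamma / beta))  # log (e g/b)^(b/g)
    for i, f in enumerate(freqs):
        ws = w[pos] * (w_peak / (2.0 * np.pi * f))
        bank[i, pos] = 2.0 * np.exp(log_norm + beta * np.log(ws) - ws ** gamma)
    return bank


def morse_scalogram(waveform: np.ndarray | EODWaveform,
                    params: MorseParams = MorseParams(),
                    fs: float = 50_000.0) -> Scalogram:
    """Normalized Morse scalogram of one snippet (scales x 31)."""
    y = waveform.y if isinstance(waveform, EODWaveform) else np.asarray(waveform)
    coeffs = _scalogram_stack(y[None, :], params, fs)[0]
    return Scalogram(coeffs=coeffs, scales_hz=params.frequencies())


def _scalogram_stack(rows: np.ndarray, params: MorseParams,
                     fs: float) -> np.ndarray:
    """Vectorized scalograms of an n x L waveform matrix -> n x S x L."""
    if params.freq_hi_hz > fs / 2:
        raise ConfigError("freq_hi_hz exceeds the Nyquist frequency")
    n_wave, length = rows.shape
    n = length + 2 * params.pad
    padded = np.zeros((n_wave, n))
    padded[:, params.pad: params.pad + length] = rows
    bank = _morse_filter_bank(params, n, fs)  # S x n
    spectra = np.fft.fft(padded, axis=1)  # n_wave x n
    # analytic CWT: inverse transform of X(w) * psi_hat(s w) per scale
    coeffs = np.abs(
        np.fft.ifft(spectra[:, None, :] * bank[None, :, :], axis=2)
    )[:, :, params.pad: params.pad + length]
    peak = coeffs.reshape(n_wave, -1).max(axis=1)
    peak[peak == 0] = 1.0
    return coeffs / peak[:, None, None]


def fft_spectrum(waveform: np.ndarray | EODWaveform, n_fft: int = 64,
                 ) -> np.ndarray:
    """One-sided magnitude spectrum of a snippet, zero-padded, max-normalized."""
    y = waveform.y if isinstance(waveform, EODWaveform) else np.asarray(waveform)
    mag = np.abs(np.fft.rfft(y, n=n_fft))
    peak = mag.max()
    return mag / peak if peak > 0 else mag


def feature_matrix(waveforms, domain: str = "timefreq",
                   params: MorseParams = MorseParams(),
                   fs: float = 50_000.0) -> np.ndarray:
    """Stack per-EOD features into an n x d matrix (row order = event order).

    domain: ``time`` (raw 31-sample rows), ``frequency`` (normalized FFT
    magnitudes) or ``timefreq`` (row-major flattened Morse scalograms,
    d = S * 31).
    """
    rows = [w.y if isinstance(w, EODWaveform) else np.asarray(w)
            for w in waveforms]
    if not rows:
        raise ShapeError("empty waveform list")
    lengths = {r.shape for r in rows}
    if len(lengths) != 1:
        raise ShapeError(f"mixed waveform lengths: {sorted(lengths)}")
    stack = np.stack(rows)
    if domain == "time":
        return stack
    if domain == "frequency":
        return np.stack([fft_spectrum(r) for r in stack])
    if domain == "timefreq":
        coeffs = _scalogram_stack(stack, params, fs)
        return coeffs.reshape(stack.shape[0], -1)
    raise ConfigError(f"unknown domain {domain!r}")


class MorseScalogram(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: waveform rows -> flattened Morse scalograms.

    Stateless (fit only validates); transform maps an n x 31 matrix to the
    n x (S*31) time-frequency feature matrix used by the separation and
    baseline estimators.
    """

    def __init__(self, gamma: float = 3.0, p2: float = 60.0,
                 voices_per_octave: int = 12, pad: int = 15,
                 freq_lo_hz: float = 1_000.0, freq_hi_hz: float = 25_000.0,
                 fs: float = 50_000.0):
        self.gamma = gamma
        self.p2 = p2
        self.voices_per_octave = voices_per_octave
        self.pad = pad
        self.freq_lo_hz = freq_lo_hz
        self.freq_hi_hz = freq_hi_hz
        self.fs = fs

    def _params(self) -> MorseParams:
        return MorseParams(gamma=self.gamma, p2=self.p2,
                           voices_per_octave=self.voices_per_octave,
                           pad=self.pad, freq_lo_hz=self.freq_lo_hz,
                           freq_hi_hz=self.freq_hi_hz)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ShapeError("expected an n x L waveform matrix")
        self.n_features_in_ = X.shape[1]
        self.scales_hz_ = self._params().frequencies()
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ShapeError("expected an n x L waveform matrix")
        coeffs = _scalogram_stack(X, self._params(), self.fs)
        return coeffs.reshape(X.shape[0], -1)
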