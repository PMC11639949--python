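"""Acoustic feature extraction for the dysarthric voice-conversion pipeline.

The conversion framework represents speech in two complementary ways:

* an 80-band Mel-spectrogram (the conversion domain), framed with a
  46.4 ms analysis window and an 11.6 ms hop at 16 kHz;
* per-frame MFCC vectors augmented with delta and delta-delta
  derivatives, concatenated with per-frame phoneme posteriors to form
  the joint feature ``X(t) = [X_mfcc(t), X_phoneme(t)]`` consumed by the
  fuzzy clustering stage.

Both paths share one framing convention (centered analysis, reflection
padding, nearest-integer window/hop in samples: 742 and 186 at 16 kHz)
so their frame counts always agree.  Mel magnitudes are linear (no log
compression) unless requested; the MFCC path applies its own log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, rfft
from scipy.io import wavfile
from scipy.signal import resample_poly

CANONICAL_RATE_HZ = 16_000
DEFAULT_WINDOW_S = 0.0464
DEFAULT_HOP_S = 0.0116
DEFAULT_N_MELS = 80

__all__ = [
    "Waveform",
    "MelSpectrogram",
    "MfccFeatures",
    "PhonemeLabels",
    "JointFeatureFrame",
    "load_waveform",
    "mel_filterbank",
    "compute_mel_spectrogram",
    "pad_frames_to_multiple_of_4",
    "compute_mfcc_with_deltas",
    "delta_features",
    "one_hot_labels",
    "concat_features",
]


@dataclass
class Waveform:
    """A mono waveform; amplitudes nominally in [-1, 1]."""

    samples: np.ndarray
    rate_hz: int = CANONICAL_RATE_HZ

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("waveform must be a nonempty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.rate_hz <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def resampled(self, rate_hz: int = CANONICAL_RATE_HZ) -> "Waveform":
        """Return this waveform resampled (polyphase) to ``rate_hz``."""
        if self.rate_hz == rate_hz:
            return self
        from math import gcd

        g = gcd(rate_hz, self.rate_hz)
        out = resample_poly(self.samples, rate_hz // g, self.rate_hz // g)
        return Waveform(out, rate_hz)


def load_waveform(path, rate_hz: int = CANONICAL_RATE_HZ) -> Waveform:
    """Read a WAV file and resample to the canonical 16 kHz."""
    rate, data = wavfile.read(path)
    was_int16 = data.dtype == np.int16
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:  # downmix to mono
        data = data.mean(axis=1)
    if was_int16:
        data = data / 32768.0
    return Waveform(data, int(rate)).resampled(rate_hz)


@dataclass
class MelSpectrogram:
    """Nonnegative ``n_mels x T`` matrix with its framing parameters."""

    values: np.ndarray
    n_mels: int = DEFAULT_N_MELS
    window_s: float = DEFAULT_WINDOW_S
    hop_s: float = DEFAULT_HOP_S
    band_centers_hz: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.n_mels:
            raise ValueError(
                f"Mel matrix must be (n_mels={self.n_mels}) x T, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("Mel entries must be finite and nonnegative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class MfccFeatures:
    """``T x (3 * n_cepstra)`` matrix: statics, deltas, delta-deltas."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] % 3 != 0:
            raise ValueError("MFCC matrix width must be divisible by 3")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cepstra(self) -> int:
        return self.values.shape[1] // 3


@dataclass
class PhonemeLabels:
    """Per-frame phoneme one-hot / posterior rows; each row sums to 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("phoneme labels must be a T x d matrix")
        if np.any(self.values < 0):
            raise ValueError("phoneme posterior entries must be nonnegative")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("phoneme posterior rows must sum to 1")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


@dataclass
class JointFeatureFrame:
    """Concatenated joint representation ``[X_mfcc(t), X_phoneme(t)]``."""

    values: np.ndarray
    d_mfcc: int = 0
    d_phoneme: int = 0

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _window_hop_samples(rate_hz: int, window_s: float, hop_s: float) -> tuple[int, int]:
    win = int(round(window_s * rate_hz))
    hop = int(round(hop_s * rate_hz))
    if not win > hop > 0:
        raise ValueError("require window_s > hop_s > 0")
    return win, hop


def _frame_signal(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Centered framing with reflection padding; T = 1 + len(x) // hop."""
    if x.size < win:
        raise ValueError(
            f"waveform of {x.size} samples is shorter than one analysis window ({win})"
        )
    n_frames = 1 + x.size // hop
    half = win // 2
    padded = np.pad(x, (half, half + win), mode="reflect")
    idx = np.arange(win)[None, :] + hop * np.arange(n_frames)[:, None]
    return padded[idx]


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate_hz: int, fmin: float = 0.0, fmax: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel filterbank.

    Returns ``(weights, centers_hz)`` where ``weights`` is
    ``n_mels x (n_fft // 2 + 1)`` and ``centers_hz`` holds each band's
    center frequency (used e.g. to locate the dominant band of a tone).
    """
    if fmax is None:
        fmax = rate_hz / 2.0
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = np.asarray(_mel_to_hz(mel_pts))
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate_hz)
    weights = np.zeros((n_mels, bin_freqs.size))
    for j in range(n_mels):
        lo, ctr, hi = hz_pts[j], hz_pts[j + 1], hz_pts[j + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        weights[j] = np.maximum(0.0, np.minimum(up, down))
    return weights, hz_pts[1:-1]


def compute_mel_spectrogram(
    wav: Waveform,
    n_mels: int = DEFAULT_N_MELS,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    n_fft: int | None = None,
    log: bool = False,
    log_floor: float = 1e-10,
) -> MelSpectrogram:
    """Magnitude STFT mapped through a triangular Mel filterbank.

    Linear in waveform amplitude by default (``log=False``): scaling the
    input by ``c > 0`` scales every output entry by ``c``.
    """
    wav = wav.resampled(CANONICAL_RATE_HZ)
    win, hop = _window_hop_samples(wav.rate_hz, window_s, hop_s)
    if n_fft is None:
        n_fft = 1 << (win - 1).bit_length()
    frames = _frame_signal(wav.samples, win, hop)
    windowed = frames * np.hanning(win)[None, :]
    mag = np.abs(rfft(windowed, n=n_fft, axis=1))  # T x bins
    fb, centers = mel_filterbank(n_mels, n_fft, wav.rate_hz)
    mel = fb @ mag.T  # n_mels x T
    if log:
        mel = np.log(mel + log_floor)
        mel -= mel.min()  # keep the nonnegativity contract
    return MelSpectrogram(mel, n_mels, window_s, hop_s, band_centers_hz=centers)


def pad_frames_to_multiple_of_4(mel: MelSpectrogram) -> MelSpectrogram:
    """Zero-pad trailing frames so the frame count is a multiple of 4."""
    t = mel.n_frames
    pad = (-t) % 4
    if pad == 0:
        return mel
    values = np.concatenate([mel.values, np.zeros((mel.n_mels, pad))], axis=1)
    return MelSpectrogram(values, mel.n_mels, mel.window_s, mel.hop_s, mel.band_centers_hz)


def delta_features(x: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression-filter temporal derivative over +/- ``width`` frames.

    ``d[t] = sum_w w * (x[t+w] - x[t-w]) / (2 * sum_w w^2)`` with edge
    replication, the standard delta filter used for MFCC dynamics.
    """
    x = np.asarray(x, dtype=np.float64)
    padded = np.pad(x, ((width, width), (0, 0)), mode="edge")
    denom = 2.0 * sum(w * w for w in range(1, width + 1))
    out = np.zeros_like(x)
    for w in range(1, width + 1):
        out += w * (padded[width + w : padded.shape[0] - width + w]
                    - padded[width - w : x.shape[0] + width - w])
    return out / denom


def compute_mfcc_with_deltas(
    wav: Waveform,
    n_cepstra: int = 13,
    n_mels: int = DEFAULT_N_MELS,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
    delta_width: int = 2,
) -> MfccFeatures:
    """MFCC statics + deltas + delta-deltas, ``T x 3*n_cepstra``.

    Uses the same 80-band Mel filterbank and framing as
    :func:`compute_mel_spectrogram`, so frame counts agree across both
    feature paths.  Short inputs are handled by the delta filter's edge
    replication.
    """
    if n_cepstra < 1:
        raise ValueError("n_cepstra must be >= 1")
    mel = compute_mel_spectrogram(wav, n_mels=n_mels, window_s=window_s, hop_s=hop_s)
    logmel = np.log(mel.values + 1e-10)
    cepstra = dct(logmel, type=2, norm="ortho", axis=0)[:n_cepstra].T  # T x n_cepstra
    d1 = delta_features(cepstra, delta_width)
    d2 = delta_features(d1, delta_width)
    return MfccFeatures(np.concatenate([cepstra, d1, d2], axis=1))


def one_hot_labels(labels, vocabulary=None) -> PhonemeLabels:
    """Encode a sequence of categorical phoneme labels as one-hot rows."""
    labels = list(labels)
    if vocabulary is None:
        vocabulary = sorted(set(labels))
    index = {lab: i for i, lab in enumerate(vocabulary)}
    out = np.zeros((len(labels), len(vocabulary)))
    for t, lab in enumerate(labels):
        out[t, index[lab]] = 1.0
    return PhonemeLabels(out)


def concat_features(mfcc: MfccFeatures, phon: PhonemeLabels) -> JointFeatureFrame:
    """Concatenate MFCC and phoneme blocks frame-wise."""
    if mfcc.n_frames != phon.n_frames:
        raise ValueError(
            f"frame-count mismatch: MFCC has {mfcc.n_frames} frames, "
            f"phoneme labels have {phon.n_frames}"
        )
    values = np.concatenate([mfcc.values, phon.values], axis=1)
    return JointFeatureFrame(values, d_mfcc=mfcc.values.shape[1], d_phoneme=phon.values.shape[1])
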