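"""Mains-hum removal and MFCC + delta feature extraction.

Every channel of a 5-s segment is reduced to a sequence of mel-frequency
cepstral coefficient vectors computed on 100 ms Hamming windows shifted
by 50 ms: 13 coefficients including the 0th, optionally augmented with
their delta (frame-to-frame regression slope) features for a 26-d vector
per frame. EMG (1000 Hz) and sound (44100 Hz) streams use the same
window timing, so equal-duration inputs yield equal frame counts — the
precondition for state-synchronous multi-stream fusion downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import rfft
from scipy.signal import iirnotch, filtfilt

from .io_signals import SOUND_CHANNEL, TaskSegment

__all__ = [
    "FrameSpec",
    "MfccConfig",
    "FeatureSequence",
    "hum_filter",
    "hamming_window",
    "frame_signal",
    "mel_scale",
    "mel_scale_inv",
    "mel_filterbank",
    "mfcc",
    "delta",
    "extract_features",
    "default_mfcc_config",
]


@dataclass(frozen=True)
class FrameSpec:
    """Analysis framing: window and shift lengths in milliseconds."""

    window_ms: float = 100.0
    shift_ms: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.shift_ms <= self.window_ms:
            raise ValueError("need 0 < shift_ms <= window_ms")

    def window_samples(self, rate: float) -> int:
        return int(round(self.window_ms * rate / 1000.0))

    def shift_samples(self, rate: float) -> int:
        return int(round(self.shift_ms * rate / 1000.0))


@dataclass(frozen=True)
class MfccConfig:
    """MFCC parameters.

    ``n_ceps`` counts the kept DCT coefficients including the 0th order.
    ``fft_size`` of None selects the next power of two at or above the
    window length. ``f_max`` of None means Nyquist. With ``append_delta``
    the feature dimension doubles to ``2 * n_ceps``.
    """

    n_ceps: int = 13
    n_mel_filters: int = 20
    f_min: float = 0.0
    f_max: float | None = None
    fft_size: int | None = None
    log_floor: float = 1e-10
    delta_window: int = 2
    append_delta: bool = True
    pre_emphasis: float = 0.0  # off by default; speech convention, unused here

    def __post_init__(self) -> None:
        if self.n_ceps > self.n_mel_filters:
            raise ValueError("n_ceps must be <= n_mel_filters")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be > 0")
        if self.delta_window < 1:
            raise ValueError("delta_window must be >= 1")

    def resolved_fft_size(self, window_samples: int) -> int:
        if self.fft_size is not None:
            if self.fft_size < window_samples:
                raise ValueError(
                    f"fft_size {self.fft_size} smaller than window ({window_samples} samples)"
                )
            return self.fft_size
        n = 1
        while n < window_samples:
            n *= 2
        return n


def default_mfcc_config(channel: str) -> MfccConfig:
    """Per-channel default: 20 mel filters over the 0-500 Hz EMG band,
    24 over the full sound band."""
    if channel == SOUND_CHANNEL:
        return MfccConfig(n_mel_filters=24)
    return MfccConfig(n_mel_filters=20)


@dataclass
class FeatureSequence:
    """T x D matrix of per-frame feature vectors for one channel."""

    values: np.ndarray
    frame_times: np.ndarray
    channel: str
    config: MfccConfig

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------

def hum_filter(
    signal: np.ndarray,
    rate: float,
    mains_freq: float = 60.0,
    n_harmonics: int = 8,
    q: float = 30.0,
) -> np.ndarray:
    """Suppress powerline hum: zero-phase IIR notches at the mains
    frequency and its harmonics k = 1..n_harmonics (truncated below
    Nyquist).

    ``q`` is the quality factor of the fundamental's notch; harmonics
    use the same *absolute* rejection bandwidth (mains_freq / q, 2 Hz at
    the defaults), so the notches stay narrow across the whole band and
    broadband power is essentially untouched.
    """
    if mains_freq >= rate / 2:
        raise ValueError(f"mains_freq {mains_freq} Hz is at or above Nyquist ({rate / 2} Hz)")
    out = np.asarray(signal, dtype=np.float64)
    bandwidth = mains_freq / q
    for k in range(1, n_harmonics + 1):
        f = k * mains_freq
        if f >= rate / 2:
            break
        b, a = iirnotch(f, f / bandwidth, fs=rate)
        out = filtfilt(b, a, out)
    return out


def hamming_window(length: int) -> np.ndarray:
    """w[n] = 0.54 - 0.46 cos(2 pi n / (L - 1)); endpoints 0.08."""
    if length == 1:
        return np.ones(1)
    n = np.arange(length)
    return 0.54 - 0.46 * np.cos(2 * np.pi * n / (length - 1))


def frame_signal(signal: np.ndarray, rate: float, spec: FrameSpec) -> np.ndarray:
    """Slice into overlapping Hamming-windowed frames (T x L).

    Frame t starts at sample t * shift; T = floor((n - L) / S) + 1.
    """
    signal = np.asarray(signal, dtype=np.float64)
    L = spec.window_samples(rate)
    S = spec.shift_samples(rate)
    n = len(signal)
    if n < L:
        raise ValueError(f"signal ({n} samples) shorter than one window ({L} samples)")
    T = (n - L) // S + 1
    idx = np.arange(L)[None, :] + S * np.arange(T)[:, None]
    return signal[idx] * hamming_window(L)[None, :]


def mel_scale(f):
    """Hz -> mel: 2595 log10(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be >= 0")
    return 2595.0 * np.log10(1.0 + f / 700.0)


def mel_scale_inv(m):
    """mel -> Hz, inverse of mel_scale."""
    m = np.asarray(m, dtype=np.float64)
    return 700.0 * (10.0 ** (m / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, fft_size: int, rate: float, f_min: float, f_max: float
) -> np.ndarray:
    """Triangular filters with mel-equidistant centres, (n_filters x bins).

    Filter m rises linearly from centre m-1 to centre m and falls to
    centre m+1, evaluated at the FFT bin frequencies.
    """
    if not 0 <= f_min < f_max <= rate / 2 + 1e-9:
        raise ValueError("need 0 <= f_min < f_max <= Nyquist")
    mel_pts = np.linspace(mel_scale(f_min), mel_scale(f_max), n_filters + 2)
    hz_pts = mel_scale_inv(mel_pts)
    bins = np.arange(fft_size // 2 + 1) * rate / fft_size
    fb = np.zeros((n_filters, len(bins)))
    for m in range(n_filters):
        lo, mid, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        rise = (bins - lo) / (mid - lo)
        fall = (hi - bins) / (hi - mid)
        fb[m] = np.clip(np.minimum(rise, fall), 0.0, None)
    return fb


def _dct_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Orthonormal DCT-II, rows 0..n_out-1."""
    k = np.arange(n_out)[:, None]
    n = np.arange(n_in)[None, :]
    mat = np.cos(np.pi * k * (2 * n + 1) / (2 * n_in))
    mat *= np.sqrt(2.0 / n_in)
    mat[0] *= np.sqrt(0.5)
    return mat


def mfcc(frames: np.ndarray, rate: float, config: MfccConfig) -> np.ndarray:
    """Windowed frames (T x L) -> MFCC matrix (T x n_ceps).

    Zero-pad to the FFT size, magnitude-squared spectrum, triangular mel
    filterbank, natural log (clamped at log_floor), orthonormal DCT-II.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    L = frames.shape[1]
    nfft = config.resolved_fft_size(L)
    f_max = config.f_max if config.f_max is not None else rate / 2
    power = np.abs(rfft(frames, n=nfft, axis=1)) ** 2
    fb = mel_filterbank(config.n_mel_filters, nfft, rate, config.f_min, f_max)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, config.log_floor))
    return log_mel @ _dct_matrix(config.n_ceps, config.n_mel_filters).T


def delta(features: np.ndarray, N: int = 2) -> np.ndarray:
    """Regression-slope (velocity) features with edge-frame replication.

    d_t = sum_{n=1..N} n (c_{t+n} - c_{t-n}) / (2 sum n^2).
    """
    if N < 1:
        raise ValueError("delta window must be >= 1")
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    T = features.shape[0]
    padded = np.concatenate(
        [np.repeat(features[:1], N, axis=0), features, np.repeat(features[-1:], N, axis=0)]
    )
    denom = 2.0 * sum(n * n for n in range(1, N + 1))
    out = np.zeros_like(features)
    for n in range(1, N + 1):
        out += n * (padded[N + n : N + n + T] - padded[N - n : N - n + T])
    return out / denom


def extract_features(
    segment: TaskSegment,
    channel: str,
    frame_spec: FrameSpec | None = None,
    mfcc_config: MfccConfig | None = None,
    *,
    mains_freq: float = 60.0,
) -> FeatureSequence:
    """Full per-channel pipeline: hum filter -> frame -> MFCC -> append delta."""
    if channel not in segment.channels:
        raise KeyError(f"segment has no channel {channel!r}")
    frame_spec = frame_spec or FrameSpec()
    config = mfcc_config or default_mfcc_config(channel)
    x, rate = segment.channels[channel]
    x = hum_filter(x, rate, mains_freq=mains_freq)
    if config.pre_emphasis > 0:
        x = np.append(x[0], x[1:] - config.pre_emphasis * x[:-1])
    frames = frame_signal(x, rate, frame_spec)
    ceps = mfcc(frames, rate, config)
    if config.append_delta:
        ceps = np.hstack([ceps, delta(ceps, config.delta_window)])
    if not np.all(np.isfinite(ceps)):
        raise FloatingPointError("non-finite value in feature matrix")
    L = frame_spec.window_samples(rate)
    S = frame_spec.shift_samples(rate)
    times = (np.arange(ceps.shape[0]) * S + L / 2) / rate
    return FeatureSequence(values=ceps, frame_times=times, channel=channel, config=config)
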