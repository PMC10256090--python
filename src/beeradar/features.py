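"""Log Area Ratio feature encoding via linear predictive coding.

Each fixed-length window is optionally resampled, split per channel into
non-overlapping sub-windows, and each sub-window is encoded as the Log Area
Ratios of an autocorrelation-method LPC model solved by the Levinson-Durbin
recursion.  LARs are a numerically well-behaved transform of the reflection
coefficients: ``LAR_i = log((1 - k_i) / (1 + k_i))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from beeradar.segmentation import WindowSample
from beeradar.sim import IQRecording

_K_CLAMP = 1.0 - 1e-6


@dataclass(frozen=True)
class LpcModel:
    """Autocorrelation-method linear predictor of one sub-window.

    ``prediction_coefficients`` ``a`` predict ``x[n] ~ sum_i a_i x[n-i]``;
    ``reflection_coefficients`` are the Levinson-Durbin partial correlations;
    ``gain`` is the residual (prediction error) amplitude.
    """

    order: int
    prediction_coefficients: np.ndarray
    reflection_coefficients: np.ndarray
    gain: float


@dataclass(frozen=True)
class FeatureSpec:
    """How to encode one window: rate, LPC order, sub-windowing, channels."""

    sample_rate: float = 44100.0
    order: int = 240
    sub_window_len: float | None = None  # None = full window
    channels: str = "iq"  # "iq" or "i"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.channels not in ("iq", "i"):
            raise ValueError("channels must be 'iq' or 'i'")
        if self.sub_window_len is not None and self.sub_window_len <= 0:
            raise ValueError("sub_window_len must be positive")

    @property
    def n_channels(self) -> int:
        return 2 if self.channels == "iq" else 1

    def n_sub_windows(self, window_len: float) -> int:
        if self.sub_window_len is None:
            return 1
        ratio = window_len / self.sub_window_len
        if abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(
                f"sub_window_len {self.sub_window_len} does not divide "
                f"window length {window_len} into an integer count"
            )
        return int(round(ratio))


@dataclass(frozen=True)
class FeatureVector:
    """Concatenated LARs, ordered channel-major, then sub-window, then lag."""

    values: np.ndarray
    spec: FeatureSpec
    label: str | None = None


def resample(recording: IQRecording, target_rate: float) -> IQRecording:
    """Anti-aliased rational-ratio resampling of both channels.

    44.1 kHz to 3.5 kHz is the rational ratio 5/63; the polyphase filter of
    :func:`scipy.signal.resample_poly` handles anti-aliasing.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if target_rate > recording.sample_rate:
        raise ValueError("target_rate must not exceed the original rate")
    if target_rate == recording.sample_rate:
        return recording
    frac = Fraction(int(round(target_rate)), int(round(recording.sample_rate)))
    up, down = frac.numerator, frac.denominator
    i = sps.resample_poly(recording.samples.real, up, down)
    q = sps.resample_poly(recording.samples.imag, up, down)
    return IQRecording(i + 1j * q, target_rate)


def _autocorrelation(x: np.ndarray, order: int) -> np.ndarray:
    n = len(x)
    nfft = next_fast_len(2 * n - 1)
    spec = np.fft.rfft(x, nfft)
    r = np.fft.irfft(spec * np.conj(spec), nfft)[: order + 1]
    return r / n


def levinson_durbin(r: np.ndarray, order: int) -> LpcModel:
    """Solve the normal equations by Levinson-Durbin.

    Degenerate (zero-energy or numerically exhausted) inputs yield zero
    reflection coefficients rather than an exception.
    """
    r = np.asarray(r, dtype=float)
    a = np.zeros(order)
    k = np.zeros(order)
    e = r[0]
    if e <= 0 or not np.isfinite(e):
        return LpcModel(order, a, k, 0.0)
    floor = r[0] * 1e-12
    for m in range(order):
        acc = r[m + 1] - np.dot(a[:m], r[m:0:-1])
        km = acc / e
        if not np.isfinite(km) or abs(km) >= 1.0:
            km = math.copysign(_K_CLAMP, km) if np.isfinite(km) else 0.0
        k[m] = km
        a_rev = a[:m][::-1].copy()
        a[:m] -= km * a_rev
        a[m] = km
        e *= 1.0 - km * km
        if e <= floor:
            # remaining orders carry no information; keep k = 0 there
            e = max(e, 0.0)
            break
    return LpcModel(order, a, k, math.sqrt(max(e, 0.0)))


def compute_lpc(samples: np.ndarray, order: int) -> LpcModel:
    """Fit an LPC model to one real-valued sub-window."""
    samples = np.asarray(samples, dtype=float)
    if order < 1:
        raise ValueError("order must be >= 1")
    if len(samples) <= order:
        raise ValueError(
            f"need more than order={order} samples, got {len(samples)}"
        )
    r = _autocorrelation(samples, order)
    return levinson_durbin(r, order)


def lar_transform(reflection_coefficients: np.ndarray) -> np.ndarray:
    """Elementwise ``log((1 - k)/(1 + k))`` with k clamped to (-1, 1)."""
    k = np.clip(np.asarray(reflection_coefficients, dtype=float), -_K_CLAMP, _K_CLAMP)
    return np.log((1.0 - k) / (1.0 + k))


def inverse_lar(lars: np.ndarray) -> np.ndarray:
    """Inverse of :func:`lar_transform`: ``k = (1 - e^g)/(1 + e^g)``."""
    g = np.exp(np.asarray(lars, dtype=float))
    return (1.0 - g) / (1.0 + g)


def extract_features(window: WindowSample, feature_spec: FeatureSpec) -> FeatureVector:
    """Encode one window as a channel-major LAR vector.

    The window is resampled to ``feature_spec.sample_rate`` if needed, each
    channel is split into non-overlapping sub-windows, each sub-window is
    Hamming-tapered and LPC-encoded, and the LARs are concatenated.
    """
    window_len = window.end - window.start
    n_sub = feature_spec.n_sub_windows(window_len)
    x = window.samples
    if feature_spec.sample_rate != window.sample_rate:
        rec = resample(IQRecording(x, window.sample_rate), feature_spec.sample_rate)
        x = rec.samples
    channels = [x.real] if feature_spec.channels == "i" else [x.real, x.imag]
    sub_len = len(x) // n_sub
    if sub_len <= feature_spec.order:
        raise ValueError(
            f"order {feature_spec.order} too high for sub-windows of "
            f"{sub_len} samples at {feature_spec.sample_rate} Hz"
        )
    taper = np.hamming(sub_len)
    lars = []
    for ch in channels:
        for s in range(n_sub):
            seg = ch[s * sub_len : (s + 1) * sub_len] * taper
            model = levinson_durbin(
                _autocorrelation(seg, feature_spec.order), feature_spec.order
            )
            lars.append(lar_transform(model.reflection_coefficients))
    return FeatureVector(np.concatenate(lars), feature_spec, window.label)


def features_matrix(
    windows: list[WindowSample], feature_spec: FeatureSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a list of windows into an (n, d) design matrix and label array."""
    X = np.stack([extract_features(w, feature_spec).values for w in windows])
    y = np.asarray([w.label for w in windows])
    return X, y


def spectral_envelope(
    lpc_model: LpcModel, freq_grid: np.ndarray, sample_rate: float
) -> np.ndarray:
    """LPC-implied magnitude response ``gain / |A(e^{j 2 pi f / fs})|``."""
    freq_grid = np.asarray(freq_grid, dtype=float)
    if freq_grid.min() < 0 or freq_grid.max() > sample_rate / 2 + 1e-9:
        raise ValueError("freq_grid must lie within [0, sample_rate / 2]")
    a_poly = np.r_[1.0, -lpc_model.prediction_coefficients]
    _, h = sps.freqz(1.0, a_poly, worN=freq_grid, fs=sample_rate)
    return lpc_model.gain * np.abs(h)


def spectrogram(
    window: WindowSample, fmax: float, nperseg: int = 256, noverlap: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """STFT magnitude of the complex IQ signal cropped to [0, fmax].

    Returns ``(freqs, times, magnitude)``; visualization/debugging aid only.
    """
    fs = window.sample_rate
    if fmax > fs / 2:
        raise ValueError("fmax must not exceed Nyquist")
    f, t, z = sps.stft(
        window.samples,
        fs=fs,
        nperseg=min(nperseg, len(window.samples)),
        noverlap=noverlap,
        return_onesided=False,
    )
    order = np.argsort(f)
    f, z = f[order], z[order]
    keep = (f >= 0) & (f <= fmax)
    return f[keep], t, np.abs(z[keep])
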