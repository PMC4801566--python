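"""Time and frequency domain feature extraction (TFFE).

Per channel of a 125-sample x 45-channel segment: 4 time-domain features
(mean, mean absolute deviation, skewness, inter-axis correlation) and 10
frequency-domain features (top-5 FFT magnitudes, top-5 cepstrum values),
giving 14 x 45 = 630 values per segment, ordered feature-major.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "POSITIONS",
    "SENSORS",
    "AXES",
    "FEATURE_NAMES",
    "N_SAMPLES",
    "N_CHANNELS",
    "ChannelMeta",
    "SensorSegment",
    "default_channel_meta",
    "mean_feature",
    "mad_feature",
    "skewness_feature",
    "corr_feature",
    "fft_magnitudes",
    "cepstrum",
    "top_k_peaks",
    "extract_features",
    "extract_matrix",
    "feature_labels",
]

POSITIONS = ("T", "RA", "LA", "RL", "LL")
SENSORS = ("acc", "gyro", "mag")
AXES = ("x", "y", "z")

N_SAMPLES = 125   # rows per 5-s window at 25 Hz
N_CHANNELS = 45   # 5 positions x 3 sensors x 3 axes

FEATURE_NAMES = (
    "mean", "mad", "skewness", "corr",
    "fft_peak1", "fft_peak2", "fft_peak3", "fft_peak4", "fft_peak5",
    "cep_peak1", "cep_peak2", "cep_peak3", "cep_peak4", "cep_peak5",
)

# cyclic intra-triad partner for the correlation feature
_NEXT_AXIS = {"x": "y", "y": "z", "z": "x"}


class ChannelMeta(NamedTuple):
    position: str
    sensor: str
    axis: str

    @property
    def name(self) -> str:
        return f"{self.position}_{self.sensor}_{self.axis}"


def default_channel_meta() -> tuple[ChannelMeta, ...]:
    """Column order: position-major, then acc/gyro/mag, then x/y/z."""
    return tuple(ChannelMeta(p, s, a)
                 for p in POSITIONS for s in SENSORS for a in AXES)


@dataclass
class SensorSegment:
    """One 5-second window of multi-channel sensor data.

    ``data`` has exactly 125 rows (time samples at 25 Hz); columns are
    described one-to-one by ``channel_meta``.
    """

    data: np.ndarray
    channel_meta: tuple[ChannelMeta, ...] = field(default_factory=default_channel_meta)
    label: str | None = None
    subject: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_SAMPLES:
            raise ValueError(
                f"segment must have exactly {N_SAMPLES} rows, got shape {self.data.shape}")
        if self.data.shape[1] != len(self.channel_meta):
            raise ValueError("channel_meta does not match column count")
        if len(set(self.channel_meta)) != len(self.channel_meta):
            raise ValueError("duplicate channel metadata entries")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# time-domain features (population 1/N conventions throughout)
# ---------------------------------------------------------------------------


def mean_feature(s: np.ndarray) -> float:
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty channel")
    return float(np.mean(s))


def mad_feature(s: np.ndarray) -> float:
    """Mean absolute deviation about the mean."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty channel")
    return float(np.mean(np.abs(s - np.mean(s))))


def skewness_feature(s: np.ndarray) -> float:
    """Third central moment over sigma^3; defined as 0 for a constant channel."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty channel")
    d = s - np.mean(s)
    sigma3 = float(np.mean(d ** 2)) ** 1.5  # may underflow for near-constant s
    if sigma3 == 0.0:
        warnings.warn("zero-variance channel in skewness; returning 0")
        return 0.0
    return float(np.mean(d ** 3)) / sigma3


def corr_feature(s_i: np.ndarray, s_j: np.ndarray) -> float:
    """Pearson correlation; 0 (with a warning) if either channel is constant."""
    s_i = np.asarray(s_i, dtype=float)
    s_j = np.asarray(s_j, dtype=float)
    if s_i.shape != s_j.shape:
        raise ValueError("channels must have equal length")
    di = s_i - np.mean(s_i)
    dj = s_j - np.mean(s_j)
    denom = np.sqrt(np.sum(di ** 2) * np.sum(dj ** 2))
    if denom == 0.0:
        warnings.warn("constant channel in correlation; returning 0")
        return 0.0
    return float(np.sum(di * dj) / denom)


# ---------------------------------------------------------------------------
# frequency-domain features
# ---------------------------------------------------------------------------


def fft_magnitudes(s: np.ndarray) -> np.ndarray:
    """Magnitudes of the length-N discrete Fourier transform."""
    s = np.asarray(s, dtype=float)
    if s.shape != (N_SAMPLES,):
        raise ValueError(f"expected a length-{N_SAMPLES} channel, got {s.shape}")
    return np.abs(np.fft.fft(s))


def cepstrum(s: np.ndarray) -> np.ndarray:
    """Real cepstrum: inverse DFT of the log magnitude spectrum.

    A floor of ``1e-12 * max|X|`` guards the logarithm; the all-zero signal
    maps to an all-zero cepstrum with a warning.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (N_SAMPLES,):
        raise ValueError(f"expected a length-{N_SAMPLES} channel, got {s.shape}")
    mag = np.abs(np.fft.fft(s))
    peak = float(np.max(mag))
    if peak == 0.0:
        warnings.warn("all-zero signal; cepstrum set to zero")
        return np.zeros(N_SAMPLES)
    return np.real(np.fft.ifft(np.log(mag + 1e-12 * peak)))


def top_k_peaks(v: np.ndarray, k: int = 5) -> np.ndarray:
    """The k largest values over bins 1..floor(N/2), sorted descending.

    DC (bin 0) is excluded; ties are broken in favour of the lower bin
    index.
    """
    v = np.asarray(v, dtype=float)
    usable = v[1:v.shape[0] // 2 + 1]
    if k > usable.shape[0]:
        raise ValueError(f"k={k} exceeds the {usable.shape[0]} usable bins")
    order = np.argsort(-usable, kind="stable")
    return usable[order[:k]]


# ---------------------------------------------------------------------------
# per-segment extraction
# ---------------------------------------------------------------------------


def _corr_partner_indices(meta: tuple[ChannelMeta, ...]) -> np.ndarray:
    lookup = {m: i for i, m in enumerate(meta)}
    partners = np.empty(len(meta), dtype=int)
    for i, m in enumerate(meta):
        key = ChannelMeta(m.position, m.sensor, _NEXT_AXIS[m.axis])
        partners[i] = lookup.get(key, -1)
    return partners


def extract_features(seg: SensorSegment) -> np.ndarray:
    """630 features from one segment (14 per channel, feature-major order).

    The output vector lays out all per-channel values of the first feature
    type, then the second, etc.: ``values[f * n_channels + ch]``.
    """
    data = seg.data
    n_ch = seg.n_channels
    out = np.zeros((len(FEATURE_NAMES), n_ch))
    partners = _corr_partner_indices(seg.channel_meta)
    for ch in range(n_ch):
        s = data[:, ch]
        out[0, ch] = mean_feature(s)
        out[1, ch] = mad_feature(s)
        out[2, ch] = skewness_feature(s)
        j = partners[ch]
        if j < 0:
            warnings.warn(
                f"channel {seg.channel_meta[ch].name} has no correlation partner; 0 fill")
            out[3, ch] = 0.0
        else:
            out[3, ch] = corr_feature(s, data[:, j])
        out[4:9, ch] = top_k_peaks(fft_magnitudes(s), 5)
        out[9:14, ch] = top_k_peaks(cepstrum(s), 5)
    return out.ravel()


def extract_matrix(segments) -> np.ndarray:
    """Stack :func:`extract_features` over a list of segments: (n, 14*C)."""
    if len(segments) == 0:
        raise ValueError("no segments")
    return np.vstack([extract_features(s) for s in segments])


def feature_labels(channel_meta: tuple[ChannelMeta, ...] | None = None) -> list[str]:
    """Column labels matching the feature-major layout: ``feature:channel``."""
    meta = channel_meta if channel_meta is not None else default_channel_meta()
    return [f"{f}:{m.name}" for f in FEATURE_NAMES for m in meta]
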