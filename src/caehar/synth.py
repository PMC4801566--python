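"""Synthetic data generators.

Two generators make every pipeline stage testable without any external
download: a swiss-roll point cloud (nonlinear-manifold reconstruction
benchmark) and a multi-sensor activity dataset whose structure mirrors the
body-worn recording protocol (19 activities x 8 subjects x 60 segments of
125 samples x 45 channels at 25 Hz).

All generators are pure functions of their config, including the seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .tffe import N_CHANNELS, N_SAMPLES, SensorSegment, default_channel_meta

__all__ = [
    "SwissRollConfig",
    "HARTemplates",
    "HARGenConfig",
    "make_swiss_roll",
    "make_har_dataset",
    "write_dsa_layout",
    "load_default_templates",
]


# ---------------------------------------------------------------------------
# swiss roll
# ---------------------------------------------------------------------------


@dataclass
class SwissRollConfig:
    n_points: int = 2000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


def make_swiss_roll(cfg: SwissRollConfig) -> np.ndarray:
    """Points on a rolled 2-D sheet, min-max normalised to [0, 1] per axis.

    Parametrisation ``(t cos t, height, t sin t)`` with ``t`` uniform on
    ``[1.5 pi, 4.5 pi]`` and height uniform; optional isotropic Gaussian
    jitter before normalisation.
    """
    rng = np.random.default_rng(cfg.seed)
    t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, cfg.n_points)
    height = rng.uniform(0.0, 21.0, cfg.n_points)
    pts = np.column_stack([t * np.cos(t), height, t * np.sin(t)])
    if cfg.noise_sd > 0:
        pts += cfg.noise_sd * rng.standard_normal(pts.shape)
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    span[span == 0] = 1.0  # degenerate axis (n_points == 1)
    return (pts - lo) / span


# ---------------------------------------------------------------------------
# synthetic activity dataset
# ---------------------------------------------------------------------------


@dataclass
class HARTemplates:
    """Per-class signal-generation constants (see data/har_templates.yaml)."""

    sensor_ranges: dict[str, float]
    sensor_amplitude: dict[str, float]
    sensor_offset_scale: dict[str, float]
    noise_fraction: float
    phase_jitter_sd: float
    frequencies_hz: list[float]
    amp_scales: list[float]
    phase_lags: list[float]
    offset_weights: list[list[float]]


def load_default_templates() -> HARTemplates:
    text = (importlib.resources.files("caehar") / "data" / "har_templates.yaml").read_text()
    raw = yaml.safe_load(text)
    return HARTemplates(**raw)


@dataclass
class HARGenConfig:
    n_activities: int = 19
    n_subjects: int = 8
    segments_per_pair: int = 60
    rate_hz: float = 25.0
    subject_jitter_sd: float = 0.1
    seed: int = 0
    templates: HARTemplates = field(default_factory=load_default_templates)

    def __post_init__(self) -> None:
        if min(self.n_activities, self.n_subjects, self.segments_per_pair) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_activities > len(self.templates.frequencies_hz):
            raise ValueError("not enough activity templates")
        nyquist = self.rate_hz / 2.0
        if any(f >= nyquist for f in
               self.templates.frequencies_hz[: self.n_activities]):
            raise ValueError(f"template frequency at or above Nyquist ({nyquist} Hz)")


# fixed rank-3 channel basis for the offset patterns
def _offset_basis(n_channels: int) -> np.ndarray:
    ch = np.arange(n_channels)
    return np.column_stack([
        np.sin(2 * np.pi * ch / n_channels),
        np.cos(2 * np.pi * ch / n_channels),
        np.sin(4 * np.pi * ch / n_channels),
    ])


def make_har_dataset(cfg: HARGenConfig) -> tuple[list[SensorSegment], np.ndarray]:
    """Generate the full synthetic dataset.

    Returns ``n_activities * n_subjects * segments_per_pair`` segments
    (125 x 45 each) plus the matching label array (``a01`` .. ``a19``).
    Channel value = class offset + jittered sinusoid + Gaussian noise,
    clamped to the physical range of the channel's sensor type.
    """
    tpl = cfg.templates
    rng = np.random.default_rng(cfg.seed)
    meta = default_channel_meta()
    n_ch = len(meta)
    basis = _offset_basis(n_ch)                         # (45, 3)
    amp = np.array([tpl.sensor_amplitude[m.sensor] for m in meta])
    off_scale = np.array([tpl.sensor_offset_scale[m.sensor] for m in meta])
    clamp = np.array([tpl.sensor_ranges[m.sensor] for m in meta])
    t = np.arange(N_SAMPLES) / cfg.rate_hz              # (125,)

    segments: list[SensorSegment] = []
    labels: list[str] = []
    axis_idx = np.arange(n_ch) % 3                      # x, y, z within a triad
    triad_idx = np.arange(n_ch) // 3
    n_triads = n_ch // 3 + (n_ch % 3 > 0)
    for a in range(cfg.n_activities):
        w = np.asarray(tpl.offset_weights[a])
        offset = off_scale * (basis @ w)                # (45,)
        freq = tpl.frequencies_hz[a]
        amp_a = amp * tpl.amp_scales[a]
        lag = tpl.phase_lags[a]
        label = f"a{a + 1:02d}"
        for subj in range(1, cfg.n_subjects + 1):
            jitter = 1.0 + cfg.subject_jitter_sd * rng.standard_normal()
            # one random phase per sensor triad; axes y/z lag the x axis by
            # the class phase lag, making inter-axis correlation ~cos(lag)
            base = rng.uniform(0, 2 * np.pi,
                               (cfg.segments_per_pair, 1, n_triads))
            phase = (base[:, :, triad_idx]
                     + lag * axis_idx
                     + tpl.phase_jitter_sd * rng.standard_normal(
                         (cfg.segments_per_pair, 1, n_ch)))
            wave = np.sin(2 * np.pi * freq * t[None, :, None] + phase)
            noise = rng.standard_normal(
                (cfg.segments_per_pair, N_SAMPLES, n_ch))
            block = (offset
                     + amp_a * jitter * wave
                     + tpl.noise_fraction * amp_a * noise)
            np.clip(block, -clamp, clamp, out=block)
            for s in range(cfg.segments_per_pair):
                segments.append(SensorSegment(block[s], meta,
                                              label=label, subject=subj))
                labels.append(label)
    return segments, np.asarray(labels)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_dsa_layout(segments: list[SensorSegment], root_path) -> Path:
    """Write segments as ``a<ii>/p<j>/s<kk>.txt`` comma-separated text files.

    Each file holds 125 lines of 45 values printed with full float64
    precision, so a write -> read round trip is bit-exact.  Segment numbers
    restart at 1 within each activity/subject directory.
    """
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    counters: dict[tuple[str, int], int] = {}
    for seg in segments:
        if seg.label is None or seg.subject is None:
            raise ValueError("segments need label and subject to be laid out")
        key = (seg.label, seg.subject)
        counters[key] = counters.get(key, 0) + 1
        d = root / seg.label / f"p{seg.subject}"
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / f"s{counters[key]:02d}.txt", seg.data,
                   delimiter=",", fmt="%.17g")
    return root
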