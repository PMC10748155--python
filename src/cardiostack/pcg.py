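"""Heart-sound front-end: severity-dependent segmentation, log-Mel
spectrograms, and training-time augmentation (SpecAugment, mixup).

Framing is non-centered with no padding: a 4-s window at 4000 Hz with a
512-sample Hann window and 64-sample hop yields exactly
``1 + (16000 - 512) // 64 == 243`` frames, so the default output grid is
243 x 128. Amplitudes are deliberately not normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from cardiostack.synthetic import GRADES, PcgRecord

__all__ = [
    "PcgPreprocParams",
    "LogMelSegment",
    "DEFAULT_SEGMENT_COUNTS",
    "segment_record",
    "segment_starts",
    "log_mel",
    "mel_filterbank",
    "spec_augment",
    "mixup",
]

# Per-grade oversampling targets reusing the published per-severity
# multiplying factors (base x3; severe AS x20, MR x44, LVD x42).
DEFAULT_SEGMENT_COUNTS: dict[str, dict[str, int]] = {
    "AS": {"none": 3, "mild": 3, "moderate": 3, "severe": 20},
    "MR": {"none": 3, "mild": 3, "moderate": 3, "severe": 44},
    "LVD": {"none": 3, "mild": 3, "moderate": 3, "severe": 42},
}


@dataclass
class PcgPreprocParams:
    window_length_s: float = 4.0
    fft_window: int = 512
    hop: int = 64
    n_mels: int = 128
    segment_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_COUNTS["AS"])
    )
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if not (self.fft_window > self.hop > 0):
            raise ValueError("require fft_window > hop > 0")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be positive")
        unknown = set(self.segment_counts) - set(GRADES)
        if unknown:
            raise ValueError(f"unknown grades in segment_counts: {unknown}")
        if self.segment_counts.get("severe", 1) < self.segment_counts.get("none", 1):
            raise ValueError("segment_counts[severe] must be >= segment_counts[none]")


@dataclass
class LogMelSegment:
    """time_frames x mel_bins log-Mel grid with its provenance and label."""

    values: np.ndarray
    source: tuple[str, str, float]  # (patient_id, site, start time s)
    label: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def segment_starts(duration: float, window_length_s: float, k: int) -> np.ndarray:
    """Evenly spaced start times: start_i = i * (D - w) / (k - 1)."""
    if k < 1:
        raise ValueError("segment count must be >= 1")
    if k == 1:
        return np.zeros(1)
    return np.arange(k) * (duration - window_length_s) / (k - 1)


def segment_record(
    record: PcgRecord, params: PcgPreprocParams, grade: str
) -> list[np.ndarray]:
    """Cut ``segment_counts[grade]`` windows of ``window_length_s`` seconds.

    Start times are evenly spaced over the feasible range and may overlap.
    """
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}")
    w = round(params.window_length_s * record.sample_rate)
    if record.samples.size < w:
        raise ValueError(
            f"record of {record.samples.size} samples shorter than "
            f"{params.window_length_s}-s window ({w} samples)"
        )
    k = params.segment_counts.get(grade, params.segment_counts["none"])
    starts = segment_starts(record.duration, params.window_length_s, k)
    out = []
    for s in starts:
        i0 = round(s * record.sample_rate)
        out.append(record.samples[i0 : i0 + w])
    return out


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel bank spanning 0 .. sample_rate/2.

    Returns (filters of shape (n_mels, n_fft//2 + 1), center frequencies Hz).
    """
    n_bins = n_fft // 2 + 1
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(sample_rate / 2), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0.0, sample_rate / 2, n_bins)
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / (ctr - lo)
        down = (hi - fft_freqs) / (hi - ctr)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb, hz_pts[1:-1]


def log_mel(
    window: np.ndarray,
    params: PcgPreprocParams,
    sample_rate: int = 4000,
    source: tuple[str, str, float] = ("", "", 0.0),
    label: int = 0,
) -> LogMelSegment:
    """Non-centered STFT power -> triangular Mel bank -> log(x + floor)."""
    window = np.asarray(window, dtype=float)
    if window.size < params.fft_window:
        raise ValueError(
            f"input of {window.size} samples shorter than fft_window={params.fft_window}"
        )
    frames = sliding_window_view(window, params.fft_window)[:: params.hop]
    taper = get_window("hann", params.fft_window, fftbins=True)
    spec = np.abs(np.fft.rfft(frames * taper, axis=1)) ** 2
    fb, _ = mel_filterbank(params.n_mels, params.fft_window, sample_rate)
    values = np.log(spec @ fb.T + params.log_floor)
    return LogMelSegment(values=values, source=source, label=label)


def spec_augment(
    segment: LogMelSegment,
    freq_mask_width: int = 16,
    time_mask_width: int = 24,
    n_masks: int = 2,
    rng: np.random.Generator | None = None,
) -> LogMelSegment:
    """Mask ``n_masks`` random frequency bands and time bands with the grid mean."""
    rng = rng or np.random.default_rng()
    n_t, n_f = segment.values.shape
    if freq_mask_width > n_f or time_mask_width > n_t:
        raise ValueError(
            f"mask widths ({freq_mask_width} freq, {time_mask_width} time) exceed "
            f"grid {n_t} x {n_f}"
        )
    out = segment.values.copy()
    fill = out.mean()
    for _ in range(n_masks):
        if freq_mask_width > 0:
            f0 = int(rng.integers(0, n_f - freq_mask_width + 1))
            out[:, f0 : f0 + freq_mask_width] = fill
        if time_mask_width > 0:
            t0 = int(rng.integers(0, n_t - time_mask_width + 1))
            out[t0 : t0 + time_mask_width, :] = fill
    return LogMelSegment(values=out, source=segment.source, label=segment.label)


def mixup(
    seg_a: np.ndarray,
    seg_b: np.ndarray,
    label_a: int,
    label_b: int,
    alpha: float = 0.2,
    rng: np.random.Generator | None = None,
    lam: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Convex combination of two inputs and their one-hot labels.

    lambda ~ Beta(alpha, alpha) unless forced via ``lam``. Returns the mixed
    grid and a soft label pair summing to 1.
    """
    seg_a = np.asarray(seg_a, dtype=float)
    seg_b = np.asarray(seg_b, dtype=float)
    if seg_a.shape != seg_b.shape:
        raise ValueError(f"shape mismatch: {seg_a.shape} vs {seg_b.shape}")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if lam is None:
        rng = rng or np.random.default_rng()
        lam = float(rng.beta(alpha, alpha))
    one_hot = np.eye(2)
    mixed = lam * seg_a + (1.0 - lam) * seg_b
    soft = lam * one_hot[label_a] + (1.0 - lam) * one_hot[label_b]
    return mixed, soft
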