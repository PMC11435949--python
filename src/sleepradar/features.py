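"""Statistical motion features from the range-FFT spectrogram.

Micro-motion (respiration, heartbeat) modulates the range-FFT magnitude of
the bins occupied by the torso. A sliding window of W slow-time samples,
stepped by S, yields the per-bin, per-window population standard deviation

    std[k, i] = sqrt( (1/W) * sum_t (|F|[k, t] - mean_i)^2 ),  t in [i S, i S + W)

The K1 contiguous range bins with the largest total standard deviation (the
"bin window") are retained, and consecutive spans of the recording become
K1 x N_W feature images. With the default radar timing (640 chirps/s),
W = 320 is 0.5 s, S = 64 is 0.1 s, and a 6-s span gives N_W = 60 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .radar import REPORT_BIN_PITCH_M, one_hot_label
from .spectrum import RangeSpectrogram


@dataclass(frozen=True)
class FeatureParams:
    """Sliding-window geometry of the feature extractor.

    window_w and step_s are counts of slow-time samples; span_s is the
    recording time covered by one feature image. Defaults: W = 320
    (10 frames), S = 64 (2 frames), 6-s span, K1 = 40 retained bins.
    """

    window_w: int = 320
    step_s: int = 64
    span_s: float = 6.0
    k1: int = 40

    def __post_init__(self) -> None:
        if self.window_w <= 0 or self.step_s <= 0:
            raise ValueError("window_w and step_s must be positive")
        if self.step_s > self.window_w:
            raise ValueError("step_s must not exceed window_w")
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if self.span_s <= 0:
            raise ValueError("span_s must be positive")


@dataclass
class MotionFeatureImage:
    """K1 x N_W non-negative std-feature matrix with its (soft) 3-class label."""

    values: np.ndarray
    bin_offset: int
    label: np.ndarray  # probability vector over (supine, lateral, prone)
    subject_id: str
    posture: str = ""
    column_duration_s: float = 0.1
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.label = np.asarray(self.label, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature image must be 2-D (range bins x windows)")
        if np.any(self.values < -1e-12):
            raise ValueError("feature values must be non-negative")
        if self.label.ndim != 1 or not np.isclose(self.label.sum(), 1.0):
            raise ValueError("label must be a probability vector summing to 1")
        if np.any(self.label < 0):
            raise ValueError("label probabilities must be non-negative")

    @property
    def hard_class(self) -> int:
        return int(np.argmax(self.label))


def sliding_std(magnitude: np.ndarray, params: FeatureParams) -> np.ndarray:
    """Per-bin sliding-window population standard deviation.

    Produces N_W = floor(N / S) windows starting at multiples of S; the tail
    of the signal is edge-replicated by up to W - S samples so the final
    windows are full length (this reproduces N_W = N/S, e.g. 60 windows for
    a 6-s span at the default timing).
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if magnitude.ndim != 2:
        raise ValueError("expected a 2-D magnitude spectrogram (bins x slow time)")
    n = magnitude.shape[1]
    w, s = params.window_w, params.step_s
    if n < w:
        raise ValueError(f"slow-time length {n} shorter than window {w}")
    n_windows = n // s
    pad = max(0, (n_windows - 1) * s + w - n)
    if pad:
        magnitude = np.pad(magnitude, ((0, 0), (0, pad)), mode="edge")
    windows = sliding_window_view(magnitude, w, axis=1)[:, ::s][:, :n_windows]
    return windows.std(axis=2)  # population (1/W) normalization


def select_bin_window(stdmat: np.ndarray, k1: int) -> int:
    """Offset of the K1-row window maximizing the summed standard deviation.

    Ties break toward the smallest offset.
    """
    stdmat = np.asarray(stdmat, dtype=np.float64)
    k = stdmat.shape[0]
    if k1 > k:
        raise ValueError(f"k1={k1} exceeds the number of range bins {k}")
    row_sums = stdmat.sum(axis=1)
    window_sums = sliding_window_view(row_sums, k1).sum(axis=1)
    return int(np.argmax(window_sums))


def bin_window_span_m(k1: int, bin_pitch_m: float = REPORT_BIN_PITCH_M) -> float:
    """Physical distance covered by the K1-bin window (reporting pitch 4 cm)."""
    return k1 * bin_pitch_m


def _segment_geometry(spectrogram: RangeSpectrogram, params: FeatureParams):
    seg_len = int(round(params.span_s * spectrogram.slow_time_rate_hz))
    if spectrogram.n_chirps < seg_len:
        raise ValueError(
            f"recording ({spectrogram.n_chirps} chirps) shorter than one "
            f"{params.span_s}-s span ({seg_len} chirps)"
        )
    n_segments = spectrogram.n_chirps // seg_len
    column_duration = params.step_s / spectrogram.slow_time_rate_hz
    return seg_len, n_segments, column_duration


def extract_feature_images(
    spectrogram: RangeSpectrogram,
    params: FeatureParams | None = None,
    label: np.ndarray | None = None,
    subject_id: str | None = None,
) -> list[MotionFeatureImage]:
    """Slice a recording into spans and build one motion-feature image per span.

    Per span: sliding-window std over all K bins, bin-window selection by
    the summed-std criterion, crop to K1 rows. The label defaults to the
    one-hot encoding of the spectrogram's posture.
    """
    params = params or FeatureParams()
    if label is None:
        label = one_hot_label(spectrogram.posture)
    if subject_id is None:
        subject_id = spectrogram.subject_id
    seg_len, n_segments, column_duration = _segment_geometry(spectrogram, params)

    images = []
    for i in range(n_segments):
        segment = spectrogram.magnitude[:, i * seg_len : (i + 1) * seg_len]
        stdmat = sliding_std(segment, params)
        offset = select_bin_window(stdmat, params.k1)
        images.append(
            MotionFeatureImage(
                values=stdmat[offset : offset + params.k1],
                bin_offset=offset,
                label=label,
                subject_id=subject_id,
                posture=spectrogram.posture,
                column_duration_s=column_duration,
            )
        )
    return images


def extract_raw_images(
    spectrogram: RangeSpectrogram,
    params: FeatureParams | None = None,
    label: np.ndarray | None = None,
    subject_id: str | None = None,
) -> list[MotionFeatureImage]:
    """Downsampled raw range-FFT magnitude images with the same geometry.

    Ablation input: instead of sliding-window std, each span's magnitude is
    block-averaged along slow time to N_W columns and cropped to the K1-row
    window with the largest total magnitude. Shapes and labels match
    :func:`extract_feature_images` so models can train on either.
    """
    params = params or FeatureParams()
    if label is None:
        label = one_hot_label(spectrogram.posture)
    if subject_id is None:
        subject_id = spectrogram.subject_id
    seg_len, n_segments, column_duration = _segment_geometry(spectrogram, params)
    n_w = seg_len // params.step_s
    block = seg_len // n_w

    images = []
    for i in range(n_segments):
        segment = spectrogram.magnitude[:, i * seg_len : (i + 1) * seg_len]
        reduced = segment[:, : n_w * block].reshape(segment.shape[0], n_w, block).mean(axis=2)
        offset = select_bin_window(reduced, params.k1)
        images.append(
            MotionFeatureImage(
                values=reduced[offset : offset + params.k1],
                bin_offset=offset,
                label=label,
                subject_id=subject_id,
                posture=spectrogram.posture,
                column_duration_s=column_duration,
            )
        )
    return images
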