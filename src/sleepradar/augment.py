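"""Feature-image augmentation: time shift, range shift, and mix-up.

Time shifts rotate the slow-time columns circularly (respiration is
quasi-periodic, so wrapped columns remain plausible and no columns are
emptied); range shifts translate the range rows with zero fill (body energy
must not wrap across the range axis). Mix-up forms convex combinations of
two images from *different* classes and of their one-hot labels, with the
weight drawn from a symmetric Beta(alpha, alpha), alpha < 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np

from .features import MotionFeatureImage

Interval = tuple[float, float]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation policy; offsets are confined to symmetric two-sided bands."""

    time_shift_s: tuple[Interval, Interval] = ((-1.0, -0.5), (0.5, 1.0))
    range_shift_bins: tuple[Interval, Interval] = ((-10, -5), (5, 10))
    mixup_alpha: float = 0.4
    multiplicity: int = 2
    enable_time_shift: bool = True
    enable_range_shift: bool = True
    enable_mixup: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mixup_alpha < 1.0:
            raise ValueError("mixup_alpha must lie in (0, 1)")
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be non-negative")
        for neg, pos in (self.time_shift_s, self.range_shift_bins):
            if not (neg[0] <= neg[1] <= 0 <= pos[0] <= pos[1]):
                raise ValueError("shift bands must be one negative and one positive interval")


def time_shift(img: MotionFeatureImage, offset_s: float) -> MotionFeatureImage:
    """Circularly rotate the slow-time columns by a whole-column offset."""
    cols = offset_s / img.column_duration_s
    if abs(cols - round(cols)) > 1e-9:
        raise ValueError(
            f"offset {offset_s} s is not a whole number of {img.column_duration_s}-s columns"
        )
    shifted = np.roll(img.values, int(round(cols)), axis=1)
    return dc_replace(
        img,
        values=shifted,
        provenance={"transform": "time_shift", "offset_s": float(offset_s),
                    "source": img.subject_id},
    )


def range_shift(img: MotionFeatureImage, offset_bins: int) -> MotionFeatureImage:
    """Translate the range rows by ``offset_bins``, zero-filling vacated rows."""
    k1 = img.values.shape[0]
    offset_bins = int(offset_bins)
    if abs(offset_bins) >= k1:
        raise ValueError(f"|offset| {abs(offset_bins)} must be < image height {k1}")
    shifted = np.zeros_like(img.values)
    if offset_bins >= 0:
        shifted[offset_bins:] = img.values[: k1 - offset_bins]
    else:
        shifted[:offset_bins] = img.values[-offset_bins:]
    return dc_replace(
        img,
        values=shifted,
        provenance={"transform": "range_shift", "offset_bins": offset_bins,
                    "source": img.subject_id},
    )


def mixup(
    img_i: MotionFeatureImage, img_j: MotionFeatureImage, lam: float
) -> MotionFeatureImage:
    """Convex combination of two feature images and their labels."""
    if img_i.values.shape != img_j.values.shape:
        raise ValueError("mix-up requires images of identical shape")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    values = lam * img_i.values + (1.0 - lam) * img_j.values
    label = lam * img_i.label + (1.0 - lam) * img_j.label
    return MotionFeatureImage(
        values=values,
        bin_offset=img_i.bin_offset,
        label=label,
        subject_id=img_i.subject_id,
        posture=img_i.posture if lam >= 0.5 else img_j.posture,
        column_duration_s=img_i.column_duration_s,
        provenance={"transform": "mixup", "lam": float(lam),
                    "sources": (img_i.subject_id, img_j.subject_id)},
    )


def _sample_two_sided(rng: np.random.Generator, bands: tuple[Interval, Interval]) -> float:
    lo, hi = bands[int(rng.integers(2))]
    return float(rng.uniform(lo, hi))


def sample_time_shift_columns(rng: np.random.Generator, config: AugmentConfig,
                              column_duration_s: float) -> int:
    """Draw a time offset in seconds from the configured bands, as whole columns."""
    return int(round(_sample_two_sided(rng, config.time_shift_s) / column_duration_s))


def sample_range_shift_bins(rng: np.random.Generator, config: AugmentConfig) -> int:
    return int(round(_sample_two_sided(rng, config.range_shift_bins)))


def augment_dataset(
    images: Sequence[MotionFeatureImage],
    config: AugmentConfig | None = None,
) -> list[MotionFeatureImage]:
    """Expand a training set with shifted and mixed-up copies, seeded.

    Per multiplicity round, every image contributes one copy with the
    enabled shifts applied (time then range) and, if mix-up is enabled, one
    mixed image formed with a random partner from a different class. The
    input images are returned first, untouched.
    """
    config = config or AugmentConfig()
    images = list(images)
    if config.multiplicity == 0 or not (
        config.enable_time_shift or config.enable_range_shift or config.enable_mixup
    ):
        return images
    if len(images) < 2:
        raise ValueError("augmentation needs at least two images")
    classes = np.array([img.hard_class for img in images])
    if config.enable_mixup and np.unique(classes).size < 2:
        raise ValueError("mix-up requires images from at least two classes")

    rng = np.random.default_rng(config.seed)
    out = list(images)
    for _ in range(config.multiplicity):
        if config.enable_time_shift or config.enable_range_shift:
            for img in images:
                aug = img
                if config.enable_time_shift:
                    cols = sample_time_shift_columns(rng, config, img.column_duration_s)
                    aug = time_shift(aug, cols * img.column_duration_s)
                if config.enable_range_shift:
                    aug = range_shift(aug, sample_range_shift_bins(rng, config))
                out.append(aug)
        if config.enable_mixup:
            for idx, img in enumerate(images):
                partners = np.flatnonzero(classes != classes[idx])
                j = int(rng.choice(partners))
                lam = float(rng.beta(config.mixup_alpha, config.mixup_alpha))
                out.append(mixup(img, images[j], lam))
    return out
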