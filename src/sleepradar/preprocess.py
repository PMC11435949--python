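"""Two consecutive mean-subtraction steps applied to the raw IF matrix.

Step 1 subtracts, from every fast-time row, its mean over slow time
(R_mn - mean_i R_mi); step 2 subtracts, from every chirp column of the
result, its mean over fast time. Together they null the per-row slow-time
mean (removing the stationary part of every range response, i.e. static
reflectors) and the per-chirp offset. Note the conventional names are
swapped relative to the effect: the first, row-wise step is what removes
static clutter, the second, column-wise step removes a per-chirp DC offset;
the formulas are implemented exactly as specified here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .radar import RadarConfig, RawCube


def suppress_dc(samples: np.ndarray) -> np.ndarray:
    """Subtract each fast-time row's slow-time mean (first mean-subtraction step).

    Parameters
    ----------
    samples
        M x N real matrix (or a :class:`RawCube`), M fast-time rows,
        N slow-time columns, N >= 2.
    """
    if isinstance(samples, RawCube):
        samples = samples.samples
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.size == 0:
        raise ValueError("expected a non-empty 2-D fast-time x slow-time matrix")
    if samples.shape[1] < 2:
        raise ValueError("need at least two chirps (slow-time samples)")
    return samples - samples.mean(axis=1, keepdims=True)


def suppress_clutter(samples: np.ndarray) -> np.ndarray:
    """Subtract each chirp column's fast-time mean (second mean-subtraction step)."""
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.size == 0:
        raise ValueError("expected a non-empty 2-D fast-time x slow-time matrix")
    if samples.shape[0] < 2:
        raise ValueError("need at least two fast-time samples per chirp")
    return samples - samples.mean(axis=0, keepdims=True)


@dataclass
class CleanCube:
    """Mean-subtracted IF matrix, same shape as its source cube."""

    samples: np.ndarray
    config: RadarConfig
    subject_id: str
    posture: str
    start_time_s: float = 0.0


def preprocess_cube(cube: RawCube) -> CleanCube:
    """Apply both mean-subtraction steps to a raw cube."""
    clean = suppress_clutter(suppress_dc(cube.samples))
    return CleanCube(
        samples=clean,
        config=cube.config,
        subject_id=cube.subject_id,
        posture=cube.posture,
        start_time_s=cube.start_time_s,
    )
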