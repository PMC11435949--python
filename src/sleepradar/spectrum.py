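"""Range Fourier transform of each chirp and the magnitude spectrogram.

Each chirp is treated as quasi-static (zero relative velocity within one
chirp), so the M-point DFT of its fast-time samples places every reflector
at the frequency bin matching its beat frequency f0 = 2 D s / c. Only the
one-sided half (K = M/2 bins) is retained; the IF signal is real, so the
upper half is redundant. No window function is applied (rectangular) and
the DFT length equals M (no zero padding).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CleanCube
from .radar import C_LIGHT, RadarConfig


@dataclass
class RangeSpectrogram:
    """One-sided range-FFT of a recording: K range bins x N chirps."""

    values: np.ndarray  # complex K x N
    magnitude: np.ndarray  # |values|, K x N
    bin_pitch_m: float  # distance per FFT bin
    slow_time_rate_hz: float  # chirps per second
    config: RadarConfig
    subject_id: str = ""
    posture: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_chirps(self) -> int:
        return self.values.shape[1]


def range_fft(clean: CleanCube) -> RangeSpectrogram:
    """Per-chirp M-point DFT, keeping bins 0..M/2-1 and their magnitudes."""
    samples = np.asarray(clean.samples, dtype=np.float64)
    m = samples.shape[0]
    if m % 2 != 0:
        raise ValueError(f"fast-time length must be even for a one-sided spectrum, got {m}")
    k = m // 2
    values = np.fft.fft(samples, axis=0)[:k]
    return RangeSpectrogram(
        values=values,
        magnitude=np.abs(values),
        bin_pitch_m=clean.config.fft_bin_pitch_m,
        slow_time_rate_hz=clean.config.chirps_per_second,
        config=clean.config,
        subject_id=clean.subject_id,
        posture=clean.posture,
    )


def predicted_peak_bin(config: RadarConfig, distance_m: float) -> int:
    """Range-FFT bin where a static reflector at the given distance lands.

    The beat frequency is f0 = 2 D s / c; on an M-point DFT sampled at Ts it
    falls on bin f0 * M * Ts.
    """
    f0 = 2.0 * distance_m * config.slope_hz_per_s / C_LIGHT
    return int(round(f0 * config.samples_per_chirp * config.sample_interval_s))


def unwrapped_phase(spectrogram: RangeSpectrogram, bin_index: int) -> np.ndarray:
    """Slow-time phase at one range bin, unwrapped chirp-to-chirp.

    For a reflector on that bin the phase tracks 4*pi*d(t)/lambda up to a
    constant, so it demodulates sub-wavelength chest displacement.
    """
    return np.unwrap(np.angle(spectrogram.values[bin_index]))


def estimate_respiration_rate_hz(
    spectrogram: RangeSpectrogram,
    bin_index: int,
    band_hz: tuple[float, float] = (0.05, 1.0),
) -> float:
    """Dominant breathing frequency from the phase at the torso bin.

    The phase is unwrapped on the full chirp series (chirp spacing is fine
    enough that successive phase steps stay below pi even across the
    inter-frame gap), then decimated to one sample per frame so the series
    is uniformly sampled at the frame rate before spectral peak picking.
    """
    config = spectrogram.config
    phase = unwrapped_phase(spectrogram, bin_index)
    per_frame = phase[:: config.chirps_per_frame]
    rate = config.frame_rate_hz
    per_frame = per_frame - per_frame.mean()
    # 4x zero padding refines the peak location below the 1/duration grid
    n_fft = 4 * per_frame.size
    amp = np.abs(np.fft.rfft(per_frame, n=n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValueError("recording too short to resolve the requested band")
    return float(freqs[in_band][np.argmax(amp[in_band])])
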