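"""Radar parameterization, derived quantities, and the raw IF-data container.

An FMCW radar transmits linear frequency sweeps ("chirps"). Mixing the echo
with the transmitted chirp yields an intermediate-frequency (IF) beat tone
whose frequency is proportional to target range. The raw recording used by
the rest of the pipeline is the fast-time x slow-time matrix of real IF
samples: one column per chirp (M = samples per chirp), columns ordered by
chirp index across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

#: Speed of light [m/s]; printed range resolutions are rounded displays of c/(2B).
C_LIGHT = 2.99792458e8

#: Acquisition postures, in acquisition order.
POSTURES_4 = ("supine", "right_lateral", "left_lateral", "prone")

#: The three classes actually recognized; both lateral postures collapse to one.
CLASS_NAMES = ("supine", "lateral", "prone")

_POSTURE_TO_CLASS = {
    "supine": 0,
    "left_lateral": 1,
    "right_lateral": 1,
    "prone": 2,
}

#: Reporting pitch [m] used for physical-span statements about the bin window
#: (40 bins x 0.04 m = 1.6 m of torso coverage). Distinct from the physical
#: resolution c/(2B); both notions are kept deliberately.
REPORT_BIN_PITCH_M = 0.04


@dataclass(frozen=True)
class RadarConfig:
    """Transmit/sampling parameters of the radar, with derived quantities.

    Defaults are the working parameters of a 58-GHz single-antenna FMCW
    sensor: 5 GHz sweep bandwidth, 133 us chirps repeated every 463 us,
    32 chirps per 20-Hz frame, 128 ADC samples per chirp at 1 MHz.
    """

    bandwidth_hz: float = 5.0e9
    start_frequency_hz: float = 58.0e9
    chirp_duration_s: float = 133e-6
    chirp_repetition_s: float = 463e-6
    samples_per_chirp: int = 128
    chirps_per_frame: int = 32
    frame_rate_hz: float = 20.0
    adc_rate_hz: float = 1.0e6

    def __post_init__(self) -> None:
        for name in (
            "bandwidth_hz",
            "start_frequency_hz",
            "chirp_duration_s",
            "chirp_repetition_s",
            "samples_per_chirp",
            "chirps_per_frame",
            "frame_rate_hz",
            "adc_rate_hz",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"RadarConfig.{name} must be strictly positive, got {value!r}")
        if self.samples_per_chirp / self.adc_rate_hz > self.chirp_duration_s:
            raise ValueError(
                "ADC window does not fit inside a chirp: "
                f"{self.samples_per_chirp} samples at {self.adc_rate_hz} Hz "
                f"exceed the chirp duration {self.chirp_duration_s} s"
            )
        if self.chirp_repetition_s < self.chirp_duration_s:
            raise ValueError("chirp_repetition_s must be >= chirp_duration_s")
        if self.chirps_per_frame * self.chirp_repetition_s > 1.0 / self.frame_rate_hz:
            raise ValueError("chirp burst does not fit inside one frame period")

    # ---- derived quantities -------------------------------------------------

    @property
    def slope_hz_per_s(self) -> float:
        """Chirp slope s = B / T_c [Hz/s]."""
        return self.bandwidth_hz / self.chirp_duration_s

    @property
    def wavelength_m(self) -> float:
        """Carrier wavelength lambda = c / f_start [m]."""
        return C_LIGHT / self.start_frequency_hz

    @property
    def range_resolution_m(self) -> float:
        """Physical range resolution c / (2B) [m]."""
        return C_LIGHT / (2.0 * self.bandwidth_hz)

    @property
    def sample_interval_s(self) -> float:
        """Fast-time sampling interval Ts = 1 / ADC rate [s]."""
        return 1.0 / self.adc_rate_hz

    @property
    def chirps_per_second(self) -> float:
        """Slow-time sample rate = chirps per frame x frame rate [1/s]."""
        return self.chirps_per_frame * self.frame_rate_hz

    @property
    def n_range_bins(self) -> int:
        """One-sided spectrum length K = M / 2."""
        return self.samples_per_chirp // 2

    @property
    def fft_bin_pitch_m(self) -> float:
        """Distance spanned by one range-FFT bin [m].

        Bin k corresponds to beat frequency k / (M Ts), hence distance
        k * c / (2 s M Ts). With the ADC window shorter than the chirp
        this is slightly coarser than c/(2B).
        """
        return C_LIGHT / (
            2.0 * self.slope_hz_per_s * self.samples_per_chirp * self.sample_interval_s
        )

    @property
    def max_unambiguous_range_m(self) -> float:
        """Largest target distance representable in the one-sided spectrum."""
        return self.n_range_bins * self.fft_bin_pitch_m

    # ---- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "RadarConfig":
        fields = {k: mapping[k] for k in cls.__dataclass_fields__ if k in mapping}
        return cls(**fields)


def derived_params(config: RadarConfig) -> dict:
    """All derived radar quantities as a plain mapping (pure function)."""
    return {
        "slope_hz_per_s": config.slope_hz_per_s,
        "wavelength_m": config.wavelength_m,
        "range_resolution_m": config.range_resolution_m,
        "chirps_per_second": config.chirps_per_second,
        "samples_per_second_slow": config.chirps_per_second,
    }


def map_to_3class(posture: str) -> int:
    """Collapse the four acquisition postures onto the three recognized classes.

    supine -> 0, left/right lateral -> 1, prone -> 2.
    """
    try:
        return _POSTURE_TO_CLASS[posture]
    except KeyError:
        raise ValueError(
            f"unknown posture {posture!r}; expected one of {sorted(_POSTURE_TO_CLASS)}"
        ) from None


def one_hot_label(posture: str) -> np.ndarray:
    """3-class one-hot probability vector for an acquisition posture."""
    label = np.zeros(len(CLASS_NAMES), dtype=np.float64)
    label[map_to_3class(posture)] = 1.0
    return label


def chirp_times(config: RadarConfig, n_chirps: int) -> np.ndarray:
    """Start time of each chirp [s], honouring the intra-frame burst structure.

    Chirps within a frame are spaced by the chirp repetition time; the
    remainder of the frame period (the idle gap after the burst) is dead time.
    """
    n = np.arange(n_chirps)
    frame = n // config.chirps_per_frame
    within = n % config.chirps_per_frame
    return frame / config.frame_rate_hz + within * config.chirp_repetition_s


@dataclass
class RawCube:
    """Fast-time x slow-time real IF sample matrix with acquisition metadata."""

    samples: np.ndarray
    config: RadarConfig
    subject_id: str
    posture: str
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("RawCube.samples must be a 2-D fast-time x slow-time matrix")
        if self.samples.shape[0] != self.config.samples_per_chirp:
            raise ValueError(
                f"row count {self.samples.shape[0]} != samples_per_chirp "
                f"{self.config.samples_per_chirp}"
            )
        if self.samples.shape[1] % self.config.chirps_per_frame != 0:
            raise ValueError("slow-time length must be a whole number of frames")
        if self.posture not in POSTURES_4:
            raise ValueError(f"unknown posture {self.posture!r}")

    @property
    def n_chirps(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_chirps / self.config.chirps_per_second

    @property
    def class_index(self) -> int:
        return map_to_3class(self.posture)
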