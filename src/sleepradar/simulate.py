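"""Synthetic FMCW bed-scene simulator.

Generates labeled raw IF cubes with the statistical structure the pipeline
assumes: a dominant torso reflector at 0.6-1.2 m whose distance is modulated
by quasi-periodic chest displacement (respiration 0.2-0.4 Hz at 1-12 mm,
heartbeat near 1.1 Hz at 0.1-0.5 mm), posture-dependent motion amplitude and
spatial spread across adjacent range bins, static clutter reflectors, a DC
offset, and additive Gaussian noise.

Each chirp is quasi-static: the fast-time samples of chirp n follow the real
IF tone

    x(m) = A sin(2 pi f0 Ts m + phi0),   f0 = 2 s d(t_n) / c,   phi0 = 4 pi d(t_n) / lambda

with the reflector distance d frozen at the chirp start time t_n. The
simulator is the stand-in for a private 16-volunteer recording campaign and
is first-class, tested code; what it does and does not emulate is laid out
in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .radar import (
    C_LIGHT,
    POSTURES_4,
    RadarConfig,
    RawCube,
    chirp_times,
)


@dataclass(frozen=True)
class SceneConfig:
    """One subject-posture bed scene seen by the radar."""

    torso_distance_m: float = 0.9
    respiration_rate_hz: float = 0.25
    respiration_amplitude_m: float = 0.006
    heartbeat_rate_hz: float = 1.1
    heartbeat_amplitude_m: float = 0.0003
    motion_spread_bins: int = 3
    reflector_amplitude: float = 1.0
    clutter: tuple = ((0.45, 0.4), (1.5, 0.3))  # (distance_m, amplitude) static reflectors
    dc_offset: float = 0.05
    noise_sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.torso_distance_m > 0:
            raise ValueError("torso_distance_m must be positive")
        for name in ("respiration_rate_hz", "heartbeat_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "respiration_amplitude_m",
            "heartbeat_amplitude_m",
            "reflector_amplitude",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.motion_spread_bins < 1:
            raise ValueError("motion_spread_bins must be >= 1")


@dataclass(frozen=True)
class PosturePreset:
    """Per-posture parameter ranges for dataset generation.

    The three recognized classes are separable by construction: supine
    breathes with the largest chest excursion spread over the most range
    bins, lateral the smallest, prone intermediate with a damped reflector
    (the mattress absorbs part of the return).
    """

    posture: str
    respiration_amplitude_range_m: tuple[float, float]
    motion_spread_range_bins: tuple[int, int]
    reflector_amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.posture not in POSTURES_4:
            raise ValueError(f"unknown posture {self.posture!r}")


def default_presets() -> list[PosturePreset]:
    """Presets for the four acquisition postures (both laterals share one)."""
    lateral = dict(
        respiration_amplitude_range_m=(0.001, 0.004),
        motion_spread_range_bins=(1, 3),
    )
    return [
        PosturePreset(
            "supine",
            respiration_amplitude_range_m=(0.006, 0.012),
            motion_spread_range_bins=(4, 6),
        ),
        PosturePreset("right_lateral", **lateral),
        PosturePreset("left_lateral", **lateral),
        PosturePreset(
            "prone",
            respiration_amplitude_range_m=(0.003, 0.007),
            motion_spread_range_bins=(2, 4),
            reflector_amplitude_scale=0.7,
        ),
    ]


def chest_displacement(scene: SceneConfig, t: np.ndarray) -> np.ndarray:
    """Radial torso distance d(t): baseline plus two sinusoidal micro-motions.

    d(t) = D + A_r sin(2 pi f_r t + phi_r) + A_h sin(2 pi f_h t + phi_h),
    with the two phases drawn once from the scene's seeded RNG.
    """
    t = np.asarray(t, dtype=np.float64)
    if t.size == 0:
        raise ValueError("time vector must be non-empty")
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("time vector must be monotone non-decreasing")
    rng = np.random.default_rng(scene.seed)
    phi_r, phi_h = rng.uniform(0.0, 2.0 * np.pi, size=2)
    return (
        scene.torso_distance_m
        + scene.respiration_amplitude_m * np.sin(2 * np.pi * scene.respiration_rate_hz * t + phi_r)
        + scene.heartbeat_amplitude_m * np.sin(2 * np.pi * scene.heartbeat_rate_hz * t + phi_h)
    )


def _if_tone(
    config: RadarConfig, amplitude: float, distance: np.ndarray | float
) -> np.ndarray:
    """Real IF tone matrix (M x N) for a reflector at distance(s) d(t_n)."""
    d = np.atleast_1d(np.asarray(distance, dtype=np.float64))
    f0 = 2.0 * d * config.slope_hz_per_s / C_LIGHT
    phi0 = 4.0 * np.pi * d / config.wavelength_m
    m = np.arange(config.samples_per_chirp, dtype=np.float64)[:, None]
    return amplitude * np.sin(2.0 * np.pi * config.sample_interval_s * m * f0[None, :] + phi0[None, :])


def synthesize_cube(
    scene: SceneConfig,
    config: RadarConfig | None = None,
    duration_s: float = 10.0,
    subject_id: str = "synthetic",
    posture: str = "supine",
) -> RawCube:
    """Simulate one raw IF cube for a scene.

    The torso return is optionally smeared over ``motion_spread_bins``
    adjacent sub-reflectors (one FFT bin apart, geometrically decaying
    amplitudes, fully correlated motion), emulating the extended body
    surface. Static clutter, DC offset, and i.i.d. Gaussian noise are added
    on top.
    """
    config = config or RadarConfig()
    if duration_s < 1.0:
        raise ValueError("duration_s must be at least 1 s")
    n_frames = int(round(duration_s * config.frame_rate_hz))
    n_chirps = n_frames * config.chirps_per_frame
    t = chirp_times(config, n_chirps)

    max_d = scene.torso_distance_m + (
        scene.motion_spread_bins - 1
    ) * config.fft_bin_pitch_m + scene.respiration_amplitude_m + scene.heartbeat_amplitude_m
    for dist, _amp in scene.clutter:
        max_d = max(max_d, dist)
    if max_d >= config.max_unambiguous_range_m:
        raise ValueError(
            f"scene extends to {max_d:.2f} m, beyond the unambiguous range "
            f"{config.max_unambiguous_range_m:.2f} m of the ADC window"
        )

    d = chest_displacement(scene, t)
    samples = np.zeros((config.samples_per_chirp, n_chirps), dtype=np.float64)

    if scene.reflector_amplitude > 0:
        # geometric amplitude decay across the spread; weights sum to 1
        weights = 0.7 ** np.arange(scene.motion_spread_bins)
        weights = weights / weights.sum()
        for j, w in enumerate(weights):
            offset = j * config.fft_bin_pitch_m
            samples += _if_tone(config, scene.reflector_amplitude * w, d + offset)

    for dist, amp in scene.clutter:
        if amp > 0:
            samples += _if_tone(config, amp, np.full(n_chirps, dist))

    samples += scene.dc_offset

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([scene.seed, 0x5EED]))
        samples += rng.normal(0.0, scene.noise_sigma, size=samples.shape)

    return RawCube(
        samples=samples,
        config=config,
        subject_id=subject_id,
        posture=posture,
    )


def make_dataset(
    presets: Sequence[PosturePreset] | None = None,
    n_subjects: int = 9,
    minutes_per_posture: float = 1.0,
    config: RadarConfig | None = None,
    seed: int = 0,
) -> list[RawCube]:
    """Simulate one cube per subject per posture, reproducibly from ``seed``.

    Subject-level parameters (torso distance, breathing/heart rates, clutter
    layout, reflector strength) are drawn once per subject to emulate
    between-subject variability; the posture presets then set the posture-
    dependent respiration amplitude, motion spread and reflector damping.
    """
    presets = list(default_presets() if presets is None else presets)
    if not presets:
        raise ValueError("presets must be non-empty")
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects so a subject-wise split is possible")
    config = config or RadarConfig()
    root = np.random.default_rng(np.random.SeedSequence(seed))

    cubes: list[RawCube] = []
    for s in range(n_subjects):
        subject_id = f"S{s:02d}"
        torso = root.uniform(0.6, 1.2)
        f_resp = root.uniform(0.2, 0.4)
        f_heart = root.uniform(0.9, 1.3)
        a_heart = root.uniform(0.0001, 0.0005)
        base_amp = root.uniform(0.8, 1.2)
        clutter = tuple(
            (float(root.uniform(0.3, 1.8)), float(root.uniform(0.2, 0.5)))
            for _ in range(2)
        )
        dc = float(root.uniform(0.0, 0.1))
        for preset in presets:
            lo, hi = preset.respiration_amplitude_range_m
            a_resp = root.uniform(lo, hi)
            spread = int(root.integers(preset.motion_spread_range_bins[0],
                                       preset.motion_spread_range_bins[1] + 1))
            scene = SceneConfig(
                torso_distance_m=torso,
                respiration_rate_hz=f_resp,
                respiration_amplitude_m=a_resp,
                heartbeat_rate_hz=f_heart,
                heartbeat_amplitude_m=a_heart,
                motion_spread_bins=spread,
                reflector_amplitude=base_amp * preset.reflector_amplitude_scale,
                clutter=clutter,
                dc_offset=dc,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            cubes.append(
                synthesize_cube(
                    scene,
                    config,
                    duration_s=minutes_per_posture * 60.0,
                    subject_id=subject_id,
                    posture=preset.posture,
                )
            )
    return cubes
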