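import numpy as np
import pytest

import sleepradar as sr


@pytest.fixture(scope="session")
def radar_config() -> sr.RadarConfig:
    return sr.RadarConfig()


@pytest.fixture(scope="session")
def static_cube(radar_config):
    """Noise-free single static reflector at 0.6 m, 1 s long."""
    scene = sr.SceneConfig(
        torso_distance_m=0.6,
        respiration_amplitude_m=0.0,
        heartbeat_amplitude_m=0.0,
        motion_spread_bins=1,
        clutter=(),
        dc_offset=0.0,
        noise_sigma=0.0,
    )
    return sr.synthesize_cube(scene, radar_config, duration_s=1.0)


@pytest.fixture(scope="session")
def breathing_cube(radar_config):
    """Noise-free breathing target, 60 s, for phase-demodulation checks."""
    scene = sr.SceneConfig(
        torso_distance_m=0.9,
        respiration_rate_hz=0.27,
        respiration_amplitude_m=0.008,
        heartbeat_amplitude_m=0.0003,
        motion_spread_bins=1,
        clutter=(),
        dc_offset=0.0,
        noise_sigma=0.0,
        seed=7,
    )
    return scene, sr.synthesize_cube(scene, radar_config, duration_s=60.0)


def make_image(values, label=(1.0, 0.0, 0.0), subject="S00", **kw):
    return sr.MotionFeatureImage(
        values=np.asarray(values, dtype=float),
        bin_offset=0,
        label=np.asarray(label, dtype=float),
        subject_id=subject,
        **kw,
    )


@pytest.fixture
def image_pair():
    rng = np.random.default_rng(0)
    a = make_image(rng.random((40, 60)), (1, 0, 0), "S00")
    b = make_image(rng.random((40, 60)), (0, 0, 1), "S01")
    return a, b
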