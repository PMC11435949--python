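import dataclasses

import numpy as np
import pytest

import sleepradar as sr
from sleepradar.preprocess import CleanCube
from sleepradar.radar import chirp_times


class TestChestDisplacement:
    def test_static_when_amplitudes_zero(self):
        scene = sr.SceneConfig(respiration_amplitude_m=0, heartbeat_amplitude_m=0)
        t = np.linspace(0, 10, 201)
        assert np.allclose(sr.chest_displacement(scene, t), scene.torso_distance_m)

    def test_excursion_bounded_by_amplitude_sum(self):
        scene = sr.SceneConfig(respiration_amplitude_m=0.01, heartbeat_amplitude_m=0.0004)
        t = np.linspace(0, 60, 4001)
        d = sr.chest_displacement(scene, t)
        assert np.max(np.abs(d - scene.torso_distance_m)) <= 0.0104 + 1e-12

    def test_spectral_peak_at_respiration_rate(self):
        """With breathing dominant, the displacement spectrum peaks at f_r."""
        scene = sr.SceneConfig(respiration_rate_hz=0.3, respiration_amplitude_m=0.01,
                               heartbeat_amplitude_m=1e-5, seed=2)
        t = np.arange(0, 60, 0.05)
        d = sr.chest_displacement(scene, t)
        amp = np.abs(np.fft.rfft(d - d.mean()))
        freqs = np.fft.rfftfreq(t.size, d=0.05)
        assert freqs[np.argmax(amp)] == pytest.approx(0.3, rel=0.06)

    def test_empty_time_vector_rejected(self):
        with pytest.raises(ValueError):
            sr.chest_displacement(sr.SceneConfig(), np.array([]))


class TestSynthesizeCube:
    def test_zero_scene_gives_zero_cube(self, radar_config):
        scene = sr.SceneConfig(reflector_amplitude=0, clutter=(), dc_offset=0,
                               noise_sigma=0)
        cube = sr.synthesize_cube(scene, radar_config, 1.0)
        assert not np.any(cube.samples)

    @pytest.mark.parametrize("distance", [0.4, 0.6, 0.9, 1.2, 1.5])
    def test_static_target_lands_on_predicted_bin(self, radar_config, distance):
        """Range-FFT peak bin equals the beat-frequency prediction."""
        scene = sr.SceneConfig(torso_distance_m=distance, respiration_amplitude_m=0,
                               heartbeat_amplitude_m=0, motion_spread_bins=1,
                               clutter=(), dc_offset=0, noise_sigma=0)
        cube = sr.synthesize_cube(scene, radar_config, 1.0)
        spectrum = np.abs(np.fft.fft(cube.samples[:, 0])[:64])
        assert np.argmax(spectrum) == sr.predicted_peak_bin(radar_config, distance)

    def test_known_bin_at_60cm(self, radar_config):
        assert sr.predicted_peak_bin(radar_config, 0.6) == 19

    def test_out_of_range_scene_rejected(self, radar_config):
        scene = sr.SceneConfig(torso_distance_m=2.5)
        with pytest.raises(ValueError, match="unambiguous"):
            sr.synthesize_cube(scene, radar_config, 1.0)

    def test_subsecond_duration_rejected(self, radar_config):
        with pytest.raises(ValueError):
            sr.synthesize_cube(sr.SceneConfig(), radar_config, 0.5)

    def test_amplitude_independent_of_phases_for_static_target(self, radar_config):
        """With zero micro-motion the torso-bin magnitude does not depend on
        the RNG-drawn motion phases."""
        base = dict(torso_distance_m=0.8, respiration_amplitude_m=0,
                    heartbeat_amplitude_m=0, motion_spread_bins=1, clutter=(),
                    dc_offset=0, noise_sigma=0)
        mags = []
        for seed in (1, 2):
            cube = sr.synthesize_cube(sr.SceneConfig(**base, seed=seed), radar_config, 1.0)
            fft = np.abs(np.fft.fft(cube.samples, axis=0)[:64])
            mags.append(fft[sr.predicted_peak_bin(radar_config, 0.8)])
        assert np.allclose(mags[0], mags[1])


class TestPhaseFidelity:
    def test_unwrapped_phase_tracks_displacement(self, radar_config, breathing_cube):
        """The torso-bin phase over slow time demodulates 4 pi d(t) / lambda."""
        scene, cube = breathing_cube
        spec = sr.range_fft(CleanCube(cube.samples, radar_config,
                                      cube.subject_id, cube.posture))
        torso_bin = sr.predicted_peak_bin(radar_config, scene.torso_distance_m)
        phase = sr.unwrapped_phase(spec, torso_bin)
        d = sr.chest_displacement(scene, chirp_times(radar_config, cube.n_chirps))
        target = 4 * np.pi * d / radar_config.wavelength_m
        assert np.corrcoef(phase, target)[0, 1] > 0.99

    def test_respiration_rate_recovered_within_5_percent(self, radar_config,
                                                         breathing_cube):
        scene, cube = breathing_cube
        spec = sr.range_fft(CleanCube(cube.samples, radar_config,
                                      cube.subject_id, cube.posture))
        torso_bin = sr.predicted_peak_bin(radar_config, scene.torso_distance_m)
        rate = sr.estimate_respiration_rate_hz(spec, torso_bin)
        assert rate == pytest.approx(scene.respiration_rate_hz, rel=0.05)


class TestMakeDataset:
    def test_counts(self, radar_config):
        cubes = sr.make_dataset(n_subjects=4, minutes_per_posture=0.1,
                                config=radar_config, seed=0)
        assert len(cubes) == 16
        assert {c.posture for c in cubes} == set(sr.POSTURES_4)
        assert len({c.subject_id for c in cubes}) == 4

    def test_deterministic_under_seed(self, radar_config):
        a = sr.make_dataset(n_subjects=3, minutes_per_posture=0.1,
                            config=radar_config, seed=5)
        b = sr.make_dataset(n_subjects=3, minutes_per_posture=0.1,
                            config=radar_config, seed=5)
        assert all(np.array_equal(x.samples, y.samples) for x, y in zip(a, b))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            sr.make_dataset(n_subjects=2, minutes_per_posture=0.1)

    def test_empty_presets_rejected(self):
        with pytest.raises(ValueError):
            sr.make_dataset(presets=[], n_subjects=3, minutes_per_posture=0.1)

    def test_presets_are_separable_by_construction(self):
        ranges = {p.posture: p.respiration_amplitude_range_m for p in sr.default_presets()}
        assert ranges["supine"][0] > ranges["left_lateral"][1]  # disjoint amplitudes
        assert ranges["left_lateral"] == ranges["right_lateral"]
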