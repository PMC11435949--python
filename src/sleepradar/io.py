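"""HDF5 persistence for cubes, spectrograms and feature stacks; CSV manifests.

Raw IF samples are stored as float32 under "/if_samples" with the radar
parameters, subject id and posture as attributes; cleaned cubes under
"/clean"; spectrograms as real/imag planes plus magnitude; feature stacks
as (n, K1, N_W) arrays with parallel label/subject/offset datasets.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .features import MotionFeatureImage
from .preprocess import CleanCube
from .radar import RadarConfig, RawCube
from .spectrum import RangeSpectrogram

MANIFEST_COLUMNS = ["subject_id", "posture", "split", "path", "seed"]


def _write_config(group, config: RadarConfig) -> None:
    for key, value in config.to_dict().items():
        group.attrs[f"radar_{key}"] = value


def _read_config(group) -> RadarConfig:
    fields = {
        key[len("radar_"):]: value
        for key, value in group.attrs.items()
        if key.startswith("radar_")
    }
    fields["samples_per_chirp"] = int(fields["samples_per_chirp"])
    fields["chirps_per_frame"] = int(fields["chirps_per_frame"])
    return RadarConfig.from_dict(fields)


def save_cube(cube: RawCube, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("if_samples", data=cube.samples.astype(np.float32))
        _write_config(f, cube.config)
        f.attrs["subject_id"] = cube.subject_id
        f.attrs["posture"] = cube.posture
        f.attrs["start_time_s"] = cube.start_time_s


def load_cube(path) -> RawCube:
    with h5py.File(path, "r") as f:
        return RawCube(
            samples=f["if_samples"][()],
            config=_read_config(f),
            subject_id=str(f.attrs["subject_id"]),
            posture=str(f.attrs["posture"]),
            start_time_s=float(f.attrs["start_time_s"]),
        )


def save_clean(clean: CleanCube, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("clean", data=clean.samples.astype(np.float32))
        _write_config(f, clean.config)
        f.attrs["subject_id"] = clean.subject_id
        f.attrs["posture"] = clean.posture
        f.attrs["start_time_s"] = clean.start_time_s


def load_clean(path) -> CleanCube:
    with h5py.File(path, "r") as f:
        return CleanCube(
            samples=f["clean"][()].astype(np.float64),
            config=_read_config(f),
            subject_id=str(f.attrs["subject_id"]),
            posture=str(f.attrs["posture"]),
            start_time_s=float(f.attrs["start_time_s"]),
        )


def save_spectrogram(spec: RangeSpectrogram, path) -> None:
    with h5py.File(path, "w") as f:
        stacked = np.stack([spec.values.real, spec.values.imag]).astype(np.float32)
        f.create_dataset("fft_complex", data=stacked)
        f.create_dataset("fft_mag", data=spec.magnitude.astype(np.float32))
        _write_config(f, spec.config)
        f.attrs["bin_pitch_m"] = spec.bin_pitch_m
        f.attrs["slow_time_rate_hz"] = spec.slow_time_rate_hz
        f.attrs["subject_id"] = spec.subject_id
        f.attrs["posture"] = spec.posture


def load_spectrogram(path) -> RangeSpectrogram:
    with h5py.File(path, "r") as f:
        stacked = f["fft_complex"][()].astype(np.float64)
        values = stacked[0] + 1j * stacked[1]
        return RangeSpectrogram(
            values=values,
            magnitude=np.abs(values),
            bin_pitch_m=float(f.attrs["bin_pitch_m"]),
            slow_time_rate_hz=float(f.attrs["slow_time_rate_hz"]),
            config=_read_config(f),
            subject_id=str(f.attrs["subject_id"]),
            posture=str(f.attrs["posture"]),
        )


def save_feature_stack(images: Sequence[MotionFeatureImage], path) -> None:
    if not images:
        raise ValueError("no images to save")
    with h5py.File(path, "w") as f:
        f.create_dataset("features",
                         data=np.stack([i.values for i in images]).astype(np.float32))
        f.create_dataset("labels",
                         data=np.stack([i.label for i in images]).astype(np.float32))
        f.create_dataset("subjects",
                         data=np.array([i.subject_id for i in images], dtype="S32"))
        f.create_dataset("postures",
                         data=np.array([i.posture for i in images], dtype="S32"))
        f.create_dataset("bin_offsets",
                         data=np.array([i.bin_offset for i in images], dtype=np.int64))
        f.attrs["column_duration_s"] = images[0].column_duration_s


def load_feature_stack(path) -> list[MotionFeatureImage]:
    with h5py.File(path, "r") as f:
        features = f["features"][()].astype(np.float64)
        labels = f["labels"][()].astype(np.float64)
        subjects = [s.decode() for s in f["subjects"][()]]
        postures = [s.decode() for s in f["postures"][()]]
        offsets = f["bin_offsets"][()]
        column = float(f.attrs["column_duration_s"])
    return [
        MotionFeatureImage(
            values=features[i],
            bin_offset=int(offsets[i]),
            label=labels[i],
            subject_id=subjects[i],
            posture=postures[i],
            column_duration_s=column,
        )
        for i in range(features.shape[0])
    ]


def save_image_csv(image: MotionFeatureImage, path) -> None:
    """Export one feature image as CSV (rows = range bins) for inspection."""
    pd.DataFrame(image.values).to_csv(path, index=False, header=False)


def write_manifest(rows: Sequence[dict], path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
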