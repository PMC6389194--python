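"""Readers and writers for the pipeline's file formats.

Recordings travel as multi-channel WAV (float32) with a YAML sidecar
holding the channel -> sensor map and the breath annotations; HU volume
series as 4-D NIfTI plus a mask NIfTI; results as CSV with fixed
9-significant-digit formatting so regression tests are byte-stable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .acoustics import Recording
from .ctvol import HUVolumeSeries

CSV_FLOAT_FORMAT = "%.9g"


def save_recording(recording: Recording, wav_path, sidecar_path) -> None:
    wavfile.write(wav_path, int(recording.fs),
                  recording.samples.T.astype(np.float32))
    sidecar = {
        "fs_hz": float(recording.fs),
        "sensor_ids": list(recording.sensor_ids),
        "breaths": [{"start_s": float(s), "duration_s": float(d)}
                    for s, d in recording.breaths],
    }
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def load_recording(wav_path, sidecar_path) -> Recording:
    with open(sidecar_path) as fh:
        sidecar = yaml.safe_load(fh)
    fs, data = wavfile.read(wav_path)
    if data.ndim == 1:
        data = data[:, None]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    data = np.ascontiguousarray(data.T, dtype=float)
    if abs(fs - sidecar["fs_hz"]) > 1e-6:
        raise ValueError("WAV sampling rate disagrees with sidecar")
    breaths = [(b["start_s"], b["duration_s"]) for b in sidecar["breaths"]]
    return Recording(samples=data, fs=float(fs),
                     sensor_ids=list(sidecar["sensor_ids"]), breaths=breaths)


def save_hu_series(series: HUVolumeSeries, frames_path, mask_path) -> None:
    # voxel edge from the (isotropic) voxel volume, mm
    edge_mm = 10.0 * series.voxel_volume_cm3 ** (1.0 / 3.0)
    affine = np.diag([edge_mm, edge_mm, edge_mm, 1.0])
    img = nib.Nifti1Image(np.moveaxis(series.frames, 0, -1)
                          .astype(np.float32), affine)
    img.header.set_zooms((edge_mm, edge_mm, edge_mm,
                          series.frame_interval_s))
    nib.save(img, str(frames_path))
    nib.save(nib.Nifti1Image(series.mask.astype(np.uint8), affine),
             str(mask_path))


def load_hu_series(frames_path, mask_path,
                   frame_interval_s: float | None = None,
                   gravity_axis: int = 2) -> HUVolumeSeries:
    img = nib.load(str(frames_path))
    zooms = img.header.get_zooms()
    voxel_volume_cm3 = float(np.prod(zooms[:3])) / 1000.0
    if frame_interval_s is None:
        frame_interval_s = float(zooms[3]) if len(zooms) > 3 else 0.58
    frames = np.moveaxis(np.asarray(img.dataobj, dtype=np.float32), -1, 0)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return HUVolumeSeries(frames=frames, voxel_volume_cm3=voxel_volume_cm3,
                          mask=mask, frame_interval_s=frame_interval_s,
                          gravity_axis=gravity_axis)


def save_breaths(breaths, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"breaths": [{"start_s": float(s),
                                     "duration_s": float(d)}
                                    for s, d in breaths]}, fh)


def load_breaths(path) -> list[tuple[float, float]]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [(b["start_s"], b["duration_s"]) for b in payload["breaths"]]


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, stages: list[str], parameters: dict,
                   outputs: list) -> None:
    manifest = {
        "stages": stages,
        "parameters": parameters,
        "outputs": [{"path": str(Path(p).name), "sha256": file_sha256(p)}
                    for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
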