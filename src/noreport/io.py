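"""Readers and writers for the package's on-disk formats.

Events and eye samples travel as BIDS-style TSV; EEG epochs in a documented
HDF5 layout (/epochs [chan x time x trial], /channels, /times_s, /labels,
attrs: condition); fMRI volumes and masks as NIfTI-1; run configuration as
YAML with an explicit seed.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .erp import EEGEpochSet
from .eyeproc import EyeRecording
from .paradigm import StimulusEvent

__all__ = [
    "write_events_tsv", "read_events_tsv",
    "write_eye_tsv", "read_eye_tsv",
    "write_eeg_h5", "read_eeg_h5",
    "write_nifti", "read_nifti",
    "write_config_yaml", "read_config_yaml",
]


def write_events_tsv(events: list[StimulusEvent], path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "onset": e.onset,
                "duration": 0.05,
                "location_set": e.location_set,
                "location": e.location,
                "opacity": e.opacity,
                "condition": e.opacity_condition,
                "relevance": e.relevance if e.relevance else "n/a",
                "response_seen": {True: "yes", False: "no", None: "n/a"}[e.response_seen],
                "response_location": e.response_location if e.response_location else "n/a",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[StimulusEvent]:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"], keep_default_na=False)
    events = []
    for _, r in df.iterrows():
        seen = r["response_seen"]
        events.append(
            StimulusEvent(
                onset=float(r["onset"]),
                location_set=str(r["location_set"]),
                location=int(r["location"]),
                opacity_condition=str(r["condition"]),
                opacity=float(r["opacity"]),
                relevance=None if pd.isna(r["relevance"]) else str(r["relevance"]),
                response_seen=None if pd.isna(seen) else seen == "yes",
                response_location=None
                if pd.isna(r["response_location"])
                else int(r["response_location"]),
            )
        )
    return events


def write_eye_tsv(rec: EyeRecording, path) -> None:
    pd.DataFrame(
        {
            "time_s": rec.time,
            "pupil": rec.pupil,
            "gaze_x_deg": rec.gaze_x,
            "gaze_y_deg": rec.gaze_y,
            "valid": rec.valid.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_eye_tsv(path) -> EyeRecording:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return EyeRecording(
        time=t,
        pupil=df["pupil"].to_numpy(float),
        gaze_x=df["gaze_x_deg"].to_numpy(float),
        gaze_y=df["gaze_y_deg"].to_numpy(float),
        valid=df["valid"].to_numpy(bool),
        sampling_rate=float(round(fs)),
    )


def write_eeg_h5(epoch_set: EEGEpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epoch_set.epochs)
        f.create_dataset(
            "channels", data=np.asarray(epoch_set.channels, dtype="S")
        )
        f.create_dataset("times_s", data=epoch_set.times)
        f.create_dataset("labels", data=epoch_set.perceived.astype(np.int8))
        f.attrs["condition"] = epoch_set.condition


def read_eeg_h5(path) -> EEGEpochSet:
    with h5py.File(path, "r") as f:
        return EEGEpochSet(
            epochs=f["epochs"][()],
            channels=[c.decode() for c in f["channels"][()]],
            times=f["times_s"][()],
            perceived=f["labels"][()].astype(bool),
            condition=str(f.attrs["condition"]),
        )


def write_nifti(data: np.ndarray, path, voxel_size: float = 2.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_config_yaml(config: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)


def read_config_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)
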