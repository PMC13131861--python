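"""Plain-text and HDF5 readers/writers for the pipeline's tables.

Subject tables travel as TSV with ``subject_id`` and ``group`` (or
``class``) columns followed by feature columns; hypnograms as
(epoch_index, zt_hours, state) TSV; activity traces as (zt_hours,
activity) TSV; trajectories as per-frame keypoint TSV; EEG recordings as
HDF5 with ``eeg``/``emg`` datasets and ``fs``/``start_zt`` attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from sundown.ethology import Trajectory
from sundown.rhythms import Hypnogram
from sundown.spectra import EEGRecording

__all__ = [
    "read_table", "write_table",
    "read_hypnogram", "write_hypnogram",
    "read_eeg", "write_eeg",
    "read_trajectory", "write_trajectory",
    "write_json",
]


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def write_hypnogram(hyp: Hypnogram, path) -> None:
    write_table(hyp.to_dataframe(), path)


def read_hypnogram(path, epoch_s: float | None = None) -> Hypnogram:
    df = read_table(path)
    if epoch_s is None:
        zt = df["zt_hours"].to_numpy()
        if len(zt) < 2:
            raise ValueError("cannot infer epoch duration from one epoch")
        epoch_s = float(round((zt[1] - zt[0]) * 3600.0, 6))
    return Hypnogram(states=df["state"].to_numpy(), epoch_s=epoch_s,
                     start_zt=float(df["zt_hours"].iloc[0]))


def write_eeg(rec: EEGRecording, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=rec.eeg)
        f.create_dataset("emg", data=rec.emg)
        f.attrs["fs"] = rec.fs
        f.attrs["start_zt"] = rec.start_zt


def read_eeg(path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        return EEGRecording(eeg=f["eeg"][:], emg=f["emg"][:],
                            fs=float(f.attrs["fs"]),
                            start_zt=float(f.attrs.get("start_zt", 0.0)))


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "centroid_x_cm": traj.centroid[:, 0],
        "centroid_y_cm": traj.centroid[:, 1],
    })
    if traj.nose is not None:
        df["nose_x_cm"] = traj.nose[:, 0]
        df["nose_y_cm"] = traj.nose[:, 1]
    write_table(df, path)


def read_trajectory(path, fps: float) -> Trajectory:
    df = read_table(path)
    nose = None
    if "nose_x_cm" in df.columns:
        nose = df[["nose_x_cm", "nose_y_cm"]].to_numpy()
    return Trajectory(centroid=df[["centroid_x_cm", "centroid_y_cm"]].to_numpy(),
                      fps=fps, nose=nose)
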