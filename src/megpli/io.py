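"""Readers and writers for the package's on-disk formats.

* sensors.tsv       — columns id, x, y, z, ox, oy, oz (metres, unit orientation)
* parcellation.tsv  — columns voxel_id, x_mm, y_mm, z_mm, roi_label
* recording         — delimited matrix (channels x samples) + JSON sidecar
                      {fs_hz, channel_ids, units: "T"}
* ROI series        — one matrix per band + JSON sidecar
* adjacency         — TSV with ROI labels as header row/column + JSON sidecar

All writers store full float precision so write-then-read round-trips
exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import AdjacencyMatrix
from .forward_sim import SensorArray, SensorRecording
from .parcellation import Parcellation, ROITimeSeriesSet

_FLOAT_FMT = "%.17e"

SENSOR_COLUMNS = ["id", "x", "y", "z", "ox", "oy", "oz"]
PARCELLATION_COLUMNS = ["voxel_id", "x_mm", "y_mm", "z_mm", "roi_label"]


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


def write_sensors(path, sensors: SensorArray) -> None:
    df = pd.DataFrame({
        "id": sensors.ids,
        "x": sensors.positions[:, 0], "y": sensors.positions[:, 1],
        "z": sensors.positions[:, 2],
        "ox": sensors.orientations[:, 0], "oy": sensors.orientations[:, 1],
        "oz": sensors.orientations[:, 2],
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_sensors(path) -> SensorArray:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SENSOR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sensors file {path} missing columns {missing}")
    ori = df[["ox", "oy", "oz"]].to_numpy(float)
    norms = np.linalg.norm(ori, axis=1)
    if np.any(norms == 0):
        raise FormatError("zero sensor orientation vector")
    if np.any(np.abs(norms - 1.0) > 1e-6):
        warnings.warn("non-unit sensor orientations: renormalising", stacklevel=2)
    ori = ori / norms[:, None]
    return SensorArray(ids=df["id"].astype(str).tolist(),
                       positions=df[["x", "y", "z"]].to_numpy(float),
                       orientations=ori)


def write_parcellation(path, parcellation: Parcellation) -> None:
    df = pd.DataFrame({
        "voxel_id": parcellation.voxel_ids,
        "x_mm": parcellation.positions[:, 0] * 1e3,
        "y_mm": parcellation.positions[:, 1] * 1e3,
        "z_mm": parcellation.positions[:, 2] * 1e3,
        "roi_label": parcellation.roi_of,
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARCELLATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parcellation file {path} missing columns {missing}")
    return Parcellation(voxel_ids=df["voxel_id"].astype(str).tolist(),
                        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float) * 1e-3,
                        roi_of=df["roi_label"].astype(str).tolist())


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(path, recording: SensorRecording) -> None:
    """Matrix as TSV (channels x samples) + JSON sidecar next to it."""
    path = Path(path)
    np.savetxt(path, recording.data, delimiter="\t", fmt=_FLOAT_FMT)
    sidecar = {"fs_hz": recording.fs, "channel_ids": list(recording.channel_ids),
               "units": "T"}
    _sidecar(path).write_text(json.dumps(sidecar))


def read_recording(path) -> SensorRecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    if data.shape[0] != len(meta["channel_ids"]):
        raise FormatError(
            f"recording matrix shape {data.shape} does not match sidecar with "
            f"{len(meta['channel_ids'])} channels")
    return SensorRecording(data=data, fs=float(meta["fs_hz"]),
                           channel_ids=[str(c) for c in meta["channel_ids"]])


def write_roi_series(directory, roi_set: ROITimeSeriesSet) -> None:
    """One `<band>.tsv` per band plus `roi_series.json` in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for band, mat in roi_set.series.items():
        np.savetxt(directory / f"{band}.tsv", mat, delimiter="\t", fmt=_FLOAT_FMT)
    meta = {"fs_hz": roi_set.fs, "roi_labels": roi_set.roi_labels,
            "bands": roi_set.band_names,
            "chosen_voxel": roi_set.chosen_voxel}
    (directory / "roi_series.json").write_text(json.dumps(meta))


def read_roi_series(directory) -> ROITimeSeriesSet:
    directory = Path(directory)
    meta = json.loads((directory / "roi_series.json").read_text())
    series = {}
    for band in meta["bands"]:
        mat = np.atleast_2d(np.loadtxt(directory / f"{band}.tsv", delimiter="\t"))
        if mat.shape[0] != len(meta["roi_labels"]):
            raise FormatError(f"band {band}: {mat.shape[0]} rows for "
                              f"{len(meta['roi_labels'])} ROI labels")
        series[band] = mat
    return ROITimeSeriesSet(series=series, chosen_voxel=meta["chosen_voxel"],
                            roi_labels=meta["roi_labels"], fs=float(meta["fs_hz"]))


def write_adjacency(path, adjacency: AdjacencyMatrix, roi_labels,
                    meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame(adjacency.values, index=roi_labels, columns=roi_labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    sidecar = {"estimator": adjacency.estimator, "level": adjacency.level}
    sidecar.update(meta or {})
    _sidecar(path).write_text(json.dumps(sidecar))


def read_adjacency(path):
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(_sidecar(path).read_text())
    adj = AdjacencyMatrix(values=df.to_numpy(float),
                          estimator=meta["estimator"], level=meta["level"])
    return adj, df.index.tolist(), meta
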