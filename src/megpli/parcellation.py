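"""Band-wise ROI representative time-series assembly.

Every voxel of a parcellation gets a beamformer-reconstructed virtual
electrode; within each region of interest (ROI) and each frequency band,
the voxel with maximum band power represents the ROI.  Averaging voxel
time-series across a ROI is deliberately not offered: the reconstructed
source orientation has an arbitrary sign, so neighbouring virtual
electrodes may have opposite polarity and their average is meaningless.

Default band scheme: the five classical EEG bands, delta (0.5-4 Hz),
theta (4-8), alpha (8-13), beta (13-30) and gamma (30-48).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt


@dataclass
class Parcellation:
    """Labelled voxels: ``positions`` (V, 3) metres, one ROI label per voxel."""

    voxel_ids: list
    positions: np.ndarray
    roi_of: list

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        v = len(self.voxel_ids)
        if len(set(self.voxel_ids)) != v:
            raise ValueError("voxel ids must be unique")
        if self.positions.shape != (v, 3) or len(self.roi_of) != v:
            raise ValueError("positions and labels must match the voxel count")
        # ordered unique labels, first-appearance order
        seen = dict.fromkeys(self.roi_of)
        self.roi_labels = list(seen)

    @property
    def n_rois(self):
        return len(self.roi_labels)

    def voxels_of(self, label: str) -> list:
        idx = [i for i, lab in enumerate(self.roi_of) if lab == label]
        if not idx:
            raise KeyError(f"unknown ROI label {label!r}")
        return idx


@dataclass(frozen=True)
class BandScheme:
    """Ordered list of named frequency bands (name, lo Hz, hi Hz)."""

    bands: tuple = (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma", 30.0, 48.0),
    )

    def __post_init__(self):
        for name, lo, hi in self.bands:
            if not (0.0 < lo < hi):
                raise ValueError(f"invalid band {name}: ({lo}, {hi})")

    @property
    def names(self):
        return [b[0] for b in self.bands]

    def edges(self, name: str):
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise KeyError(f"unknown band {name!r}")

    @property
    def total_band(self):
        return (min(b[1] for b in self.bands), max(b[2] for b in self.bands))


DEFAULT_BANDS = BandScheme()


def bandpass(series: np.ndarray, band, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    A 4th-order Butterworth is applied forward and backward (sosfiltfilt),
    so the filter cannot introduce phase lags that a lag-based connectivity
    estimator would later score.
    """
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band ({lo}, {hi}) must lie within (0, fs/2) at fs={fs}")
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(series, dtype=float), axis=-1)


def band_power(series: np.ndarray, band, fs: float) -> float:
    """Variance of the band-passed series (time-domain band power, nAm^2)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 256:
        raise ValueError("band power needs at least 256 samples")
    return float(np.var(bandpass(series, band, fs), axis=-1))


def relative_power(series: np.ndarray, band, scheme: BandScheme, fs: float) -> float:
    """Band power as a fraction of total power over the scheme's full span."""
    total = band_power(series, scheme.total_band, fs)
    if total == 0.0:
        raise ValueError("total power is zero; relative power undefined")
    return band_power(series, band, fs) / total


def relative_power_profile(series: np.ndarray, scheme: BandScheme, fs: float) -> np.ndarray:
    """Relative power in every band of the scheme, for one series."""
    total = band_power(series, scheme.total_band, fs)
    if total == 0.0:
        raise ValueError("total power is zero; relative power undefined")
    return np.array([band_power(series, scheme.edges(n), fs) for n in scheme.names]) / total


def select_representative_voxel(voxel_ids: list, series_matrix: np.ndarray,
                                band, fs: float):
    """Max-band-power voxel of one ROI; ties broken by lowest voxel id.

    ``series_matrix`` holds one broadband virtual-electrode per row.
    Returns (voxel_id, band-passed series of that voxel).
    """
    series_matrix = np.atleast_2d(series_matrix)
    if series_matrix.shape[0] == 0:
        raise ValueError("ROI has no voxels")
    filtered = bandpass(series_matrix, band, fs)
    powers = filtered.var(axis=-1)
    best = np.flatnonzero(powers == powers.max())
    if len(best) > 1:
        best = sorted(best, key=lambda i: voxel_ids[i])
    idx = int(best[0])
    return voxel_ids[idx], filtered[idx]


@dataclass
class ROITimeSeriesSet:
    """Per-band K x T representative series with the chosen voxel per ROI."""

    series: dict          # band name -> (K, T) array, nAm
    chosen_voxel: dict    # band name -> list of K voxel ids
    roi_labels: list
    fs: float

    @property
    def band_names(self):
        return list(self.series)


def extract_roi_series(recording, weights: dict, parcellation: Parcellation,
                       scheme: BandScheme = DEFAULT_BANDS) -> ROITimeSeriesSet:
    """Assemble band-wise ROI representative series from per-voxel weights.

    ``weights`` maps voxel_id to a 1 x N (or length-N) weight vector.
    Every voxel's virtual electrode is reconstructed, band-passed per band,
    and the max-power voxel per ROI per band becomes that ROI's series.
    With the default scheme and K ROIs this yields 5 sets of K time-series.
    """
    missing = [v for v in parcellation.voxel_ids if v not in weights]
    if missing:
        raise KeyError(f"missing beamformer weights for voxels: {missing[:5]}")
    W = np.vstack([np.ravel(weights[v]) for v in parcellation.voxel_ids])
    voxel_series = W @ recording.data  # (V, T)
    fs = recording.fs

    series, chosen = {}, {}
    for name in scheme.names:
        band = scheme.edges(name)
        filtered = bandpass(voxel_series, band, fs)
        powers = filtered.var(axis=-1)
        rows, ids = [], []
        for label in parcellation.roi_labels:
            idx = parcellation.voxels_of(label)
            p = powers[idx]
            best = [i for i in idx if powers[i] == p.max()]
            pick = min(best, key=lambda i: parcellation.voxel_ids[i])
            rows.append(filtered[pick])
            ids.append(parcellation.voxel_ids[pick])
        series[name] = np.vstack(rows)
        chosen[name] = ids
    return ROITimeSeriesSet(series=series, chosen_voxel=chosen,
                            roi_labels=list(parcellation.roi_labels), fs=fs)


def power_map(recording, weights: dict, parcellation: Parcellation,
              scheme: BandScheme = DEFAULT_BANDS) -> np.ndarray:
    """(K, n_bands) relative-power map over ROIs.

    Entry (k, b) is the relative power in band b of the broadband virtual
    electrode of the voxel chosen to represent ROI k in band b.
    """
    W = np.vstack([np.ravel(weights[v]) for v in parcellation.voxel_ids])
    voxel_series = W @ recording.data
    fs = recording.fs
    total = bandpass(voxel_series, scheme.total_band, fs).var(axis=-1)

    out = np.zeros((parcellation.n_rois, len(scheme.names)))
    for b, name in enumerate(scheme.names):
        powers = bandpass(voxel_series, scheme.edges(name), fs).var(axis=-1)
        for k, label in enumerate(parcellation.roi_labels):
            idx = parcellation.voxels_of(label)
            p = powers[idx]
            best = [i for i in idx if powers[i] == p.max()]
            pick = min(best, key=lambda i: parcellation.voxel_ids[i])
            if total[pick] == 0.0:
                raise ValueError("total power is zero; relative power undefined")
            out[k, b] = powers[pick] / total[pick]
    return out
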