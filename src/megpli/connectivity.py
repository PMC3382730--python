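"""Phase-based functional connectivity between ROI time-series.

Two estimators over the instantaneous phase difference dphi(t_k) of a
pair of band-limited signals (S samples):

* Phase Coherence   PC  = | (1/S) sum_k exp(i dphi(t_k)) |
* Phase Lag Index   PLI = | (1/S) sum_k sign(sin dphi(t_k)) |

PC is maximal for any constant phase difference, including zero, and is
therefore inflated by volume conduction / field spread (and by the
correlated beamformer weights that field spread induces).  PLI is
non-zero only when the phase-difference distribution is asymmetric
around 0 and pi, so consistent zero-lag mixing contributes nothing;
sign(0) counts as 0, discarding exactly-zero lags by design.

Connectivity is computed per epoch (default 5 non-overlapping epochs of
4096 samples, 13.1 s at 312.5 Hz), averaged over epochs within subject
and then over subjects.  Node strength (weighted degree) is the mean of
a ROI's connectivity with all other ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

EPOCH_LENGTH = 4096
N_EPOCHS = 5

_ESTIMATORS = ("pli", "pc")


@dataclass
class AdjacencyMatrix:
    """Symmetric K x K connectivity with zero diagonal, entries in [0, 1]."""

    values: np.ndarray
    estimator: str
    level: str = "epoch"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        if self.estimator not in _ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")

    @property
    def n_rois(self):
        return self.values.shape[0]


def epoch_duration_s(epoch_length: int = EPOCH_LENGTH, fs: float = 312.5) -> float:
    """Duration in seconds of one connectivity epoch (4096 samples -> 13.1 s)."""
    return epoch_length / fs


def instantaneous_phase(series: np.ndarray) -> np.ndarray:
    """Analytic-signal (Hilbert) phase of a band-limited series, in [-pi, pi)."""
    series = np.asarray(series, dtype=float)
    if not np.any(series):
        raise ValueError("phase of an all-zero series is undefined")
    phi = np.angle(hilbert(series, axis=-1))
    return _wrap(phi)


def _wrap(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(phi + np.pi, 2.0 * np.pi) - np.pi


def phase_difference(series_a: np.ndarray, series_b: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a minus that of b, wrapped to [-pi, pi)."""
    return _wrap(instantaneous_phase(series_a) - instantaneous_phase(series_b))


def phase_coherence(dphi: np.ndarray) -> float:
    """Modulus of the mean complex phase difference; 1 iff dphi is constant."""
    dphi = np.ravel(dphi)
    if dphi.size < 2:
        raise ValueError("need at least 2 phase-difference samples")
    return float(np.abs(np.mean(np.exp(1j * dphi))))


def phase_lag_index(dphi: np.ndarray) -> float:
    """Absolute mean sign of sin(dphi); 0 for symmetric distributions."""
    dphi = np.ravel(dphi)
    if dphi.size < 2:
        raise ValueError("need at least 2 phase-difference samples")
    return float(np.abs(np.mean(np.sign(np.sin(dphi)))))


def _estimate(dphi: np.ndarray, estimator: str) -> float:
    if estimator == "pli":
        return phase_lag_index(dphi)
    if estimator == "pc":
        return phase_coherence(dphi)
    raise ValueError(f"unknown estimator {estimator!r}")


def epoch_adjacency(series: np.ndarray, estimator: str,
                    epoch_length: int = EPOCH_LENGTH,
                    n_epochs: int = N_EPOCHS) -> list:
    """Per-epoch adjacency matrices from a (K, T) band-limited series matrix.

    The first ``n_epochs`` non-overlapping windows of ``epoch_length``
    samples are used.  Accepts a plain array or one band of a
    ROITimeSeriesSet (pass ``roi_set.series[band]``).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    k, t = series.shape
    if t < n_epochs * epoch_length:
        raise ValueError(f"need {n_epochs * epoch_length} samples, got {t}")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    out = []
    for e in range(n_epochs):
        seg = series[:, e * epoch_length:(e + 1) * epoch_length]
        u = hilbert(seg, axis=-1)
        amp = np.abs(u)
        amp[amp == 0] = 1.0
        u = u / amp  # unit-modulus analytic signal exp(i phi)
        if estimator == "pc":
            # mean exp(i dphi) over samples = (1/S) U U^H
            a = np.abs(u @ u.conj().T) / epoch_length
        else:
            # sign(sin dphi) = sign(Im u_i conj(u_j)); row-chunked for memory
            a = np.empty((k, k))
            for i in range(k):
                im = (u[i] * u.conj()).imag
                im[np.abs(im) < 1e-12] = 0.0  # numerically zero lag counts as 0
                a[i] = np.abs(np.sign(im).mean(axis=-1))
        a = 0.5 * (a + a.T)  # exact symmetry against rounding
        np.fill_diagonal(a, 0.0)
        out.append(AdjacencyMatrix(values=a, estimator=estimator, level="epoch"))
    return out


def average_adjacency(per_subject: list, estimator: str | None = None) -> AdjacencyMatrix:
    """Mean over epochs within subject, then mean over subjects.

    ``per_subject`` is a list (one entry per subject) of lists of epoch
    AdjacencyMatrix (or arrays).
    """
    if not per_subject:
        raise ValueError("no subjects to average")
    subj_means = []
    for epochs in per_subject:
        if not epochs:
            raise ValueError("a subject has no epoch matrices")
        mats = [m.values if isinstance(m, AdjacencyMatrix) else np.asarray(m, float)
                for m in epochs]
        if estimator is None:
            first = epochs[0]
            estimator = first.estimator if isinstance(first, AdjacencyMatrix) else "pli"
        subj_means.append(np.mean(mats, axis=0))
    group = np.mean(subj_means, axis=0)
    return AdjacencyMatrix(values=group, estimator=estimator, level="group")


def node_strength(adjacency) -> np.ndarray:
    """Weighted degree: mean of each row excluding the diagonal."""
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    k = a.shape[0]
    if k < 2:
        raise ValueError("node strength needs at least 2 ROIs")
    return (a.sum(axis=1) - np.diag(a)) / (k - 1)


def degree_thresholded(adjacency, fraction: float = 0.20) -> np.ndarray:
    """Integer degree after binarising at fraction x max off-diagonal entry."""
    a = adjacency.values if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    k = a.shape[0]
    if k < 2:
        raise ValueError("degree needs at least 2 ROIs")
    off = a[~np.eye(k, dtype=bool)]
    mx = off.max()
    if mx <= 0:
        raise ValueError("all-zero adjacency: threshold undefined")
    thr = fraction * mx
    binary = (a >= thr) & ~np.eye(k, dtype=bool)
    return binary.sum(axis=1).astype(int)
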