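"""Analytic spherical-head forward model and coupled-oscillator simulator.

The conductor is a single homogeneous sphere, for which the external
magnetic field of a current dipole has the closed-form solution of Sarvas.
Two consequences of that geometry shape everything downstream:

* a radially oriented dipole produces no external field (silent source),
  so lead fields are computed only for the two tangential orientations;
* the radial field component outside the sphere equals the radial
  component of the free-space (Biot-Savart) field of the primary dipole
  current alone, which provides an independent numerical check.

The simulator generates band-limited Gaussian dipole sources with
specified pairwise phase-lag couplings, projects them through the lead
fields, and adds white sensor noise.  Units throughout: positions in
metres, dipole moments in nAm, magnetic fields in Tesla, lead fields in
Tesla per nAm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T m / A


class GeometryError(ValueError):
    """Raised for degenerate or out-of-domain source/sensor geometry."""


@dataclass(frozen=True)
class HeadModel:
    """Homogeneous conducting sphere: ``center`` in metres, ``radius`` > 0."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if not self.radius > 0:
            raise ValueError("radius must be positive")


@dataclass
class SensorArray:
    """Point magnetometers: positions (N, 3) metres, unit orientations (N, 3)."""

    ids: list
    positions: np.ndarray
    orientations: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.orientations = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        n = len(self.ids)
        if n < 2:
            raise ValueError("a sensor array needs at least 2 channels")
        if len(set(self.ids)) != n:
            raise ValueError("channel ids must be unique")
        if self.positions.shape != (n, 3) or self.orientations.shape != (n, 3):
            raise ValueError("positions/orientations must be (N, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sensor orientations must have unit norm")

    def __len__(self):
        return len(self.ids)

    def validate_outside(self, head: HeadModel):
        r = np.linalg.norm(self.positions - head.center, axis=1)
        if np.any(r <= head.radius):
            raise GeometryError("all sensors must lie strictly outside the head sphere")


@dataclass
class DipoleSource:
    """Equivalent current dipole: tangential moment direction, amplitude in nAm."""

    location: np.ndarray
    moment_direction: np.ndarray
    amplitude: float = 1.0

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        self.moment_direction = np.asarray(self.moment_direction, dtype=float)
        nrm = np.linalg.norm(self.moment_direction)
        if nrm == 0:
            raise ValueError("moment_direction must be non-zero")
        self.moment_direction = self.moment_direction / nrm

    def validate(self, head: HeadModel):
        d = np.linalg.norm(self.location - head.center)
        if not (0 < d < head.radius):
            raise GeometryError("dipole must lie strictly inside the sphere, off-center")
        radial = (self.location - head.center) / d
        if abs(float(radial @ self.moment_direction)) > 1e-9:
            raise GeometryError("moment_direction must be tangential (orthogonal to radial)")


@dataclass
class CouplingSpec:
    """Planted pairwise phase-lag couplings between simulated sources.

    ``pairs`` lists (i, j, lag, strength): source j is built as the
    strength-weighted, lag-shifted copy of source i mixed with
    (1 - strength) independent same-band noise.  ``lag`` is the
    analytic-signal phase of source i minus that of source j, in
    (-pi, pi].  ``carrier_band`` is one (lo, hi) Hz interval applied to
    every source, or a list of per-source intervals.  ``noise_fraction``
    mixes independent same-band noise into every source.
    """

    pairs: list = field(default_factory=list)
    carrier_band: object = (8.0, 13.0)
    noise_fraction: float = 0.0

    def __post_init__(self):
        for (i, j, lag, strength) in self.pairs:
            if i == j:
                raise ValueError("coupling pair must involve two distinct sources")
            if not (-np.pi < lag <= np.pi):
                raise ValueError("lag must lie in (-pi, pi]")
            if not (0.0 <= strength <= 1.0):
                raise ValueError("strength must lie in [0, 1]")
        if not (0.0 <= self.noise_fraction <= 1.0):
            raise ValueError("noise_fraction must lie in [0, 1]")

    def band_for(self, i: int, n_sources: int):
        band = self.carrier_band
        if isinstance(band[0], (tuple, list, np.ndarray)):
            if len(band) != n_sources:
                raise ValueError("need one carrier band per source")
            return tuple(band[i])
        return tuple(band)


@dataclass
class SensorRecording:
    """Multichannel magnetic-field recording: ``data`` (N, T) Tesla at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    channel_ids: list

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channel_ids)} channel ids"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# geometry helpers


def tangential_basis(head: HeadModel, location) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis of the tangential plane at ``location``.

    The radial direction is u = (location - center)/|.|.  The first basis
    vector is u x a normalised, where the auxiliary axis a is ẑ unless u is
    within ~25 degrees of ±ẑ, in which case x̂ is used; the second is
    u x t1.  Both are unit, mutually orthogonal, and orthogonal to u.
    """
    location = np.asarray(location, dtype=float)
    d = location - head.center
    r = np.linalg.norm(d)
    if r == 0:
        raise GeometryError("location at sphere center: tangential plane undefined")
    if r >= head.radius:
        raise GeometryError("location must lie strictly inside the sphere")
    u = d / r
    aux = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    t1 = np.cross(u, aux)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(u, t1)
    return t1, t2


def _sarvas_field(head: HeadModel, positions: np.ndarray, location: np.ndarray,
                  q: np.ndarray) -> np.ndarray:
    """Magnetic field (T) of dipole moment ``q`` (A m) at external ``positions``."""
    r0 = location - head.center
    rv = positions - head.center            # (N, 3)
    a = rv - r0                             # (N, 3)
    an = np.linalg.norm(a, axis=1)          # |a|
    rn = np.linalg.norm(rv, axis=1)         # |r|
    r0_dot_r = rv @ r0
    a_dot_r = np.einsum("ij,ij->i", a, rv)
    F = an * (rn * an + rn**2 - r0_dot_r)
    gF = ((an**2 / rn + a_dot_r / an + 2.0 * an + 2.0 * rn)[:, None] * rv
          - (an + 2.0 * rn + a_dot_r / an)[:, None] * r0)
    qxr0 = np.cross(q, r0)
    B = (MU0 / (4.0 * np.pi * F**2))[:, None] * (F[:, None] * qxr0 - (rv @ qxr0)[:, None] * gF)
    return B


def lead_field(head: HeadModel, sensors: SensorArray, location) -> np.ndarray:
    """(N, 2) lead field in T/nAm; columns follow ``tangential_basis``."""
    location = np.asarray(location, dtype=float)
    sensors.validate_outside(head)
    t1, t2 = tangential_basis(head, location)  # validates geometry
    cols = []
    for direction in (t1, t2):
        q = 1e-9 * direction  # 1 nAm
        B = _sarvas_field(head, sensors.positions, location, q)
        cols.append(np.einsum("ij,ij->i", B, sensors.orientations))
    return np.column_stack(cols)


def lead_field_for(head: HeadModel, sensors: SensorArray, source: DipoleSource) -> np.ndarray:
    """N-vector lead field (T/nAm) for a dipole with fixed tangential orientation."""
    L = lead_field(head, sensors, source.location)
    coeff = tangential_coefficients(head, source.location, source.moment_direction)
    return L @ coeff


def tangential_coefficients(head: HeadModel, location, moment_direction) -> np.ndarray:
    """Expand a tangential unit moment direction in the ``tangential_basis``."""
    t1, t2 = tangential_basis(head, location)
    m = np.asarray(moment_direction, dtype=float)
    m = m / np.linalg.norm(m)
    return np.array([t1 @ m, t2 @ m])


# ---------------------------------------------------------------------------
# signal simulation


def narrowband_noise(n_samples: int, fs: float, band, rng) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz) by FFT masking."""
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"carrier band {band} must lie within (0, fs/2)")
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec[(freqs < lo) | (freqs > hi)] = 0.0
    x = np.fft.irfft(spec, n=n_samples)
    return x / x.std()


def phase_shift(x: np.ndarray, lag: float) -> np.ndarray:
    """Shift the analytic-signal phase of ``x`` down by ``lag`` radians.

    For a narrowband x the returned signal trails x by ``lag``: the
    instantaneous phase of x minus that of the result equals lag.
    """
    return np.real(hilbert(x) * np.exp(-1j * lag))


def simulate_sources(sources: list, coupling: CouplingSpec, duration: float,
                     fs: float, seed: int) -> np.ndarray:
    """Simulate coupled band-limited dipole moment time-series.

    Returns an (n_sources, T) array in nAm.  Each source starts from an
    independent unit-variance narrowband base signal; for every coupling
    pair (i, j, lag, strength), source j is rebuilt as the strength-weighted
    lag-shifted copy of source i plus (1-strength) independent same-band
    noise, then re-standardised.  ``noise_fraction`` finally mixes in
    independent same-band noise per source.  Fully reproducible from seed.
    """
    n_samples = int(round(duration * fs))
    if n_samples < 4096:
        raise ValueError("duration * fs must be at least 4096 samples")
    rng = np.random.default_rng(seed)
    n_src = len(sources)
    sig = np.empty((n_src, n_samples))
    for i in range(n_src):
        sig[i] = narrowband_noise(n_samples, fs, coupling.band_for(i, n_src), rng)
    for (i, j, lag, strength) in coupling.pairs:
        mixed = strength * phase_shift(sig[i], lag) + (1.0 - strength) * sig[j]
        sig[j] = mixed / mixed.std()
    if coupling.noise_fraction > 0:
        nf = coupling.noise_fraction
        for i in range(n_src):
            extra = narrowband_noise(n_samples, fs, coupling.band_for(i, n_src), rng)
            mixed = (1.0 - nf) * sig[i] + nf * extra
            sig[i] = mixed / mixed.std()
    amps = np.array([s.amplitude for s in sources])
    return sig * amps[:, None]


def project(leadfields: list, moments: np.ndarray, signals: np.ndarray,
            noise_sd: float, seed: int, fs: float,
            channel_ids: list | None = None) -> SensorRecording:
    """Superpose dipolar fields at the sensors and add white sensor noise.

    ``leadfields`` is a list of (N, 2) matrices, ``moments`` the matching
    (n_sources, 2) tangential coefficients, ``signals`` the (n_sources, T)
    moment time-series in nAm.  Noise is i.i.d. Gaussian per channel and
    sample with standard deviation ``noise_sd`` Tesla.
    """
    moments = np.atleast_2d(np.asarray(moments, dtype=float))
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if not (len(leadfields) == moments.shape[0] == signals.shape[0]):
        raise ValueError("leadfields, moments and signals must agree on n_sources")
    n = leadfields[0].shape[0]
    gains = np.empty((len(leadfields), n))
    for i, L in enumerate(leadfields):
        if L.shape != (n, 2):
            raise ValueError("every lead field must be (N, 2) with a common N")
        gains[i] = L @ moments[i]
    data = gains.T @ signals
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(scale=noise_sd, size=data.shape)
    if channel_ids is None:
        channel_ids = [f"MEG{i:03d}" for i in range(n)]
    return SensorRecording(data=data, fs=fs, channel_ids=channel_ids)


# ---------------------------------------------------------------------------
# default sensor cap and toy parcellation


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (golden-angle lattice)."""
    k = np.arange(n)
    z = 1.0 - (k + 0.5) * 2.0 / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def hemispherical_cap(head: HeadModel, n_sensors: int = 150,
                      standoff: float = 0.02) -> SensorArray:
    """Radial magnetometers on the upper hemisphere at radius + standoff.

    Echoes a whole-head axial-magnetometer layout; N defaults to 150.
    """
    dirs = _fibonacci_directions(int(np.ceil(n_sensors / 0.4)))
    dirs = dirs[dirs[:, 2] > 0.05][:n_sensors]
    if len(dirs) < n_sensors:
        raise ValueError("could not place the requested number of cap sensors")
    positions = head.center + (head.radius + standoff) * dirs
    ids = [f"MEG{i:03d}" for i in range(n_sensors)]
    return SensorArray(ids=ids, positions=positions, orientations=dirs)


def make_toy_parcellation(head: HeadModel, K: int, voxels_per_roi: int,
                          spacing: float, seed: int):
    """Toy parcellation: K compact, disjoint ROIs of voxels inside the sphere.

    ROI centers sit on a quasi-uniform shell at 0.6 x radius (with a small
    seeded jitter); each ROI is a compact cluster of ``voxels_per_roi``
    grid points at ``spacing`` metres.  Raises if the clusters would
    overlap or poke outside the sphere.
    """
    from .parcellation import Parcellation

    rng = np.random.default_rng(seed)
    side = int(np.ceil(voxels_per_roi ** (1.0 / 3.0)))
    offsets = []
    for ix in range(side):
        for iy in range(side):
            for iz in range(side):
                offsets.append((ix, iy, iz))
    offsets = np.array(offsets[:voxels_per_roi], dtype=float)
    offsets -= offsets.mean(axis=0)
    offsets *= spacing
    cluster_radius = np.linalg.norm(offsets, axis=1).max() if voxels_per_roi > 1 else 0.0

    dirs = _fibonacci_directions(max(K, 2))[:K]
    centers = head.center + 0.6 * head.radius * dirs
    centers = centers + rng.normal(scale=0.05 * spacing, size=centers.shape)

    if K > 1:
        dmin = min(np.linalg.norm(centers[i] - centers[j])
                   for i in range(K) for j in range(i + 1, K))
        if dmin <= 2.0 * cluster_radius + 0.5 * spacing:
            raise ValueError("cannot fit requested voxel clusters disjointly inside sphere")

    voxel_ids, positions, labels = [], [], []
    for k in range(K):
        label = f"ROI{k:02d}"
        for v, off in enumerate(offsets):
            pos = centers[k] + off
            if np.linalg.norm(pos - head.center) >= 0.95 * head.radius:
                raise ValueError("cannot fit requested voxels inside sphere")
            voxel_ids.append(f"{label}_v{v:02d}")
            positions.append(pos)
            labels.append(label)
    return Parcellation(voxel_ids=voxel_ids,
                        positions=np.array(positions),
                        roi_of=labels)
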