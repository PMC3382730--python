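"""Phase-randomised surrogate null and group statistics.

Significance of group-mean node strength is assessed against surrogates
obtained by randomising the Fourier phases of every ROI time-series
independently while keeping the amplitude spectrum exactly.  Each of the
R realisations is pushed through the same connectivity chain (epoching,
estimator, epoch/subject averaging, node strength) and the maximum node
strength over ROIs is recorded, giving a null distribution of the
maximum statistic that controls the family-wise error rate across ROIs.
P-values use the standard permutation estimator (1 + #exceedances)/(R + 1).

Also provided: ordinary least-squares regression of node strength on
relative power (F test with df (1, K-2)) and the pooled-variance
two-sample t contrast between bands (df K_a + K_b - 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import (EPOCH_LENGTH, N_EPOCHS, average_adjacency,
                           epoch_adjacency, node_strength)


@dataclass
class NullDistribution:
    """R max-over-ROI node strengths from phase-randomised surrogates."""

    values: np.ndarray
    seed: int
    estimator: str

    def __post_init__(self):
        self.values = np.ravel(np.asarray(self.values, dtype=float))
        if self.values.size < 1:
            raise ValueError("null distribution needs at least one realisation")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("node strengths must lie in [0, 1]")

    @property
    def R(self):
        return self.values.size


@dataclass
class SignificanceMap:
    """Per-ROI corrected p-values and the alpha-thresholded mask."""

    p_values: np.ndarray
    significant: np.ndarray
    alpha: float


@dataclass
class RegressionResult:
    """OLS fit of node strength on relative power."""

    slope: float
    intercept: float
    F: float
    df: tuple
    p: float
    r_squared: float


def phase_randomize(series: np.ndarray, seed) -> np.ndarray:
    """Surrogate with the exact amplitude spectrum but uniform random phases.

    The DC and (for even length) Nyquist bins are left untouched; all
    other positive-frequency bins get independent uniform phases, with
    Hermitian symmetry implied by the real inverse FFT.  ``seed`` may be
    an integer or a numpy Generator.
    """
    series = np.asarray(series)
    if np.iscomplexobj(series):
        raise TypeError("phase randomisation is defined for real-valued series")
    series = series.astype(float)
    n = series.shape[-1]
    if n < 4:
        raise ValueError("series too short to phase-randomise")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = np.fft.rfft(series, axis=-1)
    n_bins = spec.shape[-1]
    hi = n_bins - 1 if n % 2 == 0 else n_bins  # exclude Nyquist bin when present
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape[:-1] + (hi - 1,))
    rot = np.ones(spec.shape, dtype=complex)
    rot[..., 1:hi] = np.exp(1j * phases)
    new_spec = np.abs(spec) * rot
    new_spec[..., 0] = spec[..., 0]  # DC untouched (keeps the original sign)
    if n % 2 == 0:
        new_spec[..., -1] = spec[..., -1]
    return np.fft.irfft(new_spec, n=n, axis=-1)


def null_distribution(roi_series_per_subject, estimator: str = "pli",
                      R: int = 100, seed: int = 0,
                      epoch_length: int = EPOCH_LENGTH,
                      n_epochs: int = N_EPOCHS) -> NullDistribution:
    """Max-statistic null over R independent phase-randomised realisations.

    ``roi_series_per_subject`` is a list of (K, T) arrays (one per
    subject) of band-limited ROI series.  Realisation r uses seed + r;
    every ROI series of every subject is randomised independently, the
    epoch -> subject -> group connectivity chain is re-run, and the
    maximum group-mean node strength over ROIs is recorded.
    """
    mats = [np.atleast_2d(np.asarray(m, dtype=float)) for m in roi_series_per_subject]
    if not mats:
        raise ValueError("need ROI series for at least one subject")
    maxima = np.empty(R)
    for r in range(R):
        rng = np.random.default_rng(seed + r)
        per_subject = []
        for m in mats:
            surr = phase_randomize(m, rng)
            per_subject.append(epoch_adjacency(surr, estimator, epoch_length, n_epochs))
        group = average_adjacency(per_subject, estimator=estimator)
        maxima[r] = node_strength(group).max()
    return NullDistribution(values=maxima, seed=seed, estimator=estimator)


def significance_map(strengths: np.ndarray, null: NullDistribution,
                     alpha: float = 0.05) -> SignificanceMap:
    """Corrected p-values p_i = (1 + #{null >= s_i}) / (R + 1)."""
    strengths = np.ravel(np.asarray(strengths, dtype=float))
    exceed = (null.values[None, :] >= strengths[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (null.R + 1.0)
    return SignificanceMap(p_values=p, significant=p <= alpha, alpha=alpha)


def regress_strength_on_power(power: np.ndarray, strength: np.ndarray) -> RegressionResult:
    """OLS of node strength on relative power with the F test on the slope.

    With K ROIs the F statistic has df (1, K-2); K = 68 gives F(1, 66).
    """
    power = np.ravel(np.asarray(power, dtype=float))
    strength = np.ravel(np.asarray(strength, dtype=float))
    k = power.size
    if k < 3:
        raise ValueError("regression needs at least 3 ROIs")
    if np.var(power) == 0:
        raise ValueError("zero variance in power: slope undefined")
    import statsmodels.api as sm

    fit = sm.OLS(strength, sm.add_constant(power)).fit()
    return RegressionResult(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                            F=float(fit.fvalue), df=(1, k - 2),
                            p=float(fit.f_pvalue), r_squared=float(fit.rsquared))


def two_sample_band_contrast(values_a: np.ndarray, values_b: np.ndarray):
    """Pooled-variance two-sample t between band maps; df = K_a + K_b - 2.

    Two groups of 68 ROI values give t(134).  Returns (t, df, p).
    """
    a = np.ravel(np.asarray(values_a, dtype=float))
    b = np.ravel(np.asarray(values_b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    if np.isnan(res.statistic):
        raise ValueError("zero pooled variance: t undefined")
    return float(res.statistic), df, float(res.pvalue)
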