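# Methods

## Problem and model

`megpli` reconstructs region-of-interest (ROI) source activity from
multichannel MEG recordings with a scalar adaptive beamformer and
estimates frequency-resolved functional connectivity between ROIs with
the Phase Lag Index (PLI), using the Phase Coherence (PC) as the
volume-conduction-sensitive reference estimator. Statistical
significance of group-mean connectivity is assessed non-parametrically
with a phase-randomised surrogate null corrected for multiple
comparisons by the maximum statistic.

### Forward model

The head is a single homogeneous conducting sphere. The external
magnetic field of a current dipole then has the closed-form (Sarvas)
solution; two of its properties structure the code:

* a radially oriented dipole is externally silent, so the lead field at
  a voxel is an N x 2 matrix over the two tangential orientations;
* the radial field component equals that of the primary dipole current
  alone (Biot-Savart), which the test suite uses as an independent
  oracle for the implementation.

Units are fixed throughout: positions in metres, dipole moments in nAm,
fields in Tesla, beamformer weights in nAm/T. The default synthetic
array is a hemispherical cap of 150 radial point magnetometers 2 cm
outside a 9 cm sphere, echoing a whole-head axial system; sampling rate
defaults to 312.5 Hz.

A multi-sphere or boundary-element conductor would be more accurate for
real anatomy; the beamformer is agnostic to the lead-field provider, and
for synthetic data (no scalp surface exists) the analytic sphere is both
exact and fast.

### Beamformer

For data covariance `Cb` and tangential lead field `L_theta` at a voxel,

    sigma_theta^2 = (L_theta' Cb^{-1} L_theta)^{-1}
    W             = sigma_theta^2 L_theta' Cb^{-1}
    V(t)          = W B(t)

giving unit gain (`W L_theta = 1`) and output power `W Cb W' =
sigma_theta^2`. The source orientation maximises the noise-normalised
output (pseudo-Z) `z^2 = (W Cb W')/(W Sigma W')`; restricted to the
tangential plane this is a 2 x 2 generalised Rayleigh quotient solved by
closed-form eigendecomposition (a 0.1-degree grid search is kept in the
tests as an oracle). The orientation sign is physically arbitrary; it is
fixed by making the first non-zero component positive, for
reproducibility only.

Numerical choices:

* `Cb` is the sample covariance (divisor T-1) of band-passed,
  mean-removed data; broadband 0.5-48 Hz by default. Inversion uses an
  eigendecomposition pseudo-inverse with relative truncation at 1e-12;
  no diagonal loading by default (a `regularize` option adds
  lambda * trace/N * I).
* The sensor-noise covariance `Sigma` defaults to sigma_n^2 I with
  sigma_n^2 the smallest eigenvalue of `Cb`; it can be supplied
  explicitly when an empty-room estimate exists.
* Weight vectors are normalised to unit norm before time-series
  reconstruction. Weights grow with source depth while sensor noise does
  not; the normalisation equalises projected noise across depths. It
  rescales the series by a positive constant, so phase-based metrics are
  unchanged; orientation is optimised before normalisation (pseudo-Z is
  scale-invariant, so the order is immaterial there).
* For covariance windows beyond 1e5 samples the band-pass is applied
  spectrally (the squared magnitude response of the same 4th-order
  Butterworth, accumulated via Parseval) instead of running filtfilt;
  the two paths agree to within sampling noise and the spectral path
  avoids materialising a second filtered copy of a long recording.

### ROI time-series

Band scheme: delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma
30-48 Hz. Filtering is a 4th-order Butterworth applied
forward-backward (zero phase), so the filter cannot manufacture phase
lags that PLI would later score. Band power is the variance of the
filtered series; relative power divides by the power in the full
0.5-48 Hz analysis band.

Within each ROI and band, the voxel with maximum band power (computed on
the normalised-weight virtual electrodes) represents the ROI; ties break
to the lowest voxel id. Voxel series are never averaged across a ROI:
the reconstructed orientation sign is arbitrary, so neighbouring virtual
electrodes can have opposite polarity and their average is meaningless.
Selection is independent per band and per subject.

### Connectivity

For two band-limited series the instantaneous phase difference
`dphi(t)` comes from Hilbert-transform analytic signals; no edge samples
are trimmed (with 4096-sample epochs the transients are negligible for
the statistics used). Then

    PC  = | mean_t exp(i dphi(t)) |
    PLI = | mean_t sign(sin dphi(t)) |       with sign(0) = 0.

PC is maximal for any constant phase difference including zero, and is
therefore inflated by field spread / volume conduction (equivalently, by
correlated beamformer weights). PLI responds only to an asymmetry of the
phase-difference distribution around zero and pi, so consistent zero-lag
mixing contributes nothing — at the cost of discarding true zero-lag
coupling. Exactly zero (to 1e-12) phase differences count as zero by
construction. The phase-difference interval convention ([-pi, pi) here)
does not affect either estimator.

Connectivity is computed on 5 non-overlapping epochs of 4096 samples
(13.1 s at 312.5 Hz) — the first five windows, as there is no synthetic
analogue of visual artefact screening — then averaged over epochs within
subject and over subjects. Node strength (weighted degree) is the mean
of a ROI's connectivity to all other ROIs; a thresholded integer degree
(edges above 20% of the maximum entry) is also provided.

### Surrogate statistics

Surrogates replace the Fourier phases of every ROI series independently
with uniform draws while keeping the amplitude spectrum bin-for-bin (DC
and Nyquist untouched), destroying all cross-series coupling. Each of R
(default 100) realisations is pushed through the same
epoch -> subject -> group connectivity chain, and the maximum group-mean
node strength over ROIs is recorded; comparing each observed strength to
this max-statistic null controls the family-wise error rate across
ROIs. P-values use the permutation estimator (1 + #exceedances)/(R + 1),
which cannot return zero. Surrogates are generated from the ROI series
(post-beamformer); the beamforming and voxel selection are not rerun per
realisation. No boundary-jump windowing is applied before
randomisation; the analysis bands (<= 48 Hz) suppress the high-frequency
artefacts that circular discontinuities could introduce.

Supporting statistics: ordinary least squares of node strength on
relative power with the slope F-test at df (1, K-2) (K = 68 ROIs gives
F(1, 66)), and pooled-variance two-sample t contrasts between band maps
(two maps of 68 give t(134)).

## Synthetic data

The generator produces band-limited Gaussian sources (white noise
spectrally masked to the carrier band, unit variance) at tangential
dipoles inside the sphere. A coupled pair (i, j, lag, strength) rebuilds
source j as `strength` times the lag-shifted copy of source i plus
`(1 - strength)` independent same-band noise, re-standardised; the lag
is applied as a constant analytic-signal phase rotation, so the planted
phase difference is exact at interior samples. Sensor noise is white
Gaussian per channel; SNR is quoted as the ratio of the strongest
channel's signal standard deviation to the sensor-noise standard
deviation.

What the generator does not emulate: 1/f background spectra,
non-stationarity, physiological artefacts (cardiac, ocular), gradiometer
geometry, co-registration error, and spatially extended or correlated
sources. Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not robustness to every
property of empirical recordings.

## Reference simulation studies (`megpli.experiments`)

Problem sizes were chosen so each study runs in minutes on one core.

* **Covariance-window bias.** One tangential delta-band (0.5-4 Hz)
  dipole, 150 sensors, best-channel SNR 5; source power via
  `sigma_theta^2` from a 175 s covariance window versus a 10x longer
  reference, 20 seeds. With the pipeline's broadband 0.5-48 Hz
  covariance the mean underestimation is ~1-2%, comfortably below 10%.
  Narrowing the covariance to the delta band itself (available via
  `cov_band`) inflates the finite-sample bias towards the
  inverse-Wishart value (N-1)/(2 BW T) ~ 12% for these parameters —
  which is precisely why the weights covariance is computed from
  broadband data.
* **Leakage dissociation.** Ten single-voxel ROIs in a fixed atlas-like
  geometry (five anchors with partners at 0.7-3.5 cm), one independent
  alpha source per ROI, best-channel SNR 1 (raw resting-state scale), 20
  seeds treated as subjects. Across ROI pairs, PC correlates strongly
  (r >= 0.5) with the squared beamformer weight correlation — the
  leakage made it — while |r| for PLI stays <= 0.2.
* **Calibration and power.** Under a global null (independent alpha-band
  ROI series, K = 10, 5 epochs of 4096), the fraction of 100 runs
  declaring any ROI significant at alpha = 0.05 stays <= 0.10. With
  coupling planted on 3 of 10 ROIs (strength 0.8, lag pi/4, in-band
  noise at SNR 5), planted ROIs are recovered with sensitivity >= 0.9
  over 20 runs (R = 100 surrogates each).

## Known limitations

* Single-sphere conductor and point-dipole lead fields only.
* The scalar beamformer assumes uncorrelated sources; strongly
  zero-lag-correlated sources are cancelled (PLI ignores zero-lag
  coupling anyway, so the two blind spots coincide).
* PLI underestimates true small-lag interactions in noise; no
  weighted-PLI variant is provided.
* Epoch selection takes the first windows; there is no artefact
  screening.
* The surrogate loop randomises ROI series, not sensor data, so it tests
  the connectivity chain rather than the full reconstruction chain.
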