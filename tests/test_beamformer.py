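"""Beamformer algebra, orientation optimisation, and the weight diagnostics."""

import numpy as np
import pytest

from megpli import beamformer as bf
from megpli import forward_sim as fwd
from megpli.connectivity import phase_difference, phase_lag_index


def _cov(matrix, n=10000, band=(0.5, 48.0)):
    return bf.DataCovariance(matrix=np.asarray(matrix, float), n_samples=n, band=band)


def random_spd(rng, n):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n) * 0.1


class TestComputeCovariance:
    fs = 312.5

    def test_uncorrelated_inband_channels(self):
        rng = np.random.default_rng(0)
        t = 20480
        data = np.vstack([fwd.narrowband_noise(t, self.fs, (0.5, 48.0), rng)
                          for _ in range(2)])
        rec = fwd.SensorRecording(data=data, fs=self.fs, channel_ids=["a", "b"])
        c = bf.compute_covariance(rec).matrix
        bound = 3.0 / np.sqrt(t)
        assert abs(c[0, 1]) < bound
        # diagonal: unit variance times the filter's passband energy gain
        from scipy.signal import butter, sosfreqz
        sos = butter(4, [0.5, 48.0], btype="bandpass", fs=self.fs, output="sos")
        f = np.linspace(0.5, 48.0, 2000)
        _, h = sosfreqz(sos, worN=2 * np.pi * f / self.fs)
        gain = np.mean(np.abs(h) ** 4)  # filtfilt applies |H|^2 to amplitudes
        assert abs(c[0, 0] - gain) < 3 * bound
        assert abs(c[1, 1] - gain) < 3 * bound

    def test_constant_channels_zero_matrix(self):
        data = np.ones((2, 4096))
        rec = fwd.SensorRecording(data=data, fs=self.fs, channel_ids=["a", "b"])
        c = bf.compute_covariance(rec).matrix
        np.testing.assert_allclose(c, 0.0, atol=1e-20)

    def test_duplicated_channel_warns(self):
        rng = np.random.default_rng(1)
        row = fwd.narrowband_noise(4096, self.fs, (8, 13), rng)
        rec = fwd.SensorRecording(data=np.vstack([row, row, rng.standard_normal(4096)]),
                                  fs=self.fs, channel_ids=list("abc"))
        with pytest.warns(UserWarning, match="rank deficient|ill conditioned"):
            bf.compute_covariance(rec)

    def test_too_short_or_bad_band_rejected(self):
        rec = fwd.SensorRecording(data=np.zeros((2, 1)), fs=self.fs, channel_ids=["a", "b"])
        with pytest.raises(ValueError):
            bf.compute_covariance(rec)
        rec2 = fwd.SensorRecording(data=np.zeros((2, 100)), fs=self.fs,
                                   channel_ids=["a", "b"])
        with pytest.raises(ValueError):
            bf.compute_covariance(rec2, band=(0.5, 200.0))

    def test_spectral_method_matches_sos(self):
        """Frequency-domain covariance agrees with time-domain filtfilt covariance."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 32768))
        rec = fwd.SensorRecording(data=data, fs=self.fs, channel_ids=list("abcd"))
        c_sos = bf.compute_covariance(rec, method="sos").matrix
        c_spec = bf.compute_covariance(rec, method="spectral").matrix
        scale = np.abs(c_sos).max()
        assert np.abs(c_sos - c_spec).max() < 0.03 * scale


class TestSourceVariance:
    def test_identity_unit_leadfield(self):
        assert bf.source_variance([1.0, 0.0], _cov(np.eye(2))) == pytest.approx(1.0)

    def test_scaled_identity(self):
        l = np.array([0.6, 0.8])
        assert bf.source_variance(l, _cov(5 * np.eye(2))) == pytest.approx(5.0)

    def test_hand_computed_2x2(self):
        # Cb = diag(2,1), L = (1,1): L' Cb^-1 L = 1/2 + 1 = 3/2 -> sigma2 = 2/3
        assert bf.source_variance([1.0, 1.0], _cov(np.diag([2.0, 1.0]))) == pytest.approx(2 / 3)


class TestComputeWeights:
    def test_hand_computed_2x2(self):
        w = bf.compute_weights([1.0, 1.0], _cov(np.diag([2.0, 1.0])))
        np.testing.assert_allclose(w, [1 / 3, 2 / 3], rtol=1e-12)

    def test_unit_gain_and_projected_variance_random_spd(self):
        """W L = 1 and W Cb W' = sigma2 on 100 random SPD covariances."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(3, 12))
            cb = _cov(random_spd(rng, n))
            l = rng.standard_normal(n)
            w = bf.compute_weights(l, cb)
            s2 = bf.source_variance(l, cb)
            assert abs(w @ l - 1.0) < 1e-9
            assert abs(w @ cb.matrix @ w - s2) < 1e-9 * s2


class TestOptimalOrientation:
    def _noise(self, n, s=1.0):
        return bf.NoiseCovariance(matrix=s * np.eye(n))

    def _grid_pseudo_z(self, L, cb, sigma, step_deg=0.1):
        """Brute-force 0.1-degree grid search oracle for the best pseudo-Z."""
        ang = np.deg2rad(np.arange(0.0, 180.0, step_deg))
        ci = np.linalg.pinv(cb.matrix)
        best_z, best_v = -np.inf, None
        vs = np.stack([np.cos(ang), np.sin(ang)])
        ws = (ci @ L @ vs).T  # unnormalised weights per angle
        num = np.einsum("ij,jk,ik->i", ws, cb.matrix, ws)
        den = np.einsum("ij,jk,ik->i", ws, sigma.matrix, ws)
        z = np.sqrt(num / den)
        k = int(np.argmax(z))
        return z[k], vs[:, k]

    def test_isotropic_tie_breaks_to_first_basis_direction(self):
        rng = np.random.default_rng(4)
        L = rng.standard_normal((8, 2))
        v = bf.optimal_orientation(L, _cov(np.eye(8)), self._noise(8))
        np.testing.assert_allclose(v, [1.0, 0.0])

    def test_planted_orientation_recovered(self):
        rng = np.random.default_rng(5)
        L = rng.standard_normal((10, 2))
        u = np.array([np.cos(0.7), np.sin(0.7)])
        lu = L @ u
        cb = _cov(np.eye(10) + 10.0 * np.outer(lu, lu))
        v = bf.optimal_orientation(L, cb, self._noise(10))
        angle = np.degrees(np.arccos(np.clip(abs(v @ u), -1, 1)))
        assert angle < 1.0

    def test_matches_grid_search_on_random_cases(self):
        rng = np.random.default_rng(6)
        sigma_template = None
        for _ in range(100):
            n = int(rng.integers(4, 16))
            L = rng.standard_normal((n, 2))
            cb = _cov(random_spd(rng, n))
            sigma = bf.NoiseCovariance(matrix=np.diag(rng.uniform(0.5, 2.0, n)))
            v = bf.optimal_orientation(L, cb, sigma)
            w = bf.compute_weights(L @ v, cb)
            z = bf.pseudo_z(w, cb, sigma)
            z_grid, _ = self._grid_pseudo_z(L, cb, sigma)
            assert z >= z_grid * (1.0 - 1e-9)

    def test_rank_deficient_leadfield_rejected(self):
        L = np.outer(np.arange(1.0, 6.0), [1.0, 2.0])
        with pytest.raises(np.linalg.LinAlgError):
            bf.optimal_orientation(L, _cov(np.eye(5)), self._noise(5))


class TestPseudoZ:
    def test_noise_only_gives_one(self):
        rng = np.random.default_rng(7)
        m = random_spd(rng, 5)
        w = rng.standard_normal(5)
        # with Cb equal to Sigma the ratio is exactly 1 for any weights
        sigma = bf.NoiseCovariance(matrix=np.diag(np.diag(m)))
        cb = _cov(np.diag(np.diag(m)))
        assert bf.pseudo_z(w, cb, sigma) == pytest.approx(1.0)

    def test_fourfold_power_doubles_z(self):
        sigma = bf.NoiseCovariance(matrix=np.eye(4))
        w = np.array([1.0, -2.0, 0.5, 0.0])
        assert bf.pseudo_z(w, _cov(4 * np.eye(4)), sigma) == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        cb = _cov(random_spd(rng, 6))
        sigma = bf.NoiseCovariance(matrix=np.eye(6))
        w = rng.standard_normal(6)
        assert abs(bf.pseudo_z(w, cb, sigma) - bf.pseudo_z(10 * w, cb, sigma)) < 1e-12


class TestNormalizeAndReconstruct:
    def test_three_four_five(self):
        np.testing.assert_allclose(bf.normalize_weights([3.0, 4.0]), [0.6, 0.8])

    def test_unit_norm(self, rng):
        w = bf.normalize_weights(rng.standard_normal(20))
        assert abs(np.linalg.norm(w) - 1.0) < 1e-12

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            bf.normalize_weights(np.zeros(5))

    def test_pli_invariant_to_weight_normalisation(self):
        rng = np.random.default_rng(9)
        data = np.vstack([fwd.narrowband_noise(4096, 312.5, (8, 13), rng)
                          for _ in range(4)])
        rec = fwd.SensorRecording(data=data, fs=312.5, channel_ids=list("abcd"))
        w1 = rng.standard_normal(4)
        w2 = rng.standard_normal(4)
        v1 = bf.reconstruct_timeseries(w1, rec).series
        v2 = bf.reconstruct_timeseries(w2, rec).series
        v1n = bf.reconstruct_timeseries(bf.normalize_weights(w1), rec).series
        v2n = bf.reconstruct_timeseries(bf.normalize_weights(w2), rec).series
        pli = phase_lag_index(phase_difference(v1, v2))
        pli_n = phase_lag_index(phase_difference(v1n, v2n))
        assert abs(pli - pli_n) < 1e-12

    def test_unit_weight_returns_channel(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((3, 500))
        rec = fwd.SensorRecording(data=data, fs=100.0, channel_ids=list("abc"))
        w = np.array([1.0, 0.0, 0.0])
        np.testing.assert_array_equal(bf.reconstruct_timeseries(w, rec).series, data[0])

    def test_linearity_in_data(self):
        rng = np.random.default_rng(11)
        d1, d2 = rng.standard_normal((2, 3, 500))
        w = rng.standard_normal(3)
        va = bf.reconstruct_timeseries(w, fwd.SensorRecording(2 * d1 + 3 * d2, 100.0, list("abc"))).series
        vb = 2 * bf.reconstruct_timeseries(w, fwd.SensorRecording(d1, 100.0, list("abc"))).series \
            + 3 * bf.reconstruct_timeseries(w, fwd.SensorRecording(d2, 100.0, list("abc"))).series
        np.testing.assert_allclose(va, vb, rtol=1e-10)

    def test_forward_inverse_recovers_source(self, head, sensors):
        """Weights at the true location reconstruct the source at SNR >= 5."""
        fs = 312.5
        src = fwd.DipoleSource(location=(0.025, 0.0, 0.04),
                               moment_direction=np.cross([0.025, 0.0, 0.04], [0, 0, 1.0]))
        src.validate(head)
        l = fwd.lead_field_for(head, sensors, src)
        rng = np.random.default_rng(12)
        sig = fwd.narrowband_noise(20480, fs, (8, 13), rng)[None, :]
        noise_sd = np.abs(l).max() / 5.0
        L = fwd.lead_field(head, sensors, src.location)
        coeff = fwd.tangential_coefficients(head, src.location, src.moment_direction)
        rec = fwd.project([L], [coeff], sig, noise_sd, seed=13, fs=fs)
        cb = bf.compute_covariance(rec)
        w = bf.compute_weights(l, cb)
        v = bf.reconstruct_timeseries(w, rec).series
        corr = np.corrcoef(v, sig[0])[0, 1]
        assert abs(corr) >= 0.95


class TestWeightCorrelationMatrix:
    def test_identical_vectors_give_one(self):
        w = np.arange(5.0)
        m = bf.weight_correlation_matrix([w, w.copy()])
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 0] == 0.0 and m[1, 1] == 0.0

    def test_orthogonal_zero_mean_vectors_give_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert bf.weight_correlation_matrix([a, b])[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_pearson(self, rng):
        vs = [rng.standard_normal(30) for _ in range(3)]
        m = bf.weight_correlation_matrix(vs)
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(vs[i], vs[j])[0, 1] ** 2
                assert m[i, j] == pytest.approx(r, rel=1e-12)
                assert m[j, i] == pytest.approx(m[i, j], rel=1e-12)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            m = bf.weight_correlation_matrix([np.ones(4), np.arange(4.0)])
        assert np.isnan(m[0, 1])


class TestLocalization:
    def test_two_sources_peak_within_one_voxel(self, head, sensors):
        """Pseudo-Z over a voxel grid peaks at each of two uncorrelated sources."""
        fs = 312.5
        spacing = 0.01
        locs = [np.array([0.03, 0.0, 0.04]), np.array([-0.03, 0.0, 0.04])]
        sources = [fwd.DipoleSource(location=l,
                                    moment_direction=np.cross(l, [0, 0, 1.0]))
                   for l in locs]
        coupling = fwd.CouplingSpec(carrier_band=(8, 13))
        sig = fwd.simulate_sources(sources, coupling, 20480 / fs, fs, seed=20)
        Ls = [fwd.lead_field(head, sensors, l) for l in locs]
        coeffs = [fwd.tangential_coefficients(head, s.location, s.moment_direction)
                  for s in sources]
        noise_sd = max(np.abs(L @ c).max() for L, c in zip(Ls, coeffs)) / 10.0
        rec = fwd.project(Ls, coeffs, sig, noise_sd, seed=21, fs=fs)
        cb = bf.compute_covariance(rec)
        sigma = bf.default_noise_covariance(cb)

        xs = np.arange(-0.05, 0.051, spacing)
        grid = [np.array([x, 0.0, z]) for x in xs for z in (0.03, 0.04, 0.05)]
        zvals, positions = [], []
        for g in grid:
            L = fwd.lead_field(head, sensors, g)
            basis = np.vstack(fwd.tangential_basis(head, g))
            est = bf.estimate_source("v", L, basis, cb, sigma)
            zvals.append(est.pseudo_z)
            positions.append(g)
        zvals = np.array(zvals)
        positions = np.array(positions)
        for true_loc in locs:
            # argmax within the source's half of the grid lies within one voxel
            local = np.linalg.norm(positions - true_loc, axis=1) <= 0.03
            peak = positions[local][int(np.argmax(zvals[local]))]
            assert np.linalg.norm(peak - true_loc) <= spacing * 1.01

    def test_depth_bias_equalised_by_normalisation(self, head, sensors):
        """Normalised weights give depth-independent projected noise variance."""
        fs = 312.5
        rng = np.random.default_rng(22)
        data = rng.standard_normal((len(sensors), 20480)) * 1e-14
        rec = fwd.SensorRecording(data=data, fs=fs, channel_ids=sensors.ids)
        cb = bf.compute_covariance(rec)
        depths = [0.02, 0.04, 0.06, 0.075]  # |location| in metres, +z axis offset
        var_norm, var_raw = [], []
        for d in depths:
            loc = np.array([0.0, d / np.sqrt(2), d / np.sqrt(2)])
            L = fwd.lead_field(head, sensors, loc)
            w = bf.compute_weights(L[:, 0], cb)
            var_raw.append(bf.reconstruct_timeseries(w, rec).series.var())
            wn = bf.normalize_weights(w)
            var_norm.append(bf.reconstruct_timeseries(wn, rec).series.var())
        var_norm, var_raw = np.array(var_norm), np.array(var_raw)
        assert var_norm.max() / var_norm.min() < 1.5
        # unnormalised weights blow up the projected noise for deep sources
        # (depths[0] is nearest the sphere center, depths[-1] nearest the cap)
        assert var_raw[0] > 10.0 * var_raw[-1]
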