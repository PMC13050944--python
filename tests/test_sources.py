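"""Spherical forward model, sLORETA inverse, SnPM permutation contrast."""

import numpy as np
import pytest

from prestate import sources as src


class TestForwardModel:
    def test_series_matches_infinite_medium_oracle(self, rng):
        """With the trivial radial solution (1/r^(n+1) at the scalp) the
        series must reproduce the closed-form infinite-medium dipole
        potential -- this pins the angular machinery and sign conventions."""
        e = rng.standard_normal((20, 3))
        e /= np.linalg.norm(e, axis=1, keepdims=True)
        R, sigma = 0.1, 0.33
        g = np.ones(81)
        g[0] = 0.0
        for _ in range(5):
            pos = rng.uniform(-0.03, 0.03, 3)
            q = rng.standard_normal(3) * 1e-8
            v_series = src._series_potential(e * R, pos, g, sigma, R) @ q
            v_closed = src.dipole_potential_infinite(e * R, pos, q, sigma)
            assert np.allclose(v_series, v_closed, rtol=1e-9)

    def test_equal_conductivity_reduces_to_homogeneous_sphere(self):
        """With sigma1 = sigma2 = sigma3 the layered solver must give the
        classical bounded-sphere coefficients (2n+1)/n."""
        gn = src._radial_coefficients((0.087, 0.092, 0.1), (0.33, 0.33, 0.33), 40)
        n = np.arange(1, 41)
        assert np.allclose(gn[1:], (2 * n + 1) / n, rtol=1e-12)

    def test_central_dipole_closed_form(self, rng):
        """A dipole at the center of a homogeneous bounded sphere produces
        V = 3 q cos(theta) / (4 pi sigma R^2)."""
        e = rng.standard_normal((15, 3))
        e /= np.linalg.norm(e, axis=1, keepdims=True)
        R, sigma = 0.1, 0.33
        gn = src._radial_coefficients((0.087, 0.092, R), (sigma, sigma, sigma), 40)
        q = 1e-8
        v = src._series_potential(e * R, np.zeros(3), gn, sigma, R) @ np.array([0, 0, q])
        assert np.allclose(v, 3 * q * e[:, 2] / (4 * np.pi * sigma * R**2), rtol=1e-12)

    def test_gain_columns_finite_positive_and_linear(self, tiny_leadfield):
        lf = tiny_leadfield
        norms = np.linalg.norm(lf.gain, axis=0)
        assert np.all(np.isfinite(lf.gain))
        assert np.all(norms > 0)
        # linearity: doubling the moment doubles the potential
        phi1 = lf.gain[:, :3] @ np.array([1.0, 0.5, -0.2])
        phi2 = lf.gain[:, :3] @ np.array([2.0, 1.0, -0.4])
        assert np.allclose(phi2, 2 * phi1)

    def test_gain_rows_average_referenced(self, tiny_leadfield):
        assert np.max(np.abs(tiny_leadfield.gain.mean(axis=0))) < 1e-12

    def test_skull_conductivity_attenuates_potentials(self, elec_positions):
        """A resistive skull layer shrinks scalp potentials relative to a
        homogeneous head (physical sanity of the layered solve)."""
        sig_real = src._radial_coefficients(src.DEFAULT_RADII, src.DEFAULT_SIGMAS, 40)
        sig_homog = src._radial_coefficients(src.DEFAULT_RADII, (0.33, 0.33, 0.33), 40)
        assert np.all(sig_real[1:] < sig_homog[1:])


class TestSloreta:
    def test_zero_localization_error(self, tiny_leadfield, rng):
        lf = tiny_leadfield
        for _ in range(10):
            v = int(rng.integers(lf.n_voxels))
            phi = lf.gain[:, 3 * v : 3 * v + 3] @ rng.standard_normal(3)
            est = src.sloreta_inverse(lf, phi, alpha=0.0)
            assert est.peak_voxel == v

    def test_zero_map_zero_estimate(self, tiny_leadfield):
        est = src.sloreta_inverse(tiny_leadfield, np.zeros(32), alpha="auto")
        assert np.allclose(est.power, 0.0)

    def test_quadratic_scaling(self, tiny_leadfield, rng):
        phi = tiny_leadfield.gain[:, 30:33] @ rng.standard_normal(3)
        a = src.sloreta_inverse(tiny_leadfield, phi, alpha="auto")
        b = src.sloreta_inverse(tiny_leadfield, 3.0 * phi, alpha="auto")
        assert np.allclose(b.power, 9.0 * a.power, rtol=1e-8)

    def test_minimum_norm_linearity_before_standardization(self, tiny_leadfield, rng):
        lf = tiny_leadfield
        p1 = lf.gain[:, 3:6] @ rng.standard_normal(3)
        p2 = lf.gain[:, 60:63] @ rng.standard_normal(3)
        ja = src.sloreta_inverse(lf, p1, alpha=1e-12).current
        jb = src.sloreta_inverse(lf, p2, alpha=1e-12).current
        jab = src.sloreta_inverse(lf, 2 * p1 + 3 * p2, alpha=1e-12).current
        assert np.allclose(jab, 2 * ja + 3 * jb, atol=1e-6 * np.abs(jab).max())

    def test_negative_alpha_rejected(self, tiny_leadfield):
        with pytest.raises(ValueError):
            src.sloreta_inverse(tiny_leadfield, np.zeros(32), alpha=-1.0)


class TestSnPM:
    def test_identical_groups_nothing_suprathreshold(self, rng):
        a = rng.standard_normal((8, 50))
        res = src.snpm_paired_contrast(a, a.copy() + 1e-14 * rng.standard_normal((8, 50)),
                                       n_permutations=1000, seed=0)
        assert res.suprathreshold.size == 0

    def test_enumeration_rule(self, rng):
        """10 subjects: 2^10 = 1024 < 5000 requested, so the full sign-flip
        set is enumerated."""
        a = rng.standard_normal((10, 30))
        b = rng.standard_normal((10, 30))
        res = src.snpm_paired_contrast(a, b, n_permutations=5000, seed=0)
        assert res.enumerated and res.n_permutations == 1024

    def test_sampling_when_enumeration_too_large(self, rng):
        a = rng.standard_normal((20, 30))
        b = rng.standard_normal((20, 30))
        res = src.snpm_paired_contrast(a, b, n_permutations=500, seed=0)
        assert not res.enumerated and res.n_permutations == 500

    def test_observed_t_matches_scipy(self, rng):
        from scipy import stats as sps

        a = rng.standard_normal((12, 20))
        b = rng.standard_normal((12, 20))
        res = src.snpm_paired_contrast(a, b, n_permutations=200, seed=0)
        t_ref = sps.ttest_rel(a, b, axis=0).statistic
        assert np.allclose(res.t, t_ref, rtol=1e-10)

    def test_planted_focal_effect_detected(self):
        """A strong effect (d = 2) in 5% of voxels is detected while false
        positives outside the planted region stay controlled."""
        detected, false_any = 0, 0
        n_rep = 25
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            nv = 200
            effect = np.zeros(nv)
            effect[:10] = 2.0
            a = rng.standard_normal((10, nv)) + effect
            b = rng.standard_normal((10, nv))
            res = src.snpm_paired_contrast(a, b, n_permutations=5000, seed=seed)
            if np.intersect1d(res.suprathreshold, np.arange(10)).size > 0:
                detected += 1
            if np.setdiff1d(res.suprathreshold, np.arange(10)).size > 0:
                false_any += 1
        assert detected >= 0.8 * n_rep
        assert false_any <= 0.2 * n_rep
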