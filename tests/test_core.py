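"""GFP, spatial correlation, modified k-means, GEV, meta-criterion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from prestate import core, synth
from prestate.validation import gev_oracle


class TestGfp:
    def test_constant_vector_zero(self):
        assert core.gfp(np.full(5, 3.3)) == 0.0

    def test_two_channel_unit(self):
        assert core.gfp(np.array([1.0, -1.0])) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_direct_formula(self, seed):
        v = np.random.default_rng(seed).standard_normal(5) * 10
        direct = np.sqrt(np.sum((v - v.mean()) ** 2) / v.size)
        assert core.gfp(v) == pytest.approx(direct, rel=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            core.gfp(np.array([1.0, np.nan, 0.0]))


class TestPeaks:
    def test_monotone_no_peaks(self):
        assert core.find_gfp_peaks(np.arange(10.0)).size == 0

    def test_simple_peaks(self):
        assert core.find_gfp_peaks(np.array([0, 1, 0, 2, 0.0])).tolist() == [1, 3]

    def test_plateau_first_sample(self):
        assert core.find_gfp_peaks(np.array([0, 1, 1, 1, 0.0])).tolist() == [1]

    def test_endpoints_excluded(self):
        assert core.find_gfp_peaks(np.array([2, 1, 0, 1, 2.0])).size == 0

    def test_sinusoid_cycle_count(self):
        t = np.linspace(0, 5, 1000, endpoint=False)
        g = 1.0 + 0.5 * np.sin(2 * np.pi * t)
        assert core.find_gfp_peaks(g).size == 5


class TestSpatialCorrelation:
    def test_self_and_negation(self, rng):
        a = rng.standard_normal(32)
        assert core.spatial_correlation(a, a) == pytest.approx(1.0)
        assert core.spatial_correlation(a, -a) == pytest.approx(1.0)

    def test_orthogonal_maps_zero(self):
        a = np.array([1.0, -1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, -1.0])
        assert core.spatial_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            core.spatial_correlation(np.ones(4), np.array([1.0, 2, 3, 4]))


class TestModifiedKmeans:
    def test_single_template_recovery(self, rng):
        t = core.normalize_maps(rng.standard_normal((1, 16)))[0]
        X = np.outer(rng.choice([-1, 1], 40) * rng.uniform(0.5, 2, 40), t)
        fit = core.modified_kmeans(X, 1, n_restarts=3, seed=0)
        assert core.spatial_correlation(fit.templates.maps[0], t) == pytest.approx(1.0)
        assert fit.templates.gev_total == pytest.approx(1.0, abs=1e-12)

    def test_two_orthogonal_templates_with_flips(self):
        rng = np.random.default_rng(3)
        T = synth.random_orthonormal_maps(2, 16, rng)
        X = np.vstack([np.outer(rng.choice([-1, 1], 30), T[k]) for k in range(2)])
        fit = core.modified_kmeans(X, 2, n_restarts=5, seed=1)
        from prestate.twolevel import match_maps
        _, cc = match_maps(T, fit.templates.maps)
        assert np.all(cc >= 0.999)
        assert fit.templates.gev_total == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_under_seed(self, rng):
        X = rng.standard_normal((60, 16))
        a = core.modified_kmeans(X, 3, n_restarts=5, seed=42)
        b = core.modified_kmeans(X, 3, n_restarts=5, seed=42)
        assert np.array_equal(a.templates.maps, b.templates.maps)
        assert np.array_equal(a.segmentation.labels, b.segmentation.labels)

    def test_k_larger_than_m_rejected(self, rng):
        with pytest.raises(ValueError):
            core.modified_kmeans(rng.standard_normal((3, 8)), 5, seed=0)

    def test_gev_monotone_ascent(self, rng):
        """The GEV objective never decreases across k-means iterations."""
        X = rng.standard_normal((200, 16))
        fit = core.modified_kmeans(X, 4, n_restarts=3, seed=7)
        trace = np.array(fit.gev_trace)
        assert np.all(np.diff(trace) >= -1e-12)

    def test_polarity_invariance_exact(self, rng):
        X = rng.standard_normal((80, 16))
        flip = rng.choice([-1.0, 1.0], 80)
        a = core.modified_kmeans(X, 3, n_restarts=4, seed=9)
        b = core.modified_kmeans(X * flip[:, None], 3, n_restarts=4, seed=9)
        assert np.array_equal(a.segmentation.labels, b.segmentation.labels)
        assert np.array_equal(a.templates.maps, b.templates.maps)

    def test_channel_permutation_equivariance(self, rng):
        X = rng.standard_normal((80, 16))
        perm = rng.permutation(16)
        a = core.modified_kmeans(X, 3, n_restarts=4, seed=11)
        b = core.modified_kmeans(X[:, perm], 3, n_restarts=4, seed=11)
        assert np.array_equal(a.segmentation.labels, b.segmentation.labels)
        assert np.allclose(a.templates.maps[:, perm], b.templates.maps, atol=1e-8)


class TestGev:
    def test_noiseless_template_data_unity(self):
        rng = np.random.default_rng(5)
        T = synth.random_orthonormal_maps(3, 12, rng)
        labels = rng.integers(0, 3, 100)
        amps = rng.uniform(0.5, 3.0, 100)
        signs = rng.choice([-1.0, 1.0], 100)
        X = (signs * amps)[:, None] * T[labels]
        per_map, total = core.gev(X, T, labels)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert per_map.sum() == pytest.approx(total, abs=1e-12)

    def test_orthogonal_templates_zero(self):
        rng = np.random.default_rng(6)
        T = synth.random_orthonormal_maps(2, 12, rng)
        X = np.outer(rng.standard_normal(50), T[0])
        _, total = core.gev(X, T[1:], np.zeros(50, dtype=int))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_matches_straight_loop_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((120, 16))
        fit = core.modified_kmeans(X, 2, n_restarts=3, seed=0)
        # label every map (not only the clustered assignment) via the fit
        labels = fit.segmentation.labels
        per, total = core.gev(X, fit.templates.maps, labels)
        per_o, total_o = gev_oracle(X, fit.templates.maps, labels)
        assert np.allclose(per, per_o, atol=1e-10)
        assert total == pytest.approx(total_o, abs=1e-10)
        assert 0.0 <= total <= 1.0

    def test_zero_gfp_rejected(self):
        with pytest.raises(ValueError):
            core.gev(np.zeros((10, 8)) + 1.0, np.eye(8)[:2] - 1 / 8, np.zeros(10, dtype=int))


class TestMetaCriterion:
    def test_median_of_seven(self):
        assert core._lower_median([3, 4, 4, 5, 6, 7, 8]) == 5

    def test_even_count_ties_to_smaller(self):
        assert core._lower_median([4, 4, 6, 8]) == 4

    def test_all_agree(self, rng):
        X = np.vstack([
            np.outer(rng.choice([-1, 1], 40) * rng.uniform(0.8, 1.2, 40), t)
            for t in synth.random_orthonormal_maps(3, 16, np.random.default_rng(1))
        ]) + 0.02 * rng.standard_normal((120, 16))
        fits = core.fit_k_range(X, range(2, 7), n_restarts=5, seed=2)
        meta = core.validity_criteria(X, fits)
        if len(set(meta.optima.values())) == 1:
            assert meta.meta_k == next(iter(meta.optima.values()))

    def test_planted_four_templates_recovered(self):
        """Meta-criterion selects K=4 for 4 well-separated planted clusters
        in a majority of seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            T = synth.random_orthonormal_maps(4, 24, rng)
            X = np.vstack([
                np.outer(rng.choice([-1, 1], 50), T[k]) for k in range(4)
            ]) + 0.15 * rng.standard_normal((200, 24))
            fits = core.fit_k_range(X, range(2, 9), n_restarts=5, seed=seed)
            if core.validity_criteria(X, fits).meta_k == 4:
                hits += 1
        assert hits >= 6

    def test_too_few_k_values_rejected(self, rng):
        X = rng.standard_normal((30, 8))
        fits = core.fit_k_range(X, [2, 3], n_restarts=2, seed=0)
        with pytest.raises(ValueError):
            core.validity_criteria(X, fits)
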