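"""Synthetic generator: planted structure, determinism, noise shape."""

import numpy as np
import pytest
from scipy import signal as sps_signal

from prestate import core, synth


def test_ground_truth_invariants(small_truth):
    assert np.allclose(small_truth.maps.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(np.linalg.norm(small_truth.maps, axis=1), 1, atol=1e-12)
    assert np.allclose(small_truth.prevalence.sum(axis=2), 1)


def test_invalid_ground_truth_rejected():
    maps = np.array([[1.0, -1.0, 0.0]]) / np.sqrt(2)
    prev = np.ones((1, 1, 1))
    with pytest.raises(ValueError):
        synth.GroundTruth(maps=maps + 0.3, prevalence=prev)   # not centered
    with pytest.raises(ValueError):
        synth.GroundTruth(maps=maps, prevalence=prev, snr=0.0)
    with pytest.raises(ValueError):
        synth.GroundTruth(maps=maps, prevalence=prev * 0.5)   # doesn't sum to 1


def test_noiseless_single_template_peaks_match_planted():
    """With snr -> inf and one planted map, every GFP-peak topography is the
    planted map up to polarity."""
    truth = synth.make_ground_truth(n_maps=1, n_subjects=1, n_conditions=1,
                                    seed=5, snr=np.inf)
    ep = synth.generate_epochs(truth, 1, 1, 2)
    for tr in range(2):
        trial = ep.data[0, 0, tr]
        g = core.gfp_series(trial)
        for pk in core.find_gfp_peaks(g):
            assert core.spatial_correlation(trial[:, pk], truth.maps[0]) == pytest.approx(1.0)


def test_segment_label_fractions_binomial():
    """Realized segment labels follow the prevalence within 3 binomial SEs."""
    rng = np.random.default_rng(0)
    prev = np.array([0.5, 0.5])
    counts = np.zeros(2)
    n_seg = 0
    for _ in range(50):
        _, segments = synth._segment_plan(rng, 10_000, 10.0, prev)
        for _, _, k in segments:
            counts[k] += 1
            n_seg += 1
    frac = counts[0] / n_seg
    se = np.sqrt(0.25 / n_seg)
    assert abs(frac - 0.5) < 3 * se


def test_generate_epochs_deterministic():
    truth = synth.make_ground_truth(n_maps=3, n_subjects=2, n_conditions=2, seed=77)
    a = synth.generate_epochs(truth, 2, 2, 3)
    b = synth.generate_epochs(truth, 2, 2, 3)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.planted_labels, b.planted_labels)


def test_channel_mismatch_rejected(small_truth):
    with pytest.raises(ValueError, match="planted map dimension"):
        synth.generate_epochs(small_truth, 3, 3, 2, n_channels=16)


def test_average_reference_closure(small_epochs):
    """Every generated sample is average-referenced (templates and noise)."""
    means = small_epochs.data.mean(axis=3)
    assert np.max(np.abs(means)) < 1e-10


def test_noise_spectrum_is_pink():
    """Noise-only data shows monotonically decreasing binned power, 1-30 Hz."""
    rng = np.random.default_rng(4)
    x = np.concatenate([synth._pink_noise(rng, 8, 4096, 250.0) for _ in range(8)], axis=1)
    f, p = sps_signal.welch(x, fs=250.0, nperseg=2048, axis=1)
    pm = p.mean(axis=0)
    edges = [1, 4, 8, 16, 30]
    band_power = [pm[(f >= lo) & (f < hi)].mean() for lo, hi in zip(edges, edges[1:])]
    assert all(a > b for a, b in zip(band_power, band_power[1:]))


def test_epoch_snr_close_to_requested():
    """Signal/noise RMS ratio matches the requested SNR.

    Single-trial sets keep the RNG stream aligned between the noisy and
    noiseless generations, so their difference isolates the noise.
    """
    sig_pow, noise_pow = 0.0, 0.0
    for seed in range(11, 31):
        noisy = synth.make_ground_truth(n_maps=2, n_subjects=1, n_conditions=1,
                                        seed=seed, snr=2.0)
        clean = synth.make_ground_truth(n_maps=2, n_subjects=1, n_conditions=1,
                                        seed=seed, snr=np.inf)
        a = synth.generate_epochs(noisy, 1, 1, 1).data
        s = synth.generate_epochs(clean, 1, 1, 1).data
        sig_pow += np.mean(s**2)
        noise_pow += np.mean((a - s) ** 2)
    assert np.sqrt(sig_pow / noise_pow) == pytest.approx(2.0, rel=0.05)


class TestBehavior:
    def test_zero_shift_zero_noise_identical_rt(self):
        truth = synth.make_ground_truth(n_maps=2, n_subjects=4, n_conditions=3,
                                        seed=1, rt_shift=np.zeros(3))
        tab = synth.generate_behavior(truth, 4, 3, noise_sd_ms=0.0)
        wide = tab.pivot(index="subject", columns="condition",
                         values="reaction_time_ms")
        assert np.allclose(wide.to_numpy(), wide.to_numpy()[:, [0]])

    def test_emg_scale_doubles_rms(self):
        truth = synth.make_ground_truth(n_maps=2, n_subjects=3, n_conditions=2,
                                        seed=2, emg_scale=np.array([1.0, 2.0]))
        tab = synth.generate_behavior(truth, 3, 2, emg_noise_cv=0.0)
        wide = tab.pivot(index="subject", columns="condition", values="rms_emg")
        assert np.allclose(wide[1] / wide[0], 2.0)

    def test_monotone_scale_orders_emg(self):
        truth = synth.make_ground_truth(n_maps=2, seed=3)
        tab = synth.generate_behavior(truth, 10, 5)
        med = tab.groupby("condition")["rms_emg"].median()
        assert med.is_monotonic_increasing


class TestEmgOnsets:
    def test_onset_indices_and_reproducibility(self, small_truth):
        layout = synth.TrialLayout(n_trials=5)
        a = synth.generate_emg_and_onsets(small_truth, layout, condition=1)
        b = synth.generate_emg_and_onsets(small_truth, layout, condition=1)
        assert np.array_equal(a["onset_kin"], b["onset_kin"])
        assert np.array_equal(a["emg"], b["emg"])
        # kinematic trace rises at onset: below half-max before, above after rise
        kin = a["kinematics"][0]
        onset = a["onset_kin"][0]
        assert kin[onset - 5] < 0.1 and kin[onset + 60] > 0.9

    def test_emg_scale_doubles_in_movement_rms(self):
        truth = synth.make_ground_truth(n_maps=2, n_conditions=2, seed=8,
                                        emg_scale=np.array([1.0, 2.0]))
        layout = synth.TrialLayout(n_trials=2)
        lo = synth.generate_emg_and_onsets(truth, layout, condition=0)
        hi = synth.generate_emg_and_onsets(truth, layout, condition=1)
        def in_rms(d):
            a, b = d["onset_emg"][0], d["offset_emg"][0]
            return np.sqrt(np.mean(d["emg"][0][a:b] ** 2))
        # same per-condition RNG stream shape; ratio of RMS equals the scale
        assert in_rms(hi) / in_rms(lo) == pytest.approx(2.0, rel=0.05)
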