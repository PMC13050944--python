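"""Ground-truth validation benchmarks.

Each function plants a known structure with the synthetic generator (or a
closed-form signal), runs the corresponding analysis path, and measures how
well it is recovered.  These are the package's own correctness benchmarks:
the test suite asserts on them and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from scipy import signal, stats as sps

from . import core, sources, stats, synth, twolevel
from .montage import channel_positions
from .preprocess import FilterSpec, bandpass, downsample


def planted_template_recovery(
    n_seeds: int = 10,
    base_seed: int = 0,
    *,
    n_maps: int = 8,
    snr: float = 2.0,
    k_range: range = range(2, 13),
    n_restarts: int = 10,
) -> dict:
    """Across-subject recovery of planted orthogonalized templates.

    For each seed, 10 subjects x 5 conditions x 10 trials are generated at
    the given SNR, the full two-level meta-criterion pipeline is run, and
    the selected K plus the matched |spatial correlation| against the
    planted maps are recorded.
    """
    meta_ks, min_corrs = [], []
    for i in range(n_seeds):
        seed = base_seed + i
        truth = synth.make_ground_truth(n_maps=n_maps, seed=seed, snr=snr)
        epochs = synth.generate_epochs(truth)
        res = twolevel.two_level_pipeline(epochs, k_range, seed, n_restarts=n_restarts)
        k = res["final_templates"].n_maps
        meta_ks.append(k)
        if k == n_maps:
            _, cc = twolevel.match_maps(truth.maps, res["final_templates"].maps)
            min_corrs.append(float(cc.min()))
    return dict(
        meta_ks=meta_ks,
        n_correct=int(sum(k == n_maps for k in meta_ks)),
        n_seeds=n_seeds,
        min_matched_corr=(min(min_corrs) if min_corrs else float("nan")),
    )


def load_effect_power(
    n_replicates: int = 200,
    base_seed: int = 0,
    *,
    n_subjects: int = 10,
    n_conditions: int = 4,
    n_trials: int = 4,
    n_maps: int = 4,
    snr: float = 2.0,
    alpha: float = 0.05,
) -> dict:
    """Power of the pipeline's Friedman test for a planted load effect.

    One map's prevalence declines monotonically across conditions (2x down
    to 0.5x its uniform share); per replicate the two-level pipeline is run
    at the planted K (meta-criterion K-search off for speed), the final map
    matched back to the planted one, and Friedman + Dunn applied to its
    per-condition time frames.  Reports rejection rate and how often Dunn's
    smallest adjusted p lands on the extreme condition pair.
    """
    rejections = 0
    extreme_pair_hits = 0
    for r in range(n_replicates):
        seed = base_seed + 1000 + r
        truth = synth.make_ground_truth(
            n_maps=n_maps, n_subjects=n_subjects, n_conditions=n_conditions,
            seed=seed, snr=snr, load_sensitive_map=0,
        )
        epochs = synth.generate_epochs(
            truth, n_subjects, n_conditions, n_trials,
            truth.maps.shape[1], synth.N_SAMPLES, synth.SRATE,
        )
        res = twolevel.two_level_pipeline(
            epochs, [n_maps], seed, n_restarts=5, use_meta_criterion=False,
        )
        perm, _ = twolevel.match_maps(truth.maps, res["final_templates"].maps)
        target = int(perm[0])
        sub = res["stats"][res["stats"]["map"] == target]
        blocks = stats.blocks_from_tidy(sub, "time_frames")
        fr = stats.friedman(blocks)
        if fr.p < alpha:
            rejections += 1
        dn = stats.dunn_posthoc(blocks, alpha=alpha)
        best = dn.table.loc[dn.table["p_adj"].idxmin()]
        if {int(best["i"]), int(best["j"])} == {0, n_conditions - 1}:
            extreme_pair_hits += 1
    return dict(
        power=rejections / n_replicates,
        extreme_pair_rate=extreme_pair_hits / n_replicates,
        n_replicates=n_replicates,
    )


def friedman_null_type1(
    n_replicates: int = 5000,
    seed: int = 0,
    *,
    n_subjects: int = 10,
    n_conditions: int = 4,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the chi-square Friedman test under a Gaussian null."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_replicates, n_subjects, n_conditions))
    chi2 = stats.friedman_chi2_batch(x)
    crit = sps.chi2.isf(alpha, n_conditions - 1)
    return dict(type1=float(np.mean(chi2 > crit)), n_replicates=n_replicates)


def sloreta_localization(
    n_probes: int = 25,
    seed: int = 0,
    *,
    grid_spacing_mm: float = 12.0,
    alpha: float | str = 0.0,
) -> dict:
    """Localization error of sLORETA for noiseless single grid dipoles.

    For each probe voxel a random-moment dipole's scalp map is computed from
    the lead field and inverted; the distance between the power argmax and
    the true voxel is recorded (sLORETA's defining property is zero).
    """
    lf = sources.build_leadfield(channel_positions(), grid_spacing_mm=grid_spacing_mm)
    rng = np.random.default_rng(seed)
    errors_mm = []
    for _ in range(n_probes):
        v = int(rng.integers(lf.n_voxels))
        moment = rng.standard_normal(3)
        phi = lf.gain[:, 3 * v : 3 * v + 3] @ moment
        est = sources.sloreta_inverse(lf, phi, alpha=alpha)
        err = np.linalg.norm(lf.voxel_coords[est.peak_voxel] - lf.voxel_coords[v])
        errors_mm.append(float(err * 1000.0))
    return dict(max_error_mm=max(errors_mm), n_probes=n_probes,
                n_voxels=lf.n_voxels)


def snpm_familywise_error(
    n_replicates: int = 200,
    seed: int = 0,
    *,
    n_subjects: int = 10,
    n_voxels: int = 500,
    alpha: float = 0.05,
) -> dict:
    """Familywise error of the max-|t| sign-flip procedure under the global
    null (spatially correlated Gaussian difference images)."""
    rng = np.random.default_rng(seed)
    mix = np.linalg.qr(rng.standard_normal((n_voxels, n_voxels)))[0] @ np.diag(
        1.0 / np.sqrt(1.0 + np.arange(n_voxels))
    )
    fw_errors = 0
    for _ in range(n_replicates):
        a = rng.standard_normal((n_subjects, n_voxels)) @ mix.T
        b = rng.standard_normal((n_subjects, n_voxels)) @ mix.T
        res = sources.snpm_paired_contrast(a, b, n_permutations=5000,
                                           alpha=alpha, seed=seed)
        if res.suprathreshold.size > 0:
            fw_errors += 1
    return dict(fwe=fw_errors / n_replicates, n_replicates=n_replicates)


def signal_processing_checks(srate: float = 250.0) -> dict:
    """Filter/decimation/RMS oracles.

    The band-pass gains are measured empirically on long sinusoids and
    cross-checked against the analytic transfer function of the designed
    Butterworth cascade (|H|^2, since the filter is applied forward and
    backward).
    """
    spec = FilterSpec(0.5, 30.0, 4)
    t = np.arange(int(20 * srate)) / srate
    out10 = bandpass(np.sin(2 * np.pi * 10 * t)[None, :], spec, srate)[0]
    out60 = bandpass(np.sin(2 * np.pi * 60 * t)[None, :], spec, srate)[0]
    mid = slice(int(5 * srate), int(15 * srate))   # ignore filter edges
    gain10 = float(np.max(np.abs(out10[mid])))
    gain60 = float(np.max(np.abs(out60[mid])))
    sos = signal.butter(4, [0.5, 30.0], btype="bandpass", fs=srate, output="sos")
    w, h = signal.sosfreqz(sos, worN=[10.0, 60.0], fs=srate)
    analytic10, analytic60 = np.abs(h) ** 2       # forward-backward magnitude
    n_dec = downsample(np.zeros((1, int(srate * 2))), 500.0, 250.0).shape[-1]
    amp = 2.5
    sine = amp * np.sin(2 * np.pi * 40 * np.arange(int(4 * 4000)) / 4000.0)
    rms_ratio = float(np.sqrt(np.mean(sine**2)) / (amp / np.sqrt(2)))
    return dict(
        gain_10hz=gain10, gain_60hz=gain60,
        analytic_gain_10hz=float(analytic10), analytic_gain_60hz=float(analytic60),
        decimated_samples=int(n_dec), decimation_input_samples=int(srate * 2),
        rms_sine_over_a_sqrt2=rms_ratio,
    )


def pipeline_determinism(tmpdir: str | Path, seed: int = 0) -> dict:
    """Run a reduced full pipeline twice with one seed and hash-compare all
    output files byte for byte."""
    from .io import PipelineConfig
    from .pipeline import run_pipeline

    cfg = PipelineConfig(seed=seed, n_subjects=5, n_trials=4, n_maps=6,
                         k_min=4, k_max=8, n_restarts=8)
    out = []
    for name in ("run_a", "run_b"):
        d = Path(tmpdir) / name
        run_pipeline(cfg, d)
        out.append({p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(d.iterdir())})
    return dict(identical=out[0] == out[1], n_files=len(out[0]))


def gev_oracle(data_maps: np.ndarray, templates: np.ndarray,
               labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Straight-loop reference implementation of GEV, kept deliberately
    independent of :func:`prestate.core.gev` for cross-checking."""
    X = np.asarray(data_maps, dtype=float)
    T = np.asarray(templates, dtype=float)
    n = X.shape[0]
    gfps = np.empty(n)
    corrs = np.empty(n)
    for t in range(n):
        v = X[t] - X[t].mean()
        gfps[t] = np.sqrt(np.mean(v**2))
        k = labels[t]
        if k < 0:
            corrs[t] = 0.0
            continue
        u = T[k] - T[k].mean()
        corrs[t] = abs(float(v @ u) / (np.linalg.norm(v) * np.linalg.norm(u)))
    denom = float(np.sum(gfps**2))
    per_map = np.zeros(T.shape[0])
    for k in range(T.shape[0]):
        for t in range(n):
            if labels[t] == k:
                per_map[k] += (gfps[t] * corrs[t]) ** 2
    per_map /= denom
    return per_map, float(per_map.sum())
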