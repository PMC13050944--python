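"""End-to-end pipeline: simulate -> preprocess -> two-level microstates ->
load-effect statistics -> correlations -> source contrast -> report.

All outputs are deterministic functions of the configuration (seed
included): rerunning with the same config reproduces every file byte for
byte.  Every CSV/JSON output carries the config hash in a provenance block
or sidecar column.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import core, preprocess, sources, stats, synth, twolevel
from .io import PipelineConfig, save_templates
from .montage import channel_positions

logger = logging.getLogger(__name__)


def mean_map_topography(
    final: core.TemplateSet,
    epochs: synth.EpochSet,
    subject: int,
    condition: int,
    map_index: int,
    *,
    peaks_only: bool = True,
) -> np.ndarray:
    """Backfit-weighted mean topography of one final map for one subject x
    condition: peak topographies assigned to the map, polarity-aligned to
    the template and weighted by gfp * corr.  Falls back to the template
    itself when the map never occurs in that cell."""
    acc = np.zeros(final.n_channels)
    total_w = 0.0
    tmpl = final.maps[map_index]
    for tr in range(epochs.n_trials):
        trial = epochs.data[subject, condition, tr]
        seg = twolevel.backfit(final, trial, peaks_only=peaks_only)
        idx = np.flatnonzero(seg.labels == map_index)
        for t in idx:
            v = trial[:, t] - trial[:, t].mean()
            sign = 1.0 if v @ tmpl >= 0 else -1.0
            w = seg.gfp[t] * seg.corr[t]
            acc += sign * w * v
            total_w += w
    if total_w == 0.0:
        logger.warning(
            "map %d absent for subject %d condition %d; using the template",
            map_index, subject, condition,
        )
        return tmpl.copy()
    return acc / total_w


def load_effect_tests(
    ms_stats: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Friedman + Dunn across the loaded conditions for every final map,
    on both time frames and GEV.  Returns (friedman table, dunn table)."""
    loaded = [c for c in sorted(ms_stats["condition"].unique())
              if c != cfg.baseline_condition]
    sub = ms_stats[ms_stats["condition"].isin(loaded)]
    fr_rows, dunn_rows = [], []
    for measure in ("time_frames", "gev"):
        for m in sorted(sub["map"].unique()):
            blocks = stats.blocks_from_tidy(sub[sub["map"] == m], measure)
            fr = stats.friedman(blocks)
            fr_rows.append(dict(map=m, measure=measure, chi2=fr.chi2, df=fr.df,
                                p=fr.p, significant=fr.p < cfg.alpha))
            dn = stats.dunn_posthoc(blocks, alpha=cfg.alpha,
                                    adjustment=cfg.dunn_adjustment)
            for _, row in dn.table.iterrows():
                dunn_rows.append(dict(map=m, measure=measure,
                                      cond_i=loaded[int(row["i"])],
                                      cond_j=loaded[int(row["j"])],
                                      z=row["z"], p_raw=row["p_raw"],
                                      p_adj=row["p_adj"],
                                      significant=bool(row["significant"])))
    return pd.DataFrame(fr_rows), pd.DataFrame(dunn_rows)


def correlation_tests(
    ms_stats: pd.DataFrame, behavior_table: pd.DataFrame, maps: list[int],
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """Pearson correlations between per-map microstate measures and
    behavioral metrics over subject x loaded-condition points."""
    loaded = [c for c in sorted(ms_stats["condition"].unique())
              if c != cfg.baseline_condition]
    beh = behavior_table[behavior_table["condition"].isin(loaded)]
    rows = []
    for m in maps:
        sub = ms_stats[(ms_stats["map"] == m) & (ms_stats["condition"].isin(loaded))]
        merged = sub.merge(beh, on=["subject", "condition"])
        for measure in ("time_frames", "gev"):
            for metric in ("reaction_time_ms", "movement_duration_ms", "rms_emg"):
                try:
                    res = stats.pearson(merged[measure].to_numpy(dtype=float),
                                        merged[metric].to_numpy(dtype=float))
                except ValueError:
                    logger.warning("correlation undefined for map %d %s vs %s",
                                   m, measure, metric)
                    continue
                rows.append(dict(map=m, measure=measure, metric=metric,
                                 r=res.r, p=res.p, n=res.n,
                                 significant=res.p < cfg.alpha))
    return pd.DataFrame(rows)


def source_contrast(
    final: core.TemplateSet,
    epochs: synth.EpochSet,
    map_index: int,
    cfg: PipelineConfig,
) -> tuple[pd.DataFrame, sources.SnPMResult]:
    """sLORETA estimates of one map's mean topography per subject for the
    lightest vs. heaviest loaded condition, contrasted with SnPM."""
    elec = channel_positions(epochs.channel_labels)
    lf = sources.build_leadfield(elec, grid_spacing_mm=cfg.grid_spacing_mm)
    loaded = [c for c in range(epochs.n_conditions) if c != cfg.baseline_condition]
    lo, hi = loaded[0], loaded[-1]
    est_lo, est_hi = [], []
    for s in range(epochs.n_subjects):
        for cond, acc in ((lo, est_lo), (hi, est_hi)):
            topo = mean_map_topography(final, epochs, s, cond, map_index,
                                       peaks_only=cfg.peaks_only)
            acc.append(sources.sloreta_inverse(lf, topo, alpha=cfg.sloreta_alpha).power)
    snpm = sources.snpm_paired_contrast(
        np.array(est_hi), np.array(est_lo),
        n_permutations=cfg.n_permutations, alpha=cfg.alpha, seed=cfg.seed,
    )
    vox = pd.DataFrame(lf.voxel_coords * 1000.0, columns=["x_mm", "y_mm", "z_mm"])
    vox["t"] = snpm.t
    vox["p_corrected"] = snpm.p_corrected
    vox["suprathreshold"] = np.isin(np.arange(lf.n_voxels), snpm.suprathreshold)
    return vox, snpm


def _write_csv(df: pd.DataFrame, path: Path, digest: str) -> None:
    df = df.copy()
    df["config_hash"] = digest
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on synthetic data and write the report directory."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    digest = cfg.digest()

    logger.info("stage: simulate (seed %d)", cfg.seed)
    truth = synth.make_ground_truth(
        n_maps=cfg.n_maps, n_channels=cfg.n_channels,
        n_subjects=cfg.n_subjects, n_conditions=cfg.n_conditions,
        seed=cfg.seed, snr=cfg.snr, segment_dwell=cfg.segment_dwell,
        load_sensitive_map=cfg.load_sensitive_map,
    )
    epochs = synth.generate_epochs(
        truth, cfg.n_subjects, cfg.n_conditions, cfg.n_trials,
        cfg.n_channels, cfg.n_samples, cfg.srate,
    )
    behavior_table = synth.generate_behavior(truth, cfg.n_subjects, cfg.n_conditions)

    logger.info("stage: preprocess")
    data = epochs.data
    if cfg.apply_bandpass:
        spec = preprocess.FilterSpec(cfg.band_low_hz, cfg.band_high_hz, cfg.filter_order)
        data = preprocess.bandpass(data, spec, cfg.srate)
    data = data - data.mean(axis=3, keepdims=True)     # common average reference
    data = data - data.mean(axis=4, keepdims=True)     # epoch baseline correction
    epochs = synth.EpochSet(data=data, channel_labels=epochs.channel_labels,
                            srate=epochs.srate, planted_labels=epochs.planted_labels)

    logger.info("stage: microstates (two-level clustering)")
    res = twolevel.two_level_pipeline(
        epochs, range(cfg.k_min, cfg.k_max + 1), cfg.seed,
        n_restarts=cfg.n_restarts, use_meta_criterion=cfg.use_meta_criterion,
        peaks_only=cfg.peaks_only,
    )
    ms_stats = res["stats"]
    final = res["final_templates"]

    logger.info("stage: statistics")
    friedman_tab, dunn_tab = load_effect_tests(ms_stats, cfg)
    sig = friedman_tab[friedman_tab["significant"]]
    sig_maps = sorted(sig["map"].unique().tolist())
    test_maps = sig_maps if sig_maps else sorted(ms_stats["map"].unique())[:1]
    corr_tab = correlation_tests(ms_stats, behavior_table, test_maps, cfg)

    summary: dict = dict(
        config=cfg.to_dict(), config_hash=digest,
        n_final_maps=int(final.n_maps),
        final_gev_total=float(final.gev_total),
        mean_condition_gev=float(
            ms_stats.groupby(["subject", "condition"])["gev"].sum().mean()
        ),
        within_subject_meta_k=[
            (st.meta.meta_k if st.meta is not None else None)
            for st in res["subject_templates"]
        ],
        across_subject_meta_k=(
            res["across_meta"].meta_k if res["across_meta"] is not None else None
        ),
        significant_maps=sig_maps,
    )

    if cfg.run_sources:
        logger.info("stage: sources (sLORETA + SnPM) for map %d", test_maps[0])
        vox_tab, snpm = source_contrast(final, epochs, test_maps[0], cfg)
        _write_csv(vox_tab, out / "source_contrast.csv", digest)
        summary["snpm"] = dict(
            map=int(test_maps[0]), t_crit=float(snpm.t_crit),
            n_permutations=int(snpm.n_permutations),
            enumerated=bool(snpm.enumerated),
            n_suprathreshold=int(snpm.suprathreshold.size),
        )

    logger.info("stage: report")
    _write_csv(ms_stats, out / "microstate_stats.csv", digest)
    _write_csv(behavior_table, out / "behavior.csv", digest)
    _write_csv(friedman_tab, out / "friedman.csv", digest)
    _write_csv(dunn_tab, out / "dunn.csv", digest)
    _write_csv(corr_tab, out / "correlations.csv", digest)
    save_templates(final.maps, out / "final_templates.ep",
                   dict(provenance=final.provenance, gev_total=final.gev_total,
                        config_hash=digest))
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))

    if cfg.figures:
        _figures(final, ms_stats, out)
    return dict(summary=summary, stats=ms_stats, final=final,
                friedman=friedman_tab, dunn=dunn_tab, correlations=corr_tab,
                truth=truth)


def _figures(final: core.TemplateSet, ms_stats: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, final.n_maps, figsize=(2 * final.n_maps, 2))
    for k, ax in enumerate(np.atleast_1d(axes)):
        ax.bar(range(final.n_channels), final.maps[k])
        ax.set_title(f"map {k}")
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(out / "templates.png", dpi=100)
    plt.close(fig)

    pv = ms_stats.pivot_table(index="condition", columns="map",
                              values="time_frames", aggfunc="mean")
    fig, ax = plt.subplots(figsize=(6, 4))
    pv.plot(ax=ax, marker="o")
    ax.set_ylabel("mean time frames")
    fig.tight_layout()
    fig.savefig(out / "time_frames_by_condition.png", dpi=100)
    plt.close(fig)
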