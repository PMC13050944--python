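"""Two-level microstate clustering and per-condition statistics.

The four-step procedure: (1) within each subject, pool GFP-peak
topographies over all conditions and cluster them, selecting K by the
meta-criterion; (2) backfit the subject templates to the subject's data;
(3) pool all subject-level templates and run a second, across-subject
clustering with its own meta-criterion; (4) backfit the final maps to every
subject x condition and accumulate time frames (number of assigned GFP-peak
samples) and GEV per final map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import core
from .synth import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class SubjectTemplates:
    subject: int
    templates: core.TemplateSet
    meta: core.MetaCriterionResult | None


def collect_peak_maps(
    epochs: EpochSet, subject: int, conditions: list[int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """GFP-peak topographies (n_peaks, channels) and their GFP values for one
    subject, pooled over the requested conditions (all by default)."""
    conds = range(epochs.n_conditions) if conditions is None else conditions
    maps, gfps = [], []
    for c in conds:
        for tr in range(epochs.n_trials):
            trial = epochs.data[subject, c, tr]          # (channels, samples)
            g = core.gfp_series(trial)
            peaks = core.find_gfp_peaks(g)
            if peaks.size:
                maps.append(trial[:, peaks].T)
                gfps.append(g[peaks])
    if not maps:
        raise ValueError(f"subject {subject} has no GFP peaks")
    return np.vstack(maps), np.concatenate(gfps)


def within_subject_templates(
    epochs: EpochSet,
    k_range: range | list[int],
    seed: int,
    *,
    n_restarts: int = 20,
    use_meta_criterion: bool = True,
) -> list[SubjectTemplates]:
    """Step 1: per-subject clustering of pooled GFP-peak maps.

    With ``use_meta_criterion`` the full K range is fitted and the
    meta-criterion picks K; otherwise the single K in ``k_range`` is used
    directly (a fast path for simulations at a known K).
    """
    ks = list(k_range)
    out: list[SubjectTemplates] = []
    for s in range(epochs.n_subjects):
        maps, gfps = collect_peak_maps(epochs, s)
        if maps.shape[0] < max(ks):
            raise ValueError(
                f"subject {s} has only {maps.shape[0]} GFP peaks, fewer than max K {max(ks)}"
            )
        rng = np.random.default_rng([seed, s])
        if use_meta_criterion and len(ks) >= 3:
            fits = core.fit_k_range(
                maps, ks, n_restarts=n_restarts, seed=rng, weights=gfps,
                provenance=f"within-subject s{s}",
            )
            meta = core.validity_criteria(maps, fits)
            fit = fits[meta.meta_k]
        else:
            fit = core.modified_kmeans(
                maps, ks[0], n_restarts=n_restarts, seed=rng, weights=gfps,
                provenance=f"within-subject s{s}",
            )
            meta = None
        out.append(SubjectTemplates(subject=s, templates=fit.templates, meta=meta))
    return out


def backfit(
    templates: core.TemplateSet,
    data: np.ndarray,
    *,
    peaks_only: bool = True,
    min_corr: float | None = None,
) -> core.Segmentation:
    """Step 2/4: label topographies by their best-|correlation| template.

    ``data`` is (channels, samples) for one trial (or concatenated trials).
    With ``peaks_only`` (default) only GFP-peak samples are labeled; others
    get label -1.  An optional minimum-correlation gate unassigns samples
    below ``min_corr`` (off by default).
    """
    if data.shape[0] != templates.n_channels:
        raise ValueError("channel count mismatch between templates and data")
    g = core.gfp_series(data)
    n = data.shape[1]
    if peaks_only:
        idx = core.find_gfp_peaks(g)
    else:
        idx = np.arange(n)
    labels = np.full(n, -1, dtype=int)
    corr = np.zeros(n)
    if idx.size:
        X = core.normalize_maps(data[:, idx].T)
        lab, cc = core._assign(X, templates.maps)
        labels[idx] = lab
        corr[idx] = cc
        if min_corr is not None:
            low = corr[idx] < min_corr
            labels[idx[low]] = -1
    return core.Segmentation(labels=labels, corr=corr, gfp=g)


def across_subject_templates(
    subject_templates: list[SubjectTemplates],
    k_range: range | list[int],
    seed: int,
    *,
    n_restarts: int = 50,
    use_meta_criterion: bool = True,
) -> tuple[core.TemplateSet, core.MetaCriterionResult | None]:
    """Step 3: cluster the pooled subject-level template maps.

    A single subject's templates pass through unchanged (degenerate pooling).
    """
    if not subject_templates:
        raise ValueError("no subject templates")
    if len(subject_templates) == 1:
        t = subject_templates[0].templates
        return core.TemplateSet(t.maps.copy(), t.gev_total, "across-subject"), None
    pooled = np.vstack([st.templates.maps for st in subject_templates])
    ks = [k for k in k_range if k <= pooled.shape[0]]
    rng = np.random.default_rng([seed, 7919])
    if use_meta_criterion and len(ks) >= 3:
        fits = core.fit_k_range(pooled, ks, n_restarts=n_restarts, seed=rng,
                                provenance="across-subject")
        meta = core.validity_criteria(pooled, fits)
        fit = fits[meta.meta_k]
    else:
        fit = core.modified_kmeans(pooled, ks[0], n_restarts=n_restarts, seed=rng,
                                   provenance="across-subject")
        meta = None
    ts = fit.templates
    ts.provenance = "across-subject"
    return ts, meta


def match_maps(reference: np.ndarray, maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Match ``maps`` to ``reference`` maps by maximal |spatial correlation|
    (Hungarian assignment).  Returns (permutation, matched |corr| values):
    ``maps[permutation[j]]`` corresponds to ``reference[j]``."""
    R = core.normalize_maps(reference)
    M = core.normalize_maps(maps)
    C = np.abs(R @ M.T)
    ri, mj = linear_sum_assignment(-C)
    perm = np.empty(len(ri), dtype=int)
    perm[ri] = mj
    return perm, C[ri, perm[ri]]


def condition_stats(
    final: core.TemplateSet,
    epochs: EpochSet,
    *,
    peaks_only: bool = True,
    min_corr: float | None = None,
) -> pd.DataFrame:
    """Step 4: per subject x condition x map time frames and GEV.

    Time frames are counts of labeled (GFP-peak) samples; GEV is normalized
    within subject x condition.  Returns a tidy frame with columns
    subject, condition, map, time_frames, gev, occurrence_fraction.
    """
    K = final.n_maps
    rows = []
    for s in range(epochs.n_subjects):
        for c in range(epochs.n_conditions):
            tf = np.zeros(K, dtype=int)
            num = np.zeros(K)
            denom = 0.0
            labeled_total = 0
            for tr in range(epochs.n_trials):
                trial = epochs.data[s, c, tr]
                seg = backfit(final, trial, peaks_only=peaks_only, min_corr=min_corr)
                denom += float(np.sum(seg.gfp**2)) if not peaks_only else float(
                    np.sum(seg.gfp[seg.labels >= 0] ** 2)
                )
                sel = seg.labels >= 0
                labeled_total += int(sel.sum())
                for k in range(K):
                    m = seg.labels == k
                    tf[k] += int(m.sum())
                    num[k] += float(np.sum((seg.gfp[m] * seg.corr[m]) ** 2))
            gev_cells = num / denom if denom > 0 else np.zeros(K)
            total = max(labeled_total, 1)
            for k in range(K):
                rows.append(
                    dict(subject=s, condition=c, map=k,
                         time_frames=int(tf[k]), gev=float(gev_cells[k]),
                         occurrence_fraction=tf[k] / total)
                )
    return pd.DataFrame(rows)


def two_level_pipeline(
    epochs: EpochSet,
    k_range: range | list[int],
    seed: int,
    *,
    n_restarts: int = 20,
    use_meta_criterion: bool = True,
    peaks_only: bool = True,
) -> dict:
    """Run steps 1-4 end to end and return all intermediate products."""
    subj = within_subject_templates(
        epochs, k_range, seed, n_restarts=n_restarts,
        use_meta_criterion=use_meta_criterion,
    )
    final, meta = across_subject_templates(
        subj, k_range, seed, n_restarts=max(n_restarts, 20),
        use_meta_criterion=use_meta_criterion,
    )
    stats = condition_stats(final, epochs, peaks_only=peaks_only)
    return dict(subject_templates=subj, final_templates=final,
                across_meta=meta, stats=stats)
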