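"""Core topographic machinery for EEG microstate analysis.

Implements global field power (GFP), GFP-peak detection, polarity-invariant
spatial correlation, the polarity-invariant ("modified") k-means clustering
of scalp topographies, global explained variance (GEV), a battery of
cluster-validity criteria on the polarity-invariant distance
``d = sqrt(1 - corr**2)``, and the meta-criterion (median of per-criterion
optimal cluster counts).

Conventions
-----------
Topographies are row vectors over channels, average-referenced.  A map and
its negation denote the same microstate: every similarity here is the
absolute spatial correlation, and cluster centroids are dominant
eigenvectors of the within-cluster scatter, so the whole module is invariant
to flipping the polarity of any input map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

#: Names of the default seven cluster-validity criteria.
DEFAULT_CRITERIA: tuple[str, ...] = (
    "silhouette",
    "davies_bouldin",
    "calinski_harabasz",
    "dunn",
    "point_biserial",
    "krzanowski_lai",
    "cross_validation",
)


# ---------------------------------------------------------------------------
# GFP and spatial correlation
# ---------------------------------------------------------------------------

def gfp(values: np.ndarray) -> float:
    """Global field power of one topography: spatial SD across channels.

    ``sqrt(mean((v - mean(v))**2))`` -- the root-mean-square of the
    average-referenced potentials.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("gfp expects one topography with >= 2 channels")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite potentials")
    return float(np.sqrt(np.mean((v - v.mean()) ** 2)))


def gfp_series(data: np.ndarray) -> np.ndarray:
    """GFP at every sample of a (channels, samples) array."""
    d = np.asarray(data, dtype=float)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("expected a (channels, samples) array")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite potentials")
    return np.sqrt(np.mean((d - d.mean(axis=0, keepdims=True)) ** 2, axis=0))


def find_gfp_peaks(series: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a GFP series.

    A peak satisfies ``g[t-1] < g[t] > g[t+1]``; a flat plateau flanked by
    lower values counts once, at its first sample; endpoints are never peaks.
    """
    g = np.asarray(series, dtype=float)
    if g.ndim != 1 or g.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    peaks = []
    t = 1
    n = g.size
    while t < n - 1:
        if g[t] > g[t - 1]:
            # scan a possible plateau starting at t
            u = t
            while u + 1 < n and g[u + 1] == g[t]:
                u += 1
            if u + 1 < n and g[u + 1] < g[t]:
                peaks.append(t)
            t = u + 1
        else:
            t += 1
    return np.asarray(peaks, dtype=int)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Absolute spatial (Pearson) correlation between two topographies.

    Both maps are average-referenced first, so this equals the absolute
    cosine similarity of the centered vectors; negating either map leaves
    the value unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D with equal channel counts")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-variance map has no defined spatial correlation")
    return float(min(abs(float(ac @ bc) / (na * nb)), 1.0))


def normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Average-reference and L2-normalize each row of (n_maps, n_channels)."""
    m = np.asarray(maps, dtype=float)
    m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-variance map cannot be normalized")
    return m / norms


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic polarity convention: largest-|component| is positive.

    Picking the sign from the largest-magnitude entry (first on exact ties)
    commutes with channel permutations, which keeps the clustering
    permutation-equivariant.
    """
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class TemplateSet:
    """An ordered set of K template topographies with fit diagnostics."""

    maps: np.ndarray              # (K, n_channels), centered, unit norm
    gev_total: float              # fraction of GFP-weighted variance explained
    provenance: str = ""          # e.g. "within-subject", "across-subject"

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not (0.0 <= self.gev_total <= 1.0 + 1e-12):
            raise ValueError(f"gev_total outside [0, 1]: {self.gev_total}")


@dataclass
class Segmentation:
    """Per-sample microstate labels with fit quality.

    ``labels[t]`` is the winning template index at sample ``t`` (or -1 for
    unassigned), ``corr[t]`` the absolute spatial correlation with that
    template, ``gfp[t]`` the sample's global field power.
    """

    labels: np.ndarray
    corr: np.ndarray
    gfp: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.corr) == len(self.gfp)):
            raise ValueError("labels, corr and gfp must have equal length")


@dataclass
class KMeansFit:
    """Result of one polarity-invariant k-means fit."""

    templates: TemplateSet
    segmentation: Segmentation
    gev_per_map: np.ndarray
    gev_trace: list = field(default_factory=list)  # GEV after each iteration
    n_iter: int = 0


@dataclass
class MetaCriterionResult:
    """Optimal K per validity criterion, and their median (the meta-criterion)."""

    optima: dict[str, int]
    meta_k: int
    scores: dict[str, dict[int, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# GEV
# ---------------------------------------------------------------------------

def gev(
    data_maps: np.ndarray,
    templates: np.ndarray,
    labels: np.ndarray,
    sample_gfp: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Global explained variance of a labeling.

    ``GEV_k = sum_{t: label_t = k} (gfp_t * corr_t)^2 / sum_t gfp_t^2`` where
    ``corr_t`` is the absolute spatial correlation between sample ``t`` and
    its assigned template; the total is the sum over templates.  Unassigned
    samples (label < 0) contribute only to the denominator.

    Parameters
    ----------
    data_maps : (n_samples, n_channels) topographies (any scaling).
    templates : (K, n_channels) template maps.
    labels : per-sample template index, -1 for unassigned.
    sample_gfp : optional precomputed GFP per sample; derived from
        ``data_maps`` when omitted.
    """
    X = np.asarray(data_maps, dtype=float)
    T = normalize_maps(templates)
    lab = np.asarray(labels)
    Xc = X - X.mean(axis=1, keepdims=True)
    g = gfp_series(X.T) if sample_gfp is None else np.asarray(sample_gfp, dtype=float)
    denom = float(np.sum(g**2))
    if denom == 0.0:
        raise ValueError("zero total GFP: GEV undefined")
    norms = np.linalg.norm(Xc, axis=1)
    K = T.shape[0]
    per_map = np.zeros(K)
    for k in range(K):
        sel = lab == k
        if not np.any(sel):
            continue
        c = np.abs(Xc[sel] @ T[k]) / norms[sel]
        per_map[k] = float(np.sum((g[sel] * c) ** 2)) / denom
    return per_map, float(per_map.sum())


# ---------------------------------------------------------------------------
# Polarity-invariant (modified) k-means
# ---------------------------------------------------------------------------

def _assign(X: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and |corr| for normalized maps X against templates T.

    ``np.argmax`` keeps the first (lowest-index) template on exact ties.
    """
    C = np.abs(X @ T.T)
    labels = np.argmax(C, axis=1)
    corr = C[np.arange(C.shape[0]), labels]
    return labels, corr


def _eig_centroid(X: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Polarity-invariant centroid: dominant eigenvector of sum_i w_i x_i x_i'."""
    if w is None:
        S = X.T @ X
    else:
        S = (X * w[:, None]).T @ X
    _, vecs = np.linalg.eigh(S)
    v = vecs[:, -1]
    v = v - v.mean()          # stay in the average-reference subspace
    n = np.linalg.norm(v)
    if n == 0.0:              # pathological; fall back to first map
        v = X[0].copy()
        n = np.linalg.norm(v)
    return _fix_sign(v / n)


def modified_kmeans(
    maps: np.ndarray,
    k: int,
    *,
    n_restarts: int = 100,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | np.random.Generator,
    weights: np.ndarray | None = None,
    provenance: str = "",
) -> KMeansFit:
    """Cluster topographies into ``k`` polarity-invariant templates.

    Alternates (i) assigning each map to the template with the highest
    absolute spatial correlation and (ii) re-estimating each template as the
    dominant eigenvector of its members' outer-product sum, until labels
    stabilize or the relative GEV change falls below ``tol``.  The best of
    ``n_restarts`` random initializations by GEV is returned.

    ``weights`` are per-map GFP values used in the GEV objective (equal when
    omitted, appropriate when the maps were pre-normalized).
    """
    X = normalize_maps(maps)
    M, C = X.shape
    if k < 1 or k > M:
        raise ValueError(f"need 1 <= k <= n_maps, got k={k}, n_maps={M}")
    g = np.ones(M) if weights is None else np.asarray(weights, dtype=float)
    if g.shape != (M,) or np.any(g < 0):
        raise ValueError("weights must be non-negative, one per map")
    g2 = g**2
    denom = float(g2.sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best: KMeansFit | None = None
    for _ in range(n_restarts):
        idx = rng.choice(M, size=k, replace=False)
        T = np.array([_fix_sign(X[i]) for i in idx])
        labels = np.full(M, -1)
        prev_gev = -np.inf
        trace: list[float] = []
        for it in range(max_iter):
            new_labels, corr = _assign(X, T)
            # re-seed empty clusters from the worst-fit map
            for kk in range(k):
                if not np.any(new_labels == kk):
                    worst = int(np.argmin(corr))
                    T[kk] = _fix_sign(X[worst])
                    new_labels, corr = _assign(X, T)
            cur_gev = float(np.sum(g2 * corr**2)) / denom
            trace.append(cur_gev)
            converged = np.array_equal(new_labels, labels) or (
                prev_gev > -np.inf and abs(cur_gev - prev_gev) <= tol * max(prev_gev, 1e-30)
            )
            labels = new_labels
            prev_gev = cur_gev
            if converged:
                break
            for kk in range(k):
                sel = labels == kk
                T[kk] = _eig_centroid(X[sel], g2[sel])
        labels, corr = _assign(X, T)
        final_gev = float(np.sum(g2 * corr**2)) / denom
        if best is None or final_gev > best.templates.gev_total:
            per_map = np.array(
                [np.sum(g2[labels == kk] * corr[labels == kk] ** 2) for kk in range(k)]
            ) / denom
            best = KMeansFit(
                templates=TemplateSet(T.copy(), final_gev, provenance),
                segmentation=Segmentation(labels.copy(), corr.copy(), g.copy()),
                gev_per_map=per_map,
                gev_trace=trace,
                n_iter=len(trace),
            )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Cluster-validity criteria and the meta-criterion
# ---------------------------------------------------------------------------

def _pair_dist(X: np.ndarray) -> np.ndarray:
    """Polarity-invariant distance matrix d = sqrt(1 - |corr|^2)."""
    c = np.clip(np.abs(X @ X.T), 0.0, 1.0)
    d = np.sqrt(np.clip(1.0 - c**2, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


def _dist_to(X: np.ndarray, T: np.ndarray) -> np.ndarray:
    c = np.clip(np.abs(X @ T.T), 0.0, 1.0)
    return np.sqrt(np.clip(1.0 - c**2, 0.0, None))


def _criterion_scores(
    X: np.ndarray, fits: dict[int, KMeansFit], names: tuple[str, ...]
) -> dict[str, dict[int, float]]:
    """Score every requested criterion at every K (higher-is-better sign applied later)."""
    D = _pair_dist(X)
    M, C = X.shape
    p_eff = C - 1  # average-referenced maps live in a (C-1)-dim subspace
    ks = sorted(fits)
    within: dict[int, float] = {}
    for k in ks:
        f = fits[k]
        within[k] = float(np.sum(1.0 - f.segmentation.corr**2))

    scores: dict[str, dict[int, float]] = {name: {} for name in names}
    for k in ks:
        f = fits[k]
        lab = f.segmentation.labels
        T = f.templates.maps
        counts = np.bincount(lab, minlength=k)
        if np.any(counts == 0) or k < 2:
            logger.warning("degenerate fit at K=%d excluded from validity criteria", k)
            continue
        DT = _dist_to(X, T)
        d_own = DT[np.arange(M), lab]
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(M, 1)
        d_flat = D[iu]
        same_flat = same[iu]

        if "silhouette" in names:
            scores["silhouette"][k] = float(silhouette_score(D, lab, metric="precomputed"))
        if "davies_bouldin" in names:
            S = np.array([d_own[lab == kk].mean() for kk in range(k)])
            MT = _dist_to(T, T)
            np.fill_diagonal(MT, np.inf)
            ratio = (S[:, None] + S[None, :]) / MT
            np.fill_diagonal(ratio, -np.inf)
            scores["davies_bouldin"][k] = float(np.mean(ratio.max(axis=1)))
        if "calinski_harabasz" in names:
            t_glob = _eig_centroid(X)
            W = float(np.sum(d_own**2))
            B = float(np.sum(counts * _dist_to(T, t_glob[None, :])[:, 0] ** 2))
            if W > 0 and M > k:
                scores["calinski_harabasz"][k] = (B / (k - 1)) / (W / (M - k))
        if "dunn" in names:
            inter = np.inf
            intra = 0.0
            for kk in range(k):
                sel = lab == kk
                if sel.sum() > 1:
                    intra = max(intra, float(D[np.ix_(sel, sel)].max()))
                for ll in range(kk + 1, k):
                    sub = D[np.ix_(sel, lab == ll)]
                    if sub.size:
                        inter = min(inter, float(sub.min()))
            if intra > 0 and np.isfinite(inter):
                scores["dunn"][k] = inter / intra
        if "point_biserial" in names:
            sb = d_flat[~same_flat]
            sw = d_flat[same_flat]
            if sb.size and sw.size and d_flat.std() > 0:
                nt = d_flat.size
                scores["point_biserial"][k] = float(
                    (sb.mean() - sw.mean())
                    * np.sqrt(sb.size * sw.size / nt**2)
                    / d_flat.std()
                )
        if "cross_validation" in names:
            # predictive residual variance with a degrees-of-freedom penalty
            sigma2 = within[k] / (M * p_eff)
            if p_eff - k > 0:
                scores["cross_validation"][k] = -float(
                    sigma2 * (p_eff / (p_eff - k)) ** 2
                )
    if "krzanowski_lai" in names:
        for k in ks:
            if k - 1 in within and k + 1 in within and k >= 2:
                diff_k = (k - 1) ** (2 / p_eff) * within[k - 1] - k ** (2 / p_eff) * within[k]
                diff_k1 = k ** (2 / p_eff) * within[k] - (k + 1) ** (2 / p_eff) * within[k + 1]
                if diff_k1 != 0.0:
                    scores["krzanowski_lai"][k] = float(abs(diff_k / diff_k1))
    return scores


#: optimization direction per criterion (True = maximize).
_MAXIMIZE = {
    "silhouette": True,
    "davies_bouldin": False,
    "calinski_harabasz": True,
    "dunn": True,
    "point_biserial": True,
    "krzanowski_lai": True,
    "cross_validation": True,  # stored negated, so maximize
}


def _lower_median(values: list[int]) -> int:
    """Median with even-count ties broken to the smaller value."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def validity_criteria(
    maps: np.ndarray,
    fits: dict[int, KMeansFit],
    criteria: tuple[str, ...] = DEFAULT_CRITERIA,
) -> MetaCriterionResult:
    """Meta-criterion cluster-number selection.

    For each named criterion the best K over the fitted range is recorded;
    the meta-criterion K is the median of those optima, ties broken to the
    smaller K.  Criteria that are undefined over the whole range (e.g. the
    Krzanowski-Lai index at range edges, degenerate fits) are dropped with a
    logged note.
    """
    if len(fits) < 3:
        raise ValueError("meta-criterion needs fits over at least 3 values of K")
    X = normalize_maps(maps)
    scores = _criterion_scores(X, fits, criteria)
    optima: dict[str, int] = {}
    for name in criteria:
        sc = scores.get(name, {})
        if not sc:
            logger.warning("criterion %s undefined over the K range; excluded", name)
            continue
        sign = 1.0 if _MAXIMIZE[name] else -1.0
        # ties to smaller K: iterate ascending, strict improvement required
        best_k, best_v = None, -np.inf
        for k in sorted(sc):
            v = sign * sc[k]
            if v > best_v:
                best_k, best_v = k, v
        optima[name] = int(best_k)
    if not optima:
        raise ValueError("no validity criterion could be evaluated")
    meta_k = _lower_median(list(optima.values()))
    return MetaCriterionResult(optima=optima, meta_k=meta_k, scores=scores)


def fit_k_range(
    maps: np.ndarray,
    k_range: range | list[int],
    *,
    n_restarts: int = 20,
    seed: int | np.random.Generator,
    weights: np.ndarray | None = None,
    provenance: str = "",
) -> dict[int, KMeansFit]:
    """Run modified k-means for every K in ``k_range`` from one seed stream."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return {
        int(k): modified_kmeans(
            maps, int(k), n_restarts=n_restarts, seed=rng, weights=weights,
            provenance=provenance,
        )
        for k in k_range
    }
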