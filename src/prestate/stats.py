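"""Nonparametric statistics for repeated-measures load effects.

Friedman's rank test (with mid-rank tie correction and an exact/Monte Carlo
permutation option), Dunn's pairwise post hoc with familywise adjustment,
and Pearson correlation.  Input is a subjects x conditions block matrix (or
the tidy long format via :func:`blocks_from_tidy`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    mean_ranks: np.ndarray
    n_subjects: int
    method: str = "chi-square"


@dataclass
class DunnResult:
    """Pairwise Dunn comparisons; one row per unordered condition pair."""

    table: pd.DataFrame   # columns: i, j, z, p_raw, p_adj, significant
    alpha: float
    adjustment: str


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def _check_blocks(blocks: np.ndarray) -> np.ndarray:
    x = np.asarray(blocks, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a (subjects >= 2, conditions >= 2) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite cells are not supported")
    return x


def _chi2_from_ranks(ranks: np.ndarray, tie_term: float) -> float:
    n, k = ranks.shape
    col = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(col**2)) - 3.0 * n * (k + 1)
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0
    return chi2 / denom


def friedman(blocks: np.ndarray, *, method: str = "auto",
             n_mc: int = 20000, seed: int = 0) -> FriedmanResult:
    """Friedman rank test across conditions with subjects as blocks.

    Values are ranked within each subject (mid-ranks on ties, with the
    standard tie correction of the chi-square statistic).  ``method`` is
    ``"chi-square"`` (asymptotic, df = k-1), ``"permutation"`` (exact
    enumeration of within-subject orderings when (k!)^n is small, Monte
    Carlo otherwise), or ``"auto"`` (chi-square).
    """
    x = _check_blocks(blocks)
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    ties = 0.0
    for i in range(n):
        _, counts = np.unique(x[i], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    chi2 = _chi2_from_ranks(ranks, ties)
    mean_ranks = ranks.mean(axis=0)
    if method in ("auto", "chi-square"):
        p = float(sps.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
        return FriedmanResult(chi2, k - 1, p, mean_ranks, n, "chi-square")
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    perms = list(itertools.permutations(range(k)))
    n_total = len(perms) ** n
    if n_total <= 2_000_000:
        # exact: enumerate all within-subject permutations of the rank rows
        count = 0
        total = 0
        for combo in itertools.product(range(len(perms)), repeat=n):
            r = np.array([ranks[i, list(perms[c])] for i, c in enumerate(combo)])
            total += 1
            if _chi2_from_ranks(r, ties) >= chi2 - 1e-12:
                count += 1
        p = count / total
        return FriedmanResult(chi2, k - 1, p, mean_ranks, n, "exact-permutation")
    rng = np.random.default_rng(seed)
    count = 1  # include the observed arrangement
    for _ in range(n_mc):
        r = np.array([ranks[i, rng.permutation(k)] for i in range(n)])
        if _chi2_from_ranks(r, ties) >= chi2 - 1e-12:
            count += 1
    p = count / (n_mc + 1)
    return FriedmanResult(chi2, k - 1, p, mean_ranks, n, "mc-permutation")


def friedman_chi2_batch(blocks: np.ndarray) -> np.ndarray:
    """Vectorized Friedman chi-square (no tie correction) for an array of
    (replicates, subjects, conditions) blocks -- a fast path for null
    simulations with continuous data."""
    x = np.asarray(blocks, dtype=float)
    r, n, k = x.shape
    ranks = sps.rankdata(x, axis=2)
    col = ranks.sum(axis=1)
    return 12.0 / (n * k * (k + 1)) * np.sum(col**2, axis=1) - 3.0 * n * (k + 1)


def dunn_posthoc(
    blocks: np.ndarray, *, alpha: float = 0.05, adjustment: str = "bonferroni"
) -> DunnResult:
    """Dunn's pairwise post hoc on Friedman mean ranks.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt(k (k+1) / (6 n))`` with two-sided
    normal p-values and familywise adjustment over all k(k-1)/2 pairs
    (Bonferroni by default; also "holm" or "none").
    """
    x = _check_blocks(blocks)
    n, k = x.shape
    ranks = sps.rankdata(x, axis=1)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append(dict(i=i, j=j, z=float(z), p_raw=min(p_raw, 1.0)))
    tab = pd.DataFrame(rows)
    if adjustment == "bonferroni":
        tab["p_adj"] = np.minimum(tab["p_raw"] * m, 1.0)
    elif adjustment == "holm":
        order = np.argsort(tab["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, (m - rank_pos) * tab["p_raw"].iloc[idx])
            adj[idx] = min(running, 1.0)
        tab["p_adj"] = adj
    elif adjustment == "none":
        tab["p_adj"] = tab["p_raw"]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    tab["significant"] = tab["p_adj"] < alpha
    return DunnResult(table=tab, alpha=alpha, adjustment=adjustment)


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def blocks_from_tidy(
    df: pd.DataFrame, value: str, subject: str = "subject", condition: str = "condition"
) -> np.ndarray:
    """Pivot a tidy (subject, condition, value) frame to a block matrix."""
    wide = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("missing subject x condition cells")
    return wide.to_numpy()
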