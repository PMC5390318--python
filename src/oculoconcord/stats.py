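"""Shared statistical helpers used across pipeline stages.

Thin, vectorised wrappers around scipy/statsmodels primitives plus the
row-wise Spearman machinery the matched-pair analysis needs.  Keeping them
in one place means every stage uses identical conventions (mid-ranks for
ties, two-sided p-values, Benjamini-Hochberg step-up).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import ArgumentError, UndefinedResultError

__all__ = [
    "bh_adjust",
    "spearman_rho",
    "rowwise_spearman",
    "spearman_p_t_approx",
    "spearman_p_exact",
    "rank_sum_test",
    "fisher_exact_test",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def _midranks(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return sps.rankdata(x, axis=axis, method="average")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Pairwise-complete: pairs with a missing member are dropped first.
    Raises :class:`UndefinedResultError` for fewer than 3 complete pairs or
    zero rank variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ArgumentError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise UndefinedResultError(
            f"need >= 3 complete pairs for Spearman correlation, got {x.size}"
        )
    rx, ry = _midranks(x), _midranks(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedResultError("zero rank variance: correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def rowwise_spearman(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of each row of ``x`` against the matching row of ``y``.

    Both arrays are (n_probes, n_donors) with no missing values; rows with
    zero rank variance on either side yield NaN.
    """
    rx = _midranks(x, axis=1)
    ry = _midranks(y, axis=1)
    zx = rx - rx.mean(axis=1, keepdims=True)
    zy = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((zx**2).sum(axis=1))
    sy = np.sqrt((zy**2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (zx * zy).sum(axis=1) / denom
    rho[denom == 0] = np.nan
    return np.clip(rho, -1.0, 1.0)


def spearman_p_t_approx(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via t = rho * sqrt((n-2)/(1-rho^2)),
    df = n - 2; |rho| = 1 maps to p = 0."""
    rho = np.asarray(rho, dtype=float)
    if n < 3:
        raise ArgumentError("need n >= 3 for the t approximation")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.minimum(p, 1.0))


def spearman_p_exact(x: np.ndarray, y: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Exact permutation p for row-wise Spearman rho at small n.

    Enumerates all n! orderings of the second vector's ranks per row
    (feasible for n <= 8) and reports the two-sided tail fraction
    ``P(|rho_perm| >= |rho_obs|)``, handling ties exactly because the
    observed mid-ranks are permuted.
    """
    from itertools import permutations

    n = x.shape[1]
    if n > 9:
        raise ArgumentError("exact permutation p only supported for n <= 9")
    perms = np.array(list(permutations(range(n))))  # (n!, n)
    rx = _midranks(x, axis=1)
    ry = _midranks(y, axis=1)
    zx = rx - rx.mean(axis=1, keepdims=True)
    zy = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((zx**2).sum(axis=1))
    sy = np.sqrt((zy**2).sum(axis=1))
    out = np.full(x.shape[0], np.nan)
    valid = (sx > 0) & (sy > 0)
    denom = sx * sy
    for i in np.nonzero(valid)[0]:
        rho_perm = (zx[i][perms] * zy[i]).sum(axis=1) / denom[i]
        out[i] = np.mean(np.abs(rho_perm) >= np.abs(rho[i]) - 1e-12)
    return out


def rank_sum_test(a, b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test, normal approximation
    with tie correction and no continuity correction.

    Returns ``(U, z, p)`` where U counts pairs won by ``a``.
    Raises :class:`UndefinedResultError` when all pooled values are tied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ArgumentError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise UndefinedResultError("all values tied: rank-sum test undefined")
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    u = float(res.statistic)
    n1, n2 = a.size, b.size
    mu = n1 * n2 / 2.0
    ranks = _midranks(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma = np.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term))
    z = (u - mu) / sigma
    return u, float(z), float(res.pvalue)


def fisher_exact_test(table) -> tuple[float, float]:
    """Two-sided Fisher exact test of a 2x2 count table.

    Returns ``(odds_ratio, p)``; the odds ratio is the sample
    cross-product ratio ``(a*d)/(b*c)`` with ``inf`` for zero denominators
    and NaN for 0/0.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ArgumentError("table must be 2x2 and nonnegative")
    a, b = t[0]
    c, d = t[1]
    num, den = a * d, b * c
    if den > 0:
        oddsratio = num / den
    else:
        oddsratio = np.nan if num == 0 else np.inf
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(oddsratio), float(p)
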