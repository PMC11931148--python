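"""Clinical validation statistics.

Spearman rank correlation with seeded percentile-bootstrap confidence
intervals, Mann-Whitney U (exact by enumeration for small tie-free samples,
tie-corrected normal approximation otherwise), Wilcoxon signed-rank (exact
sign-flip enumeration for small tie-free samples), the two-way random
average-measures absolute-agreement ICC, significance stars, and the
structure-function results table over volume/score columns.

Conventions: the reported U and W are the min-of-both-directions statistics;
exact two-sided p-values are tail probabilities of those minima, which for
the symmetric null equal the usual two-tailed p.  Missing values are dropped
pairwise per analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "spearman_r",
    "bootstrap_ci",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "icc_average_random_raters",
    "significance_stars",
    "structure_function_table",
]

#: largest pooled sample for which exact enumeration is used (tie-free data)
EXACT_N_MAX = 12


@dataclass(frozen=True)
class StatResult:
    test: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    stars: str


def _midrank(v: np.ndarray) -> np.ndarray:
    """Mid-ranks (ties averaged), vectorised; equivalent to rankdata."""
    order = np.argsort(v, kind="mergesort")
    sv = v[order]
    new_group = np.r_[True, sv[1:] != sv[:-1]]
    group = np.cumsum(new_group) - 1
    counts = np.bincount(group)
    ends = np.cumsum(counts)
    avg = ends - (counts - 1) / 2.0  # mean of ranks within each tie run
    ranks = np.empty(v.size)
    ranks[order] = avg[group]
    return ranks


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of mid-ranks (ties averaged)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rx = _midrank(x)
    ry = _midrank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0.0:
        raise ValueError("zero rank variance: correlation undefined")
    return float(rx @ ry) / denom


def bootstrap_ci(stat: Callable[[np.ndarray], float], data: np.ndarray,
                 n_boot: int = 10000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Seeded percentile bootstrap interval of ``stat`` over row-resamples
    (with replacement) of ``data``.

    ``stat`` receives a 2D array of resampled rows.  Resamples where the
    statistic raises or returns non-finite are dropped; more than 50%
    undefined is an error.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to bootstrap")
    rng = np.random.default_rng(seed)
    indices = rng.integers(0, n, size=(n_boot, n))
    values = []
    for idx in indices:
        try:
            v = stat(data[idx])
        except (ValueError, ZeroDivisionError, FloatingPointError):
            continue
        if np.isfinite(v):
            values.append(v)
    if len(values) < n_boot / 2:
        raise ValueError("statistic undefined on more than half of the resamples")
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U_x counts pairs with x below y (ties half); U_y the reverse."""
    less = (x[:, None] < y[None, :]).sum()
    ties = (x[:, None] == y[None, :]).sum()
    u_x = float(less) + 0.5 * float(ties)
    u_y = x.size * y.size - u_x
    return u_x, u_y


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(min(U_x, U_y), p)``.

    Exact p by full enumeration of group labelings when the pooled size is at
    most ``EXACT_N_MAX`` and there are no ties; otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u_x, u_y = _u_statistics(x, y)
    u = min(u_x, u_y)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if nx + ny <= EXACT_N_MAX and not has_ties:
        # exhaustive null distribution of U_min over all C(n, nx) labelings
        count = 0
        total = 0
        for combo in itertools.combinations(range(nx + ny), nx):
            sel = np.zeros(nx + ny, dtype=bool)
            sel[list(combo)] = True
            ux_i, uy_i = _u_statistics(pooled[sel], pooled[~sel])
            if min(ux_i, uy_i) <= u + 1e-12:
                count += 1
            total += 1
        return u, count / total

    mu = nx * ny / 2.0
    n = nx + ny
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        raise ValueError("degenerate data: zero variance")
    z = (u - mu + 0.5) / math.sqrt(sigma2)  # continuity-corrected, u <= mu
    p = min(1.0, 2.0 * sps.norm.cdf(z)) if u < mu else 1.0
    return u, p


def wilcoxon_signed_rank(differences: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences; returns
    ``(min(W+, W-), p)``.  Zeros are dropped; absolute ties are mid-ranked.

    Exact p enumerates all sign assignments when at most ``EXACT_N_MAX``
    nonzero tie-free differences remain; otherwise normal approximation.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    w = min(w_pos, w_neg)
    n = d.size
    has_ties = np.unique(np.abs(d)).size < n

    if n <= EXACT_N_MAX and not has_ties:
        total = ranks.sum()
        count = 0
        for signs in itertools.product([0, 1], repeat=n):
            wp = float(sum(r for r, s in zip(ranks, signs) if s))
            if min(wp, total - wp) <= w + 1e-12:
                count += 1
        return w, count / 2 ** n

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = (n * (n + 1) * (2 * n + 1)
              - 0.5 * (tie_counts ** 3 - tie_counts).sum()) / 24.0
    if sigma2 <= 0:
        raise ValueError("degenerate differences: zero variance")
    z = (w - mu + 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.cdf(z)) if w < mu else 1.0
    return w, p


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def icc_average_random_raters(ratings: np.ndarray) -> float:
    """Two-way random-effects, average-measures, absolute-agreement ICC —
    ICC(A,k) in the McGraw-Wong taxonomy — from the mean-squares
    decomposition of a complete subjects x raters matrix."""
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters matrix")
    n, k = ratings.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if not np.isfinite(ratings).all():
        raise ValueError("ratings matrix must be complete")

    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((ratings - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if denom == 0:
        raise ValueError("degenerate ratings: zero denominator")
    return float((msr - mse) / denom)


def significance_stars(p: float) -> str:
    """Star bands at 0.05 / 0.01 / 0.001 (strict inequalities)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of range: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# results table
# ---------------------------------------------------------------------------

def _spearman_row(vol: np.ndarray, score: np.ndarray, n_boot: int,
                  seed: int) -> StatResult:
    r = spearman_r(vol, score)
    data = np.column_stack([vol, score])
    low, high = bootstrap_ci(lambda rows: spearman_r(rows[:, 0], rows[:, 1]),
                             data, n_boot=n_boot, seed=seed)
    # p from the t approximation of Spearman's rho
    n = vol.size
    p = float(sps.spearmanr(vol, score).pvalue)
    return StatResult("spearman", r, low, high, p, n, significance_stars(p))


def _mannwhitney_row(vol: np.ndarray, finding: np.ndarray, n_boot: int,
                     seed: int) -> StatResult:
    groups = np.unique(finding)
    if groups.size != 2:
        raise ValueError("binary finding column must have exactly two levels")
    with_f = vol[finding == groups.max()]
    without = vol[finding == groups.min()]
    u, p = mann_whitney_u(with_f, without)
    data = np.column_stack([vol, finding])

    def stat(rows: np.ndarray) -> float:
        a = rows[rows[:, 1] == groups.max(), 0]
        b = rows[rows[:, 1] == groups.min(), 0]
        if a.size == 0 or b.size == 0:
            raise ValueError("empty group in resample")
        return mann_whitney_u(a, b)[0]

    low, high = bootstrap_ci(stat, data, n_boot=n_boot, seed=seed)
    return StatResult("mann_whitney_u", u, low, high, p, vol.size,
                      significance_stars(p))


def structure_function_table(scores: pd.DataFrame,
                             spec: Sequence[tuple[str, str, str]],
                             n_boot: int = 10000,
                             seed: int = 0) -> pd.DataFrame:
    """One :class:`StatResult` row per ``(volume column, score column, test)``
    triple; ``test`` is ``'spearman'`` for graded scores or
    ``'mann_whitney'`` for binary findings.  Missing values are dropped
    pairwise; rows with fewer than 3 complete pairs or degenerate scores are
    flagged instead of failing.  P-values are unadjusted by design.
    """
    rows = []
    for i, (vol_col, score_col, test) in enumerate(spec):
        for col in (vol_col, score_col):
            if col not in scores.columns:
                raise KeyError(f"column {col!r} not in score table")
        sub = scores[[vol_col, score_col]].dropna()
        base = {"volume": vol_col, "score": score_col, "test": test}
        if len(sub) < 3:
            rows.append({**base, "flag": "insufficient", "n": len(sub),
                         "estimate": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "stars": ""})
            continue
        vol = sub[vol_col].to_numpy(dtype=float)
        score = sub[score_col].to_numpy(dtype=float)
        try:
            if test == "spearman":
                res = _spearman_row(vol, score, n_boot, seed + i)
            elif test in ("mann_whitney", "mann_whitney_u"):
                res = _mannwhitney_row(vol, score, n_boot, seed + i)
            else:
                raise KeyError(f"unknown test {test!r}")
        except ValueError as exc:
            rows.append({**base, "flag": f"undefined: {exc}", "n": len(sub),
                         "estimate": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "stars": ""})
            continue
        rows.append({**base, "flag": "", "n": res.n, "estimate": res.estimate,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "p_value": res.p_value, "stars": res.stars})
    return pd.DataFrame(rows, columns=["volume", "score", "test", "flag", "n",
                                       "estimate", "ci_low", "ci_high",
                                       "p_value", "stars"])
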