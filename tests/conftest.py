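"""Shared fixtures and independent oracle implementations.

The oracle functions here are deliberately written as brute-force/naive
re-implementations (explicit loops, sorting, exhaustive enumeration) so they
stay independent of the package code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from brainquant.imaging_core import Hemisphere
from brainquant.phantom import (
    LesionClass,
    LesionSpec,
    PhantomConfig,
    generate_phantom,
)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SMALL_LESIONS = (
    LesionSpec(1, LesionClass.HYPERINTENSITY, (4.0, 6.0)),
    LesionSpec(1, LesionClass.CAVITY, (5.0, 7.0)),
)


def small_config(seed: int = 0, **kwargs) -> PhantomConfig:
    defaults = dict(shape=(32, 32, 32), spacing_mm=(4.0, 4.0, 4.0),
                    lesions=SMALL_LESIONS, seed=seed)
    defaults.update(kwargs)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 at 4 mm with one hyperintensity and one cavity."""
    return generate_phantom(small_config(seed=7))


@pytest.fixture(scope="session")
def default_phantom():
    """64^3 at 2 mm with lesions in both classes."""
    cfg = PhantomConfig(seed=11, lesions=(
        LesionSpec(2, LesionClass.HYPERINTENSITY, (3.0, 5.0),
                   hemisphere=Hemisphere.LEFT),
        LesionSpec(1, LesionClass.CAVITY, (4.0, 6.0)),
    ))
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def clean_phantom():
    """64^3 at 2 mm, no lesions."""
    return generate_phantom(PhantomConfig(seed=3))


# ---------------------------------------------------------------------------
# oracles: percentiles and normalization
# ---------------------------------------------------------------------------

def percentile_oracle(values, q: float) -> float:
    """Sort-based percentile with linear interpolation between order stats."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 1:
        return float(v[0])
    pos = q / 100.0 * (v.size - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def robust_stats_oracle(values, floor_pct=10.0, spread=(5.0, 95.0)):
    """Centre/spread recomputed by explicit sorting and selection."""
    flat = np.asarray(values, dtype=float).ravel()
    floor = percentile_oracle(flat, floor_pct)
    above = np.sort(flat[flat > floor])
    n = above.size
    center = (above[n // 2] if n % 2 == 1
              else 0.5 * (above[n // 2 - 1] + above[n // 2]))
    lo = percentile_oracle(flat, spread[0])
    hi = percentile_oracle(flat, spread[1])
    band = flat[(flat >= lo) & (flat <= hi)]
    mean = band.sum() / band.size
    var = ((band - mean) ** 2).sum() / band.size
    return float(center), float(math.sqrt(var))


# ---------------------------------------------------------------------------
# oracles: morphology and fusion
# ---------------------------------------------------------------------------

def chebyshev_dilation_oracle(mask: np.ndarray, radius: int) -> np.ndarray:
    """A voxel is set iff some set voxel lies within Chebyshev distance r."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    set_voxels = np.argwhere(mask)
    for idx in np.ndindex(mask.shape):
        if set_voxels.size and (np.abs(set_voxels - np.asarray(idx)).max(axis=1)
                                <= radius).any():
            out[idx] = True
    return out


def fusion_reference(affected, filled, dilated, t1, low, high, csf_id):
    """Per-voxel three-branch reference for the silver-label fusion rules."""
    out = np.empty_like(affected)
    for idx in np.ndindex(affected.shape):
        if not dilated[idx]:
            out[idx] = affected[idx]
        elif low <= t1[idx] <= high:
            out[idx] = csf_id
        else:
            v = filled[idx]
            out[idx] = v if v != 0 else csf_id
    return out


# ---------------------------------------------------------------------------
# oracles: overlap metrics
# ---------------------------------------------------------------------------

def dice_oracle(a, b) -> float:
    a = set(map(tuple, np.argwhere(np.asarray(a, dtype=bool))))
    b = set(map(tuple, np.argwhere(np.asarray(b, dtype=bool))))
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def surface_oracle(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-neighbour outside the mask (edges background)."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for idx in np.argwhere(mask):
        for off in offsets:
            nb = idx + np.asarray(off)
            if ((nb < 0).any() or (nb >= np.asarray(mask.shape)).any()
                    or not mask[tuple(nb)]):
                out[tuple(idx)] = True
                break
    return out


def hd95_oracle(a, b, spacing) -> float:
    """All-pairs surface-distance 95th percentile, symmetrized by max."""
    sa = np.argwhere(surface_oracle(a)) * np.asarray(spacing, dtype=float)
    sb = np.argwhere(surface_oracle(b)) * np.asarray(spacing, dtype=float)
    d = np.sqrt(((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2))
    d_ab = percentile_oracle(d.min(axis=1), 95.0)
    d_ba = percentile_oracle(d.min(axis=0), 95.0)
    return max(d_ab, d_ba)


# ---------------------------------------------------------------------------
# oracles: statistics
# ---------------------------------------------------------------------------

def midrank_oracle(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    ranks = np.empty(v.size)
    order = np.argsort(v, kind="stable")
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_oracle(x, y) -> float:
    rx = midrank_oracle(x)
    ry = midrank_oracle(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def mwu_oracle(x, y):
    """U_min and exact two-sided p by exhaustive labeling enumeration."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def u_min(a, b):
        ua = sum(0.5 if xi == yj else float(xi < yj) for xi in a for yj in b)
        return min(ua, a.size * b.size - ua)

    u_obs = u_min(x, y)
    pooled = np.concatenate([x, y])
    hits = total = 0
    for combo in itertools.combinations(range(pooled.size), x.size):
        sel = np.zeros(pooled.size, dtype=bool)
        sel[list(combo)] = True
        if u_min(pooled[sel], pooled[~sel]) <= u_obs + 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


def wilcoxon_oracle(diffs):
    """W_min and exact two-sided p over all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = midrank_oracle(np.abs(d))
    w_pos = ranks[d > 0].sum()
    total = ranks.sum()
    w_obs = min(w_pos, total - w_pos)
    hits = 0
    n = d.size
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        if min(wp, total - wp) <= w_obs + 1e-12:
            hits += 1
    return w_obs, hits / 2 ** n


def icc_oracle(ratings: np.ndarray) -> float:
    """ICC(A,k) from the explicit ANOVA table, computed with loops."""
    ratings = np.asarray(ratings, dtype=float)
    n, k = ratings.shape
    grand = ratings.sum() / (n * k)
    msr = sum(k * (ratings[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = sum(n * (ratings[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (ratings[i, j] - ratings[i].mean()
                    - ratings[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)
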