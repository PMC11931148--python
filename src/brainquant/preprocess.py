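"""Intensity preprocessing before segmentation: percentile clipping and a
robust z-scoring variant whose centre is the median of above-floor voxels
and whose spread is the standard deviation over a central percentile band.

The composition is invariant (to float precision) under positive affine
rescalings of the input intensities, which is what makes it useful against
scanner-to-scanner intensity variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .imaging_core import Volume3D

__all__ = ["NormalizationParams", "clip_intensities", "robust_zscore", "normalize"]


@dataclass(frozen=True)
class NormalizationParams:
    clip_low_pct: float = 1.0
    clip_high_pct: float = 99.0
    #: centre statistic = median of voxels strictly above this percentile
    center_floor_pct: float = 10.0
    #: spread = std of voxels inside this central percentile band
    spread_range: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self) -> None:
        for low, high in [(self.clip_low_pct, self.clip_high_pct), self.spread_range]:
            if not (0.0 <= low < high <= 100.0):
                raise ValueError(f"percentile pair out of order: ({low}, {high})")
        if not (0.0 <= self.center_floor_pct <= 100.0):
            raise ValueError("center_floor_pct must be in [0, 100]")


def clip_intensities(vol: Volume3D,
                     params: NormalizationParams = NormalizationParams()) -> Volume3D:
    """Clip intensities at the configured low/high percentiles (linear
    interpolation between order statistics).

    A constant image has equal percentiles; it is returned unchanged with a
    warning rather than failing.
    """
    data = np.asarray(vol.data, dtype=np.float64)
    lo, hi = np.percentile(data, [params.clip_low_pct, params.clip_high_pct])
    if lo == hi:
        warnings.warn("constant image: clipping percentiles coincide, returning copy",
                      stacklevel=2)
        return vol.with_data(data.copy())
    return vol.with_data(np.clip(data, lo, hi))


def robust_statistics(data: np.ndarray,
                      params: NormalizationParams) -> tuple[float, float]:
    """Return (centre, spread) of the robust z-score for ``data``.

    centre = median of voxels strictly above the ``center_floor_pct``
    percentile value; spread = std (population, ddof=0) of voxels whose value
    lies inside ``spread_range`` percentiles, inclusive on both ends.
    """
    flat = np.asarray(data, dtype=np.float64).ravel()
    floor = np.percentile(flat, params.center_floor_pct)
    above = flat[flat > floor]
    if above.size == 0:
        raise ValueError("degenerate intensity distribution")
    center = float(np.median(above))
    lo, hi = np.percentile(flat, list(params.spread_range))
    band = flat[(flat >= lo) & (flat <= hi)]
    spread = float(np.std(band))
    return center, spread


def robust_zscore(vol: Volume3D,
                  params: NormalizationParams = NormalizationParams()) -> Volume3D:
    """Map every voxel to ``(x - c) / s`` with robust centre c and spread s."""
    data = np.asarray(vol.data, dtype=np.float64)
    center, spread = robust_statistics(data, params)
    if spread == 0.0:
        raise ValueError("degenerate intensity distribution")
    return vol.with_data((data - center) / spread)


def normalize(vol: Volume3D,
              params: NormalizationParams = NormalizationParams()) -> Volume3D:
    """Percentile clipping followed by the robust z-score; modality preserved."""
    return robust_zscore(clip_intensities(vol, params), params)
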