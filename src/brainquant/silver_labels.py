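"""Silver-ground-truth label fusion.

Merges a *lesion-affected* segmentation (accurate outside lesions) with a
*lesion-filled* segmentation (plausible inside lesions) under a dilated
manual lesion mask, using the T1 CSF intensity range of the lesion-affected
segmentation to decide which voxels inside the mask are fluid:

1. outside the dilated lesion mask — take the lesion-affected label;
2. inside the mask, T1 within the CSF percentile range (inclusive) — CSF;
3. inside the mask, T1 outside the range — take the lesion-filled label
   (background there falls back to the CSF id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_core import (
    LabelMap3D,
    Tissue,
    Volume3D,
    require_same_grid,
)

__all__ = ["FusionParams", "dilate_mask", "csf_intensity_range", "fuse_silver_gt"]


@dataclass(frozen=True)
class FusionParams:
    dilation_radius_voxels: int = 1
    csf_low_pct: float = 1.0
    csf_high_pct: float = 95.0
    #: label used when rule 3 hits background in the lesion-filled map;
    #: None selects the CSF id of the scheme
    csf_fallback_label: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.csf_low_pct < self.csf_high_pct <= 100.0):
            raise ValueError("CSF percentile pair out of order")
        if self.dilation_radius_voxels < 0:
            raise ValueError("dilation radius must be >= 0")


def dilate_mask(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological dilation with a 26-connected (3x3x3 cube) structuring
    element applied ``radius`` times; radius 0 is the identity."""
    mask = np.asarray(mask)
    if not np.isin(mask, [0, 1]).all():
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if radius == 0:
        return mask.copy()
    structure = np.ones((3, 3, 3), dtype=bool)
    return ndimage.binary_dilation(mask, structure=structure, iterations=radius)


def _csf_id(label_map: LabelMap3D) -> int:
    csf_ids = sorted(label_map.scheme.ids_for_tissue(Tissue.CSF))
    if not csf_ids:
        raise ValueError("scheme declares no CSF class")
    return csf_ids[0]


def csf_intensity_range(t1: Volume3D, lesion_affected: LabelMap3D,
                        params: FusionParams = FusionParams()) -> tuple[float, float]:
    """Percentile range (linear interpolation) of T1 intensities over the
    voxels labelled CSF in the lesion-affected segmentation."""
    require_same_grid(t1, lesion_affected)
    csf_ids = lesion_affected.scheme.ids_for_tissue(Tissue.CSF)
    if not csf_ids:
        raise ValueError("scheme declares no CSF class")
    csf_voxels = np.asarray(t1.data)[lesion_affected.mask(csf_ids)]
    if csf_voxels.size == 0:
        raise ValueError("no CSF voxels in lesion-affected segmentation")
    low, high = np.percentile(csf_voxels,
                              [params.csf_low_pct, params.csf_high_pct])
    return float(low), float(high)


def fuse_silver_gt(lesion_affected: LabelMap3D, lesion_filled: LabelMap3D,
                   lesion_mask: np.ndarray, t1: Volume3D,
                   params: FusionParams = FusionParams()) -> LabelMap3D:
    """Apply the three fusion rules voxel-wise and return the fused map.

    The output shares the lesion-affected scheme (its id space must cover the
    lesion-filled labels in play).
    """
    require_same_grid(lesion_affected, lesion_filled, t1)
    if lesion_mask.shape != lesion_affected.shape:
        raise ValueError("lesion mask grid mismatch")

    dilated = dilate_mask(lesion_mask, params.dilation_radius_voxels)
    low, high = csf_intensity_range(t1, lesion_affected, params)
    csf_id = params.csf_fallback_label
    if csf_id is None:
        csf_id = _csf_id(lesion_affected)

    t1_data = np.asarray(t1.data)
    in_range = (t1_data >= low) & (t1_data <= high)

    fused = lesion_affected.labels.copy()
    rule2 = dilated & in_range
    rule3 = dilated & ~in_range
    fused[rule2] = csf_id
    filled_labels = lesion_filled.labels
    fused[rule3] = filled_labels[rule3]
    fused[rule3 & (filled_labels == 0)] = csf_id
    return LabelMap3D(labels=fused, affine=lesion_affected.affine.copy(),
                      scheme=lesion_affected.scheme)
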