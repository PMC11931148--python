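"""Segmentation evaluation: Dice overlap, 95th-percentile Hausdorff surface
distance (mm), benchmark region grouping, and the defect-severity / review
status classifiers used for qualitative quality control.

Surface voxels are mask voxels with at least one 6-connected background
neighbour (grid edges count as background).  HD95 is symmetrised as the max
of the two directed 95th-percentile distances; the directed variants are
also exposed.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .imaging_core import LabelMap3D, LabelScheme, Tissue, remap_labels, require_same_grid

__all__ = [
    "DefectSeverity",
    "ReviewStatus",
    "dice_coefficient",
    "surface_voxels",
    "hausdorff95",
    "benchmark_grouping",
    "grouped_benchmark_metrics",
    "classify_defect",
    "review_status",
]


def benchmark_grouping(scheme: LabelScheme) -> dict[str, frozenset[int]]:
    """Benchmark region grouping: CSF, GM, WM, deep GM, brainstem and
    cerebellum, built from the scheme's tissue tags and named groups.

    Deep GM, brainstem and cerebellum ids (when those groups are declared)
    are pulled out of the generic GM/WM pools.
    """
    deep = scheme.groups.get("deep_gm", frozenset())
    stem = scheme.groups.get("brainstem", frozenset())
    cereb = scheme.groups.get("cerebellum", frozenset())
    gm = scheme.ids_for_tissue(Tissue.GM) - deep - stem - cereb
    wm = scheme.ids_for_tissue(Tissue.WM) - deep - stem - cereb
    grouping: dict[str, frozenset[int]] = {
        "csf": scheme.ids_for_tissue(Tissue.CSF),
        "gm": gm,
        "wm": wm,
    }
    if deep:
        grouping["deep_gm"] = deep
    if stem:
        grouping["brainstem"] = stem
    if cereb:
        grouping["cerebellum"] = cereb
    return {k: v for k, v in grouping.items() if v}


class DefectSeverity(enum.Enum):
    MINOR = "MINOR"
    INTERMEDIATE = "INTERMEDIATE"
    MAJOR = "MAJOR"


class ReviewStatus(enum.Enum):
    APPROVED = "APPROVED"
    APPROVED_WITH_REMARKS = "APPROVED_WITH_REMARKS"
    REJECTED = "REJECTED"


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """``2|a&b| / (|a|+|b|)``; 1.0 when both masks are empty, 0.0 when
    exactly one is."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / size


_FACES = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-connected background neighbour (edges included)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=_FACES, border_value=0)
    return mask & ~eroded


def _directed_95(surf_a: np.ndarray, surf_b: np.ndarray,
                 spacing: Sequence[float]) -> float:
    """95th percentile (linear interpolation) of distances from each voxel of
    surface a to the nearest voxel of surface b, in mm."""
    pts_a = np.argwhere(surf_a) * np.asarray(spacing, dtype=float)
    pts_b = np.argwhere(surf_b) * np.asarray(spacing, dtype=float)
    dists, _ = cKDTree(pts_b).query(pts_a, k=1)
    return float(np.percentile(dists, 95))


def hausdorff95(a: np.ndarray, b: np.ndarray,
                spacing: Sequence[float] = (1.0, 1.0, 1.0),
                symmetrize: str = "max") -> float:
    """95th-percentile Hausdorff distance between two binary masks in mm.

    ``symmetrize='max'`` (default) takes the max of the two directed
    distances; ``'a_to_b'``/``'b_to_a'`` return a single direction.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise ValueError("hausdorff95 undefined for empty masks")
    surf_a, surf_b = surface_voxels(a), surface_voxels(b)
    if symmetrize == "a_to_b":
        return _directed_95(surf_a, surf_b, spacing)
    if symmetrize == "b_to_a":
        return _directed_95(surf_b, surf_a, spacing)
    if symmetrize != "max":
        raise ValueError(f"unknown symmetrization {symmetrize!r}")
    return max(_directed_95(surf_a, surf_b, spacing),
               _directed_95(surf_b, surf_a, spacing))


def grouped_benchmark_metrics(pred: LabelMap3D, truth: LabelMap3D,
                              grouping: Mapping[str, Iterable[int]],
                              ) -> pd.DataFrame:
    """Remap both maps by ``grouping`` then compute Dice and HD95 per group.

    Rows follow the grouping order; a group with no truth voxels is flagged
    ``missing`` with NaN metrics.
    """
    require_same_grid(pred, truth)
    pred_g = remap_labels(pred, grouping)
    truth_g = remap_labels(truth, grouping)
    # per-axis voxel spacing = column norms of the direction matrix
    spacing = np.sqrt((truth.affine[:3, :3] ** 2).sum(axis=0))
    rows = []
    for idx, name in enumerate(grouping, start=1):
        p_mask = pred_g.labels == idx
        t_mask = truth_g.labels == idx
        if not t_mask.any():
            rows.append({"region": name, "dice": np.nan, "hd95_mm": np.nan,
                         "missing": True})
            continue
        dice = dice_coefficient(p_mask, t_mask)
        hd = (hausdorff95(p_mask, t_mask, spacing=spacing)
              if p_mask.any() else np.nan)
        rows.append({"region": name, "dice": dice, "hd95_mm": hd,
                     "missing": False})
    return pd.DataFrame(rows, columns=["region", "dice", "hd95_mm", "missing"])


def classify_defect(fraction: float) -> DefectSeverity:
    """Severity of a parcellation defect from its fraction of region volume:
    <=10% minor, (10%, 25%] intermediate, >25% major."""
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"defect fraction must be in [0, 1], got {fraction}")
    if fraction <= 0.10:
        return DefectSeverity.MINOR
    if fraction <= 0.25:
        return DefectSeverity.INTERMEDIATE
    return DefectSeverity.MAJOR


def review_status(defects: Sequence[DefectSeverity]) -> ReviewStatus:
    """Approval category from a list of classified defects.

    Rejected: any major defect or more than three intermediate defects.
    Approved with remarks: one to three intermediate defects, or more than
    three minor defects.  Approved: at most three minor defects and nothing
    else.
    """
    counts = Counter(defects)
    major = counts[DefectSeverity.MAJOR]
    inter = counts[DefectSeverity.INTERMEDIATE]
    minor = counts[DefectSeverity.MINOR]
    if major >= 1 or inter > 3:
        return ReviewStatus.REJECTED
    if inter >= 1 or minor > 3:
        return ReviewStatus.APPROVED_WITH_REMARKS
    return ReviewStatus.APPROVED
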