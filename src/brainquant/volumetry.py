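"""Regional volumetry: total / lesion / lesion-free volumes per region,
hemisphere splitting by world-x sign, affected-vs-less-affected relative
asymmetry, and atlas-guided WM-lobe / PLIC postprocessing.

The lesion-free volume of a region is its total volume minus the volume of
lesion voxels falling inside it; lesion voxels are attributed to the region
of the underlying structural label.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .imaging_core import (
    AtlasMap,
    Hemisphere,
    LabelEntry,
    LabelMap3D,
    LabelScheme,
    Tissue,
    voxel_volume_ml,
    world_x_coordinates,
)

__all__ = [
    "HemisphereAssignment",
    "AsymmetryDenominator",
    "region_volumes",
    "lesion_free_volumes",
    "validate_report",
    "split_hemispheres",
    "relative_asymmetry",
    "atlas_postprocess",
]

REPORT_COLUMNS = ["region", "hemisphere", "total_ml", "lesion_ml", "lesion_free_ml"]


@dataclass(frozen=True)
class HemisphereAssignment:
    """Affected hemisphere is contralateral to the clinical (motor) side."""

    clinical_side: Hemisphere

    def __post_init__(self) -> None:
        if self.clinical_side not in (Hemisphere.LEFT, Hemisphere.RIGHT):
            raise ValueError("clinical side must be LEFT or RIGHT")

    @property
    def affected_hemisphere(self) -> Hemisphere:
        return (Hemisphere.RIGHT if self.clinical_side is Hemisphere.LEFT
                else Hemisphere.LEFT)

    @property
    def less_affected_hemisphere(self) -> Hemisphere:
        return self.clinical_side


class AsymmetryDenominator(enum.Enum):
    MEAN = "mean"
    LESS_AFFECTED = "less_affected"


def region_volumes(labels: LabelMap3D) -> dict[str, float]:
    """Volume per region name in mL (voxel count x voxel volume)."""
    vox = voxel_volume_ml(labels)
    counts = np.bincount(labels.labels.ravel(),
                         minlength=max(labels.scheme.ids, default=0) + 1)
    return {e.name: float(counts[e.id] * vox) for e in labels.scheme.entries}


def lesion_free_volumes(labels: LabelMap3D,
                        lesion_masks: Mapping[object, np.ndarray] | np.ndarray,
                        ) -> pd.DataFrame:
    """Per-region total / lesion / lesion-free volumes (mL) as a DataFrame.

    ``lesion_masks`` may be a single binary mask or a mapping of masks whose
    union is used.  Lesion voxels on background are warned about and excluded.
    """
    if isinstance(lesion_masks, np.ndarray):
        union = lesion_masks.astype(bool)
    else:
        union = np.zeros(labels.shape, dtype=bool)
        for m in lesion_masks.values():
            union |= m.astype(bool)
    if union.shape != labels.shape:
        raise ValueError("lesion mask grid mismatch")

    vox = voxel_volume_ml(labels)
    on_background = union & (labels.labels == 0)
    if on_background.any():
        warnings.warn(
            f"{int(on_background.sum())} lesion voxels fall on background "
            "and are excluded from all regions", stacklevel=2)

    max_id = max(labels.scheme.ids, default=0)
    total_counts = np.bincount(labels.labels.ravel(), minlength=max_id + 1)
    lesion_counts = np.bincount(labels.labels[union].ravel(), minlength=max_id + 1)
    rows = []
    for e in labels.scheme.entries:
        total = float(total_counts[e.id] * vox)
        lesion = float(lesion_counts[e.id] * vox)
        rows.append({
            "region": e.name,
            "hemisphere": e.hemisphere.value,
            "total_ml": total,
            "lesion_ml": lesion,
            "lesion_free_ml": total - lesion,
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    validate_report(report)
    return report


def validate_report(report: pd.DataFrame, atol: float = 1e-9) -> None:
    resid = (report["lesion_free_ml"] - (report["total_ml"] - report["lesion_ml"])).abs()
    if (resid > atol).any():
        raise ValueError("volume conservation violated: lesion_free != total - lesion")
    if (report[["total_ml", "lesion_ml", "lesion_free_ml"]] < -atol).any().any():
        raise ValueError("negative volume in report")
    if (report["lesion_ml"] > report["total_ml"] + atol).any():
        raise ValueError("lesion volume exceeds total volume")


def split_hemispheres(labels: LabelMap3D) -> LabelMap3D:
    """Split bilateral (hemisphere NA) labels into left/right/midline variants
    by the sign of each voxel centre's world x; pre-tagged structures keep
    their tag and id.  World x > 0 is the anatomical right; exactly 0 is
    midline."""
    x = world_x_coordinates(labels.shape, labels.affine)
    entries = list(labels.scheme.entries)
    next_id = max(labels.scheme.ids, default=0) + 1
    new_labels = labels.labels.copy()
    new_entries: list[LabelEntry] = []
    for e in entries:
        if e.hemisphere is not Hemisphere.NA:
            new_entries.append(e)
            continue
        region = labels.labels == e.id
        for hemi, sel in ((Hemisphere.LEFT, x < 0),
                          (Hemisphere.RIGHT, x > 0),
                          (Hemisphere.MIDLINE, x == 0)):
            voxels = region & sel
            if hemi is Hemisphere.LEFT:
                # reuse the original id for the left part to stay compact
                new_id = e.id
            else:
                new_id = next_id
                next_id += 1
            new_labels[voxels] = new_id
            suffix = hemi.value.lower()
            new_entries.append(LabelEntry(new_id, f"{e.name}_{suffix}",
                                          e.tissue, hemi))
    scheme = LabelScheme(entries=tuple(new_entries))
    return LabelMap3D(labels=new_labels, affine=labels.affine.copy(), scheme=scheme)


def _base_region(name: str, hemi: str) -> str:
    suffix = "_" + hemi.lower()
    return name[: -len(suffix)] if name.lower().endswith(suffix) else name


def relative_asymmetry(report: pd.DataFrame, assignment: HemisphereAssignment,
                       value_column: str = "lesion_free_ml",
                       denominator: AsymmetryDenominator = AsymmetryDenominator.MEAN,
                       ) -> pd.Series:
    """Percent volume difference between affected and less-affected
    hemispheres per region: ``100 * (V_aff - V_less) / denom``.

    With the default denominator (mean of the two volumes) the measure is
    bounded in +-200% and antisymmetric under swapping the affected side.
    Regions where both hemispheres are zero are reported as missing (NaN).
    """
    aff = assignment.affected_hemisphere.value
    less = assignment.less_affected_hemisphere.value
    by_hemi: dict[str, dict[str, float]] = {aff: {}, less: {}}
    for _, row in report.iterrows():
        if row["hemisphere"] in by_hemi:
            base = _base_region(row["region"], row["hemisphere"])
            by_hemi[row["hemisphere"]][base] = float(row[value_column])

    regions = sorted(set(by_hemi[aff]) | set(by_hemi[less]))
    out = {}
    for region in regions:
        if region not in by_hemi[aff] or region not in by_hemi[less]:
            missing = aff if region not in by_hemi[aff] else less
            raise ValueError(f"region {region!r} missing {missing} hemisphere volume")
        v_aff, v_less = by_hemi[aff][region], by_hemi[less][region]
        if v_aff == 0.0 and v_less == 0.0:
            out[region] = np.nan
            continue
        if denominator is AsymmetryDenominator.MEAN:
            denom = 0.5 * (v_aff + v_less)
        else:
            denom = v_less
        out[region] = 100.0 * (v_aff - v_less) / denom
    return pd.Series(out, name="relative_asymmetry_pct")


def atlas_postprocess(wm_mask: np.ndarray, cgm_mask: np.ndarray,
                      atlas: AtlasMap) -> LabelMap3D:
    """Refine WM and cortical-GM masks with atlas territories.

    WM voxels are labelled by the lobar or PLIC territory they fall in; CGM
    voxels by lobar territories only.  Voxels outside every territory keep
    generic WM/CGM ids.  The two masks must be disjoint.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    cgm_mask = np.asarray(cgm_mask, dtype=bool)
    if wm_mask.shape != atlas.shape or cgm_mask.shape != atlas.shape:
        raise ValueError("mask grid mismatch with atlas")
    if (wm_mask & cgm_mask).any():
        raise ValueError("WM and CGM masks overlap")

    entries: list[LabelEntry] = []
    out = np.zeros(atlas.shape, dtype=np.int16)
    next_id = 1
    for e in atlas.scheme.entries:
        territory = atlas.labels == e.id
        is_plic = e.name.lower().startswith("plic")
        out[wm_mask & territory] = next_id
        entries.append(LabelEntry(next_id, f"wm_{e.name}", Tissue.WM, e.hemisphere))
        next_id += 1
        if not is_plic:
            out[cgm_mask & territory] = next_id
            entries.append(LabelEntry(next_id, f"cgm_{e.name}", Tissue.GM,
                                      e.hemisphere))
            next_id += 1
    generic_wm = next_id
    entries.append(LabelEntry(generic_wm, "wm_generic", Tissue.WM, Hemisphere.NA))
    next_id += 1
    generic_cgm = next_id
    entries.append(LabelEntry(generic_cgm, "cgm_generic", Tissue.GM, Hemisphere.NA))
    out[wm_mask & (out == 0)] = generic_wm
    out[cgm_mask & (out == 0)] = generic_cgm
    # CGM voxels inside PLIC territories are not lobar: send them to generic
    plic_ids = [e.id for e in atlas.scheme.entries if e.name.lower().startswith("plic")]
    if plic_ids:
        in_plic = np.isin(atlas.labels, plic_ids)
        out[cgm_mask & in_plic] = generic_cgm
    scheme = LabelScheme(entries=tuple(entries))
    return LabelMap3D(labels=out, affine=atlas.affine.copy(), scheme=scheme)
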