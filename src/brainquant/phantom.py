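"""Seeded synthetic brain phantom.

Builds a nested-ellipsoid "brain" (CSF shell / cortical GM shell / WM core)
with paired deep grey structures, a two-lobed cerebellum and a three-part
brainstem, then renders paired pre-/post-lesion T1 and FLAIR images with
Gaussian per-tissue intensities, exact voxel ground-truth labels, per-class
lesion masks, analytic (closed-form ellipsoid) region volumes and a toy
lobar/PLIC atlas.

All geometry is specified in world millimetres so the same configuration can
be voxelised on any grid/spacing; the default test grid is 64 voxels at 2 mm
and acceptance runs use 1 mm spacing.

Intensity ordering (means): T1 CSF < GM < WM; FLAIR CSF < WM < GM with
hyperintense lesions above GM.  Cavities take near-CSF intensity in both
modalities, which is what the silver-label fusion rules key on.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .imaging_core import (
    AtlasMap,
    Hemisphere,
    LabelEntry,
    LabelMap3D,
    LabelScheme,
    Modality,
    Tissue,
    Volume3D,
    voxel_volume_ml,
    write_volume,
)

__all__ = [
    "LesionClass",
    "EllipsoidSpec",
    "LesionSpec",
    "PhantomConfig",
    "PhantomTruth",
    "StructureCollisionError",
    "LesionPlacementError",
    "generate_phantom",
    "insert_lesions",
    "shrink_hemisphere",
    "toy_atlas",
    "write_phantom",
]


class LesionClass(enum.Enum):
    HYPERINTENSITY = "HYPERINTENSITY"
    CAVITY = "CAVITY"


class StructureCollisionError(ValueError):
    """Deep structures or posterior-fossa parts overlap."""


class LesionPlacementError(RuntimeError):
    """A lesion could not be placed in its target tissue within the retry budget."""


@dataclass(frozen=True)
class EllipsoidSpec:
    name: str
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    hemisphere: Hemisphere = Hemisphere.NA
    tissue: Tissue = Tissue.GM

    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def scaled(self, factor: float) -> "EllipsoidSpec":
        a, b, c = self.semi_axes_mm
        return dataclasses.replace(self, semi_axes_mm=(a * factor, b * factor, c * factor))


@dataclass(frozen=True)
class LesionSpec:
    count: int
    lesion_class: LesionClass
    radius_mm: tuple[float, float] = (3.0, 6.0)
    target_tissue: Tissue = Tissue.WM
    hemisphere: Hemisphere = Hemisphere.NA  # NA places anywhere

    def __post_init__(self) -> None:
        lo, hi = self.radius_mm
        if lo <= 0 or hi < lo:
            raise ValueError(f"lesion radii must be positive and ordered, got {self.radius_mm}")
        if self.count < 0:
            raise ValueError("lesion count must be >= 0")


def _default_deep_structures() -> tuple[EllipsoidSpec, ...]:
    out: list[EllipsoidSpec] = []
    specs = [
        ("thalamus", (11.0, -4.0, 10.0), (6.0, 7.0, 5.0)),
        ("caudate", (13.0, 14.0, 16.0), (5.0, 7.0, 5.0)),
        ("putamen", (24.0, 2.0, 8.0), (5.0, 7.0, 5.0)),
        ("pallidum", (16.0, 2.0, 0.0), (4.5, 5.5, 4.5)),
    ]
    for name, (cx, cy, cz), semis in specs:
        out.append(EllipsoidSpec(f"{name}_left", (-cx, cy, cz), semis,
                                 Hemisphere.LEFT, Tissue.GM))
        out.append(EllipsoidSpec(f"{name}_right", (cx, cy, cz), semis,
                                 Hemisphere.RIGHT, Tissue.GM))
    return tuple(out)


def _default_posterior_fossa() -> tuple[EllipsoidSpec, ...]:
    return (
        EllipsoidSpec("cerebellum_left", (-16.0, -44.0, -24.0), (13.0, 11.0, 9.0),
                      Hemisphere.LEFT, Tissue.GM),
        EllipsoidSpec("cerebellum_right", (16.0, -44.0, -24.0), (13.0, 11.0, 9.0),
                      Hemisphere.RIGHT, Tissue.GM),
        EllipsoidSpec("midbrain", (0.0, -30.0, -30.0), (5.5, 5.5, 5.0),
                      Hemisphere.MIDLINE, Tissue.WM),
        EllipsoidSpec("pons", (0.0, -32.0, -42.0), (6.0, 6.0, 4.5),
                      Hemisphere.MIDLINE, Tissue.WM),
        EllipsoidSpec("medulla", (0.0, -34.0, -53.0), (5.0, 5.0, 5.5),
                      Hemisphere.MIDLINE, Tissue.WM),
    )


#: (t1_mean, flair_mean) per intensity class
_DEFAULT_INTENSITIES: dict[str, tuple[float, float]] = {
    "background": (5.0, 5.0),
    "csf": (20.0, 15.0),
    "gm": (60.0, 80.0),
    "wm": (90.0, 65.0),
    "hyperintensity": (78.0, 100.0),  # FLAIR above GM, T1 mildly below WM
    "cavity": (20.0, 15.0),           # near-CSF in both modalities
}


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    #: nested cerebral shells, outermost first: CSF / cortical GM / WM
    cerebrum_center_mm: tuple[float, float, float] = (0.0, 4.0, 12.0)
    csf_semi_axes_mm: tuple[float, float, float] = (44.0, 50.0, 38.0)
    gm_semi_axes_mm: tuple[float, float, float] = (40.0, 46.0, 34.0)
    wm_semi_axes_mm: tuple[float, float, float] = (34.0, 40.0, 28.0)
    deep_structures: tuple[EllipsoidSpec, ...] = field(default_factory=_default_deep_structures)
    posterior_fossa: tuple[EllipsoidSpec, ...] = field(default_factory=_default_posterior_fossa)
    intensities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_INTENSITIES))
    noise_sd: float = 2.0
    lesions: tuple[LesionSpec, ...] = ()
    shrink_side: Hemisphere | None = None
    shrink_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for outer, inner in [(self.csf_semi_axes_mm, self.gm_semi_axes_mm),
                             (self.gm_semi_axes_mm, self.wm_semi_axes_mm)]:
            if not all(o > i for o, i in zip(outer, inner)):
                raise ValueError("cerebral shells must be strictly nested")
        if not (0.0 < self.shrink_factor <= 1.0):
            raise ValueError("shrink factor must be in (0, 1]")
        if self.shrink_side not in (None, Hemisphere.LEFT, Hemisphere.RIGHT):
            raise ValueError("shrink side must be LEFT or RIGHT")


@dataclass
class PhantomTruth:
    """Ground-truth bundle: images, labels, lesion masks, analytic volumes."""

    t1_prelesion: Volume3D
    flair_prelesion: Volume3D
    t1: Volume3D
    flair: Volume3D
    labels: LabelMap3D
    lesion_masks: dict[LesionClass, np.ndarray]
    analytic_volumes_ml: dict[str, float]
    atlas: AtlasMap
    config: PhantomConfig

    @property
    def scheme(self) -> LabelScheme:
        return self.labels.scheme

    def union_lesion_mask(self) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=bool)
        for mask in self.lesion_masks.values():
            out |= mask
        return out


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _grid_affine(config: PhantomConfig) -> np.ndarray:
    affine = np.eye(4)
    for axis in range(3):
        affine[axis, axis] = config.spacing_mm[axis]
        affine[axis, 3] = -(config.shape[axis] - 1) / 2.0 * config.spacing_mm[axis]
    return affine


def _world_grids(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    affine = _grid_affine(config)
    coords = [
        affine[a, a] * np.arange(config.shape[a]) + affine[a, 3] for a in range(3)
    ]
    return (coords[0][:, None, None], coords[1][None, :, None], coords[2][None, None, :])


def _ellipsoid_mask(config: PhantomConfig, center: Sequence[float],
                    semis: Sequence[float]) -> np.ndarray:
    x, y, z = _world_grids(config)
    return (((x - center[0]) / semis[0]) ** 2
            + ((y - center[1]) / semis[1]) ** 2
            + ((z - center[2]) / semis[2]) ** 2) <= 1.0


def _structures_after_shrink(config: PhantomConfig) -> tuple[tuple[EllipsoidSpec, ...],
                                                             tuple[EllipsoidSpec, ...]]:
    deep, fossa = config.deep_structures, config.posterior_fossa
    if config.shrink_side is not None and config.shrink_factor < 1.0:
        f = config.shrink_factor
        deep = tuple(s.scaled(f) if s.hemisphere is config.shrink_side else s for s in deep)
        fossa = tuple(s.scaled(f) if s.hemisphere is config.shrink_side else s for s in fossa)
    return deep, fossa


def _build_scheme(deep: Sequence[EllipsoidSpec],
                  fossa: Sequence[EllipsoidSpec]) -> LabelScheme:
    entries = [
        LabelEntry(1, "csf", Tissue.CSF, Hemisphere.NA),
        LabelEntry(2, "cortical_gm", Tissue.GM, Hemisphere.NA),
        LabelEntry(3, "wm", Tissue.WM, Hemisphere.NA),
    ]
    next_id = 4
    name_to_id: dict[str, int] = {}
    for spec in list(deep) + list(fossa):
        entries.append(LabelEntry(next_id, spec.name, spec.tissue, spec.hemisphere))
        name_to_id[spec.name] = next_id
        next_id += 1

    def ids_with(prefix: str) -> set[int]:
        return {i for n, i in name_to_id.items() if n.startswith(prefix)}

    groups = {
        "deep_gm": (ids_with("thalamus") | ids_with("caudate")
                    | ids_with("putamen") | ids_with("pallidum")),
        "lenticular": ids_with("putamen") | ids_with("pallidum"),
        "lenticular_left": {i for n, i in name_to_id.items()
                            if n in ("putamen_left", "pallidum_left")},
        "lenticular_right": {i for n, i in name_to_id.items()
                             if n in ("putamen_right", "pallidum_right")},
        "brainstem": (ids_with("midbrain") | ids_with("pons") | ids_with("medulla")),
        "cerebellum": ids_with("cerebellum"),
    }
    groups = {k: v for k, v in groups.items() if v}
    return LabelScheme(entries=tuple(entries), groups=groups)


def _paint_labels(config: PhantomConfig, scheme: LabelScheme,
                  deep: Sequence[EllipsoidSpec],
                  fossa: Sequence[EllipsoidSpec]) -> np.ndarray:
    labels = np.zeros(config.shape, dtype=np.int16)
    c = config.cerebrum_center_mm
    labels[_ellipsoid_mask(config, c, config.csf_semi_axes_mm)] = 1
    labels[_ellipsoid_mask(config, c, config.gm_semi_axes_mm)] = 2
    labels[_ellipsoid_mask(config, c, config.wm_semi_axes_mm)] = 3

    collisions: list[str] = []
    for spec in deep:
        mask = _ellipsoid_mask(config, spec.center_mm, spec.semi_axes_mm)
        # deep structures must be carved entirely out of the WM core
        bad = labels[mask] != 3
        if bad.any():
            collisions.append(f"{spec.name} overlaps non-WM voxels")
            continue
        labels[mask] = scheme.id_of(spec.name)
    for spec in fossa:
        mask = _ellipsoid_mask(config, spec.center_mm, spec.semi_axes_mm)
        bad = labels[mask] != 0
        if bad.any():
            collisions.append(f"{spec.name} overlaps existing structures")
            continue
        labels[mask] = scheme.id_of(spec.name)
    if collisions:
        raise StructureCollisionError("; ".join(collisions))
    return labels


def _analytic_volumes(config: PhantomConfig, deep: Sequence[EllipsoidSpec],
                      fossa: Sequence[EllipsoidSpec]) -> dict[str, float]:
    def ell(semis: Sequence[float]) -> float:
        a, b, c = semis
        return 4.0 / 3.0 * np.pi * a * b * c

    vols: dict[str, float] = {}
    v_csf = ell(config.csf_semi_axes_mm)
    v_gm = ell(config.gm_semi_axes_mm)
    v_wm = ell(config.wm_semi_axes_mm)
    vols["csf"] = (v_csf - v_gm) / 1000.0
    vols["cortical_gm"] = (v_gm - v_wm) / 1000.0
    vols["wm"] = (v_wm - sum(s.volume_mm3() for s in deep)) / 1000.0
    for spec in list(deep) + list(fossa):
        vols[spec.name] = spec.volume_mm3() / 1000.0
    return vols


# ---------------------------------------------------------------------------
# intensities and lesions
# ---------------------------------------------------------------------------

def _intensity_class(entry: LabelEntry) -> str:
    if entry.tissue is Tissue.CSF:
        return "csf"
    if entry.tissue is Tissue.WM:
        return "wm"
    return "gm"


def _render_images(config: PhantomConfig, labels: np.ndarray, scheme: LabelScheme,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    size = max(int(labels.max()), max(scheme.ids, default=0)) + 1
    t1_mean = np.full(size, config.intensities["background"][0])
    fl_mean = np.full(size, config.intensities["background"][1])
    for entry in scheme.entries:
        key = _intensity_class(entry)
        t1_mean[entry.id], fl_mean[entry.id] = config.intensities[key]
    noise_t1 = rng.normal(0.0, config.noise_sd, size=labels.shape)
    noise_fl = rng.normal(0.0, config.noise_sd, size=labels.shape)
    return t1_mean[labels] + noise_t1, fl_mean[labels] + noise_fl


_MAX_LESION_RETRIES = 1000


def _place_lesions(config: PhantomConfig, labels: np.ndarray, scheme: LabelScheme,
                   t1: np.ndarray, flair: np.ndarray,
                   specs: Sequence[LesionSpec],
                   existing: dict[LesionClass, np.ndarray],
                   rng: np.random.Generator) -> dict[LesionClass, np.ndarray]:
    """Mutates t1/flair in place; returns per-class lesion masks."""
    x, y, z = _world_grids(config)
    masks = {cls: m.copy() for cls, m in existing.items()}
    occupied = np.zeros(labels.shape, dtype=bool)
    for m in masks.values():
        occupied |= m

    for spec in specs:
        tissue_ids = list(scheme.ids_for_tissue(spec.target_tissue))
        tissue_mask = np.isin(labels, tissue_ids)
        if spec.hemisphere is Hemisphere.LEFT:
            tissue_mask &= np.broadcast_to(x < 0, labels.shape)
        elif spec.hemisphere is Hemisphere.RIGHT:
            tissue_mask &= np.broadcast_to(x > 0, labels.shape)
        candidates = np.argwhere(tissue_mask)
        if candidates.size == 0:
            raise LesionPlacementError(
                f"no {spec.target_tissue.value} voxels available for lesion placement")
        for _ in range(spec.count):
            placed = False
            for _attempt in range(_MAX_LESION_RETRIES):
                idx = candidates[rng.integers(len(candidates))]
                radius = rng.uniform(*spec.radius_mm)
                cx = float(x[idx[0], 0, 0])
                cy = float(y[0, idx[1], 0])
                cz = float(z[0, 0, idx[2]])
                ball = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) <= radius ** 2
                if not ball.any():
                    continue
                if np.all(tissue_mask[ball]) and not occupied[ball].any():
                    mask = masks.setdefault(spec.lesion_class,
                                            np.zeros(labels.shape, dtype=bool))
                    mask |= ball
                    occupied |= ball
                    n = int(ball.sum())
                    if spec.lesion_class is LesionClass.HYPERINTENSITY:
                        m_t1, m_fl = config.intensities["hyperintensity"]
                        flair[ball] = m_fl + rng.normal(0, config.noise_sd, n)
                        t1[ball] = m_t1 + rng.normal(0, config.noise_sd, n)
                    else:
                        m_t1, m_fl = config.intensities["cavity"]
                        t1[ball] = m_t1 + rng.normal(0, config.noise_sd, n)
                        flair[ball] = m_fl + rng.normal(0, config.noise_sd, n)
                    placed = True
                    break
            if not placed:
                raise LesionPlacementError(
                    f"could not place {spec.lesion_class.value} lesion in "
                    f"{spec.target_tissue.value} ({spec.hemisphere.value}) "
                    f"after {_MAX_LESION_RETRIES} retries")
    return masks


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig) -> PhantomTruth:
    """Build a deterministic phantom from ``config`` (seeded by ``config.seed``)."""
    rng = np.random.default_rng(config.seed)
    deep, fossa = _structures_after_shrink(config)
    scheme = _build_scheme(deep, fossa)
    labels_arr = _paint_labels(config, scheme, deep, fossa)
    affine = _grid_affine(config)

    t1_pre, fl_pre = _render_images(config, labels_arr, scheme, rng)
    t1_post, fl_post = t1_pre.copy(), fl_pre.copy()
    masks = _place_lesions(config, labels_arr, scheme, t1_post, fl_post,
                           config.lesions, {}, rng)

    labels = LabelMap3D(labels=labels_arr, affine=affine, scheme=scheme)
    truth = PhantomTruth(
        t1_prelesion=Volume3D(t1_pre, affine, Modality.T1),
        flair_prelesion=Volume3D(fl_pre, affine, Modality.FLAIR),
        t1=Volume3D(t1_post, affine, Modality.T1),
        flair=Volume3D(fl_post, affine, Modality.FLAIR),
        labels=labels,
        lesion_masks=masks,
        analytic_volumes_ml=_analytic_volumes(config, deep, fossa),
        atlas=None,  # type: ignore[arg-type]  # filled just below
        config=config,
    )
    truth.atlas = toy_atlas(truth)
    return truth


def insert_lesions(phantom: PhantomTruth, specs: Sequence[LesionSpec],
                   seed: int) -> PhantomTruth:
    """Add further lesions to an existing phantom (never overlapping existing
    ones); ground-truth labels are untouched — lesions overlay tissue."""
    rng = np.random.default_rng(seed)
    t1 = phantom.t1.data.astype(np.float64).copy()
    flair = phantom.flair.data.astype(np.float64).copy()
    masks = _place_lesions(phantom.config, phantom.labels.labels,
                           phantom.scheme, t1, flair, specs,
                           phantom.lesion_masks, rng)
    return dataclasses.replace(
        phantom,
        t1=Volume3D(t1, phantom.t1.affine.copy(), Modality.T1),
        flair=Volume3D(flair, phantom.flair.affine.copy(), Modality.FLAIR),
        lesion_masks=masks,
    )


def shrink_hemisphere(phantom: PhantomTruth, side: Hemisphere,
                      factor: float) -> PhantomTruth:
    """Regenerate the phantom with every structure tagged to ``side`` scaled
    about its centroid by ``factor``; analytic volumes scale by ``factor**3``.
    """
    if not (0.0 < factor <= 1.0):
        raise ValueError("shrink factor must be in (0, 1]")
    combined = phantom.config.shrink_factor * factor
    if phantom.config.shrink_side not in (None, side) and factor < 1.0:
        raise ValueError("phantom already shrunk on the other side")
    cfg = dataclasses.replace(phantom.config, shrink_side=side,
                              shrink_factor=combined)
    return generate_phantom(cfg)


def toy_atlas(phantom: PhantomTruth) -> AtlasMap:
    """Toy localisation atlas: the foreground bounding box is cut into four
    anterior-posterior slabs per hemisphere (frontal, parietal, temporal,
    occipital) and a small PLIC box is carved out between the thalamus and
    lenticular nucleus on each side.  Territories are disjoint by
    construction (single integer image)."""
    config = phantom.config
    labels = phantom.labels.labels
    fg = labels > 0
    x, y, z = _world_grids(config)
    ys = np.broadcast_to(y, labels.shape)[fg]
    y_min, y_max = float(ys.min()), float(ys.max())
    edges = np.linspace(y_max, y_min, 5)  # anterior -> posterior

    lobes = ["frontal", "parietal", "temporal", "occipital"]
    entries = []
    atlas = np.zeros(labels.shape, dtype=np.int16)
    next_id = 1
    xb = np.broadcast_to(x, labels.shape)
    yb = np.broadcast_to(y, labels.shape)
    for li, lobe in enumerate(lobes):
        hi, lo = edges[li], edges[li + 1]
        # include the lower edge only on the last slab so slabs partition
        in_slab = (yb <= hi) & ((yb > lo) if li < 3 else (yb >= lo))
        for hemi, hmask in ((Hemisphere.LEFT, xb < 0), (Hemisphere.RIGHT, xb >= 0)):
            atlas[in_slab & hmask] = next_id
            entries.append(LabelEntry(next_id, f"{lobe}_{hemi.value.lower()}",
                                      Tissue.WM, hemi))
            next_id += 1

    # PLIC boxes sit between the thalamus and lenticular nucleus centres
    deep, _ = _structures_after_shrink(config)
    by_name = {s.name: s for s in deep}
    half = (3.0, 6.0, 5.0)
    for hemi, suffix in ((Hemisphere.LEFT, "left"), (Hemisphere.RIGHT, "right")):
        thal = by_name.get(f"thalamus_{suffix}")
        lent = by_name.get(f"pallidum_{suffix}") or by_name.get(f"putamen_{suffix}")
        if thal is None or lent is None:
            continue
        center = [(a + b) / 2.0 for a, b in zip(thal.center_mm, lent.center_mm)]
        zb = np.broadcast_to(z, labels.shape)
        box = ((np.abs(xb - center[0]) <= half[0])
               & (np.abs(yb - center[1]) <= half[1])
               & (np.abs(zb - center[2]) <= half[2]))
        atlas[box] = next_id
        entries.append(LabelEntry(next_id, f"plic_{suffix}", Tissue.WM, hemi))
        next_id += 1

    scheme = LabelScheme(entries=tuple(entries))
    return LabelMap3D(labels=atlas, affine=_grid_affine(config), scheme=scheme)


def write_phantom(phantom: PhantomTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the full phantom bundle (NIfTI set, analytic volumes JSON,
    label scheme YAML) into ``out_dir`` and return the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, vol in [("t1", phantom.t1), ("flair", phantom.flair),
                      ("t1_prelesion", phantom.t1_prelesion),
                      ("flair_prelesion", phantom.flair_prelesion)]:
        paths[name] = write_volume(vol, out / f"{name}.nii.gz")
    paths["labels"] = write_volume(phantom.labels, out / "labels.nii.gz")
    paths["atlas"] = write_volume(phantom.atlas, out / "atlas.nii.gz")
    for cls, mask in phantom.lesion_masks.items():
        lm = LabelMap3D(mask.astype(np.int16), phantom.labels.affine,
                        LabelScheme((LabelEntry(1, cls.value.lower(), Tissue.LESION),)))
        paths[f"lesions_{cls.value.lower()}"] = write_volume(
            lm, out / f"lesions_{cls.value.lower()}.nii.gz")
    (out / "analytic_volumes.json").write_text(
        json.dumps(phantom.analytic_volumes_ml, indent=2, sort_keys=True))
    paths["analytic_volumes"] = out / "analytic_volumes.json"
    phantom.scheme.to_yaml(out / "scheme.yaml")
    paths["scheme"] = out / "scheme.yaml"
    vox = voxel_volume_ml(phantom.labels)
    (out / "provenance.json").write_text(json.dumps(
        {"seed": phantom.config.seed, "voxel_volume_ml": vox,
         "shape": list(phantom.config.shape),
         "spacing_mm": list(phantom.config.spacing_mm)}, indent=2))
    return paths
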