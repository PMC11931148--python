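"""Core volumetric data model: typed 3D volumes, label maps, label schemes,
NIfTI I/O and label-grouping remaps shared by every pipeline stage.

Conventions
-----------
* World coordinates are RAS in millimetres: world ``x > 0`` is the anatomical
  right, ``y > 0`` anterior, ``z > 0`` superior.
* Voxel indices are 0-based; paired images must share the grid exactly
  (identical shape, affines equal to ``1e-4`` per entry) — there is no
  implicit resampling.
* Label value 0 is reserved for background.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "Modality",
    "Tissue",
    "Hemisphere",
    "LabelEntry",
    "LabelScheme",
    "Volume3D",
    "LabelMap3D",
    "AtlasMap",
    "GridMismatchError",
    "read_volume",
    "read_label_map",
    "write_volume",
    "voxel_volume_ml",
    "remap_labels",
    "same_grid",
    "world_x_coordinates",
]

#: tolerance for affine comparison between paired grids
AFFINE_ATOL = 1e-4


class Modality(enum.Enum):
    T1 = "T1"
    FLAIR = "FLAIR"
    OTHER = "OTHER"


class Tissue(enum.Enum):
    CSF = "CSF"
    GM = "GM"
    WM = "WM"
    LESION = "LESION"
    BACKGROUND = "BACKGROUND"


class Hemisphere(enum.Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    MIDLINE = "MIDLINE"
    NA = "NA"


class GridMismatchError(ValueError):
    """Raised when paired images do not share shape and affine."""


@dataclass(frozen=True)
class LabelEntry:
    id: int
    name: str
    tissue: Tissue = Tissue.GM
    hemisphere: Hemisphere = Hemisphere.NA

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"label id must be positive, got {self.id}")


@dataclass
class LabelScheme:
    """Registry of label ids with tissue/hemisphere tags and named groups.

    ``groups`` maps a group name (e.g. ``deep_gm``) to the set of member ids;
    every member must be a declared id.
    """

    entries: tuple[LabelEntry, ...]
    groups: dict[str, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = tuple(self.entries)
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate label ids in scheme")
        self.groups = {k: frozenset(v) for k, v in self.groups.items()}
        declared = set(ids)
        for name, members in self.groups.items():
            unknown = members - declared
            if unknown:
                raise ValueError(
                    f"group {name!r} references undeclared ids {sorted(unknown)}"
                )

    # -- lookups ---------------------------------------------------------
    @property
    def ids(self) -> frozenset[int]:
        return frozenset(e.id for e in self.entries)

    def __getitem__(self, label_id: int) -> LabelEntry:
        for e in self.entries:
            if e.id == label_id:
                return e
        raise KeyError(label_id)

    def id_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.id
        raise KeyError(name)

    def ids_for_tissue(self, tissue: Tissue) -> frozenset[int]:
        return frozenset(e.id for e in self.entries if e.tissue is tissue)

    def group(self, name: str) -> frozenset[int]:
        return self.groups[name]

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "labels": [
                {
                    "id": e.id,
                    "name": e.name,
                    "tissue": e.tissue.value,
                    "hemisphere": e.hemisphere.value,
                }
                for e in self.entries
            ],
            "groups": {k: sorted(v) for k, v in self.groups.items()},
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LabelScheme":
        doc = yaml.safe_load(Path(path).read_text())
        entries = tuple(
            LabelEntry(
                id=int(d["id"]),
                name=str(d["name"]),
                tissue=Tissue(d.get("tissue", "GM")),
                hemisphere=Hemisphere(d.get("hemisphere", "NA")),
            )
            for d in doc["labels"]
        )
        groups = {k: frozenset(int(i) for i in v) for k, v in (doc.get("groups") or {}).items()}
        return cls(entries=entries, groups=groups)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine: upper-left 3x3 not invertible")
    return affine


@dataclass
class Volume3D:
    """A scalar 3D image with a voxel-to-world affine and a modality tag."""

    data: np.ndarray
    affine: np.ndarray
    modality: Modality = Modality.OTHER

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"expected 3D volume, got shape {self.data.shape}"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "Volume3D":
        return Volume3D(data=data, affine=self.affine.copy(), modality=self.modality)


@dataclass
class LabelMap3D:
    """An integer 3D label image on a :class:`Volume3D` grid."""

    labels: np.ndarray
    affine: np.ndarray
    scheme: LabelScheme

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3D label map, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("label map must hold integers")
            self.labels = self.labels.astype(np.int16)
        if self.labels.min() < 0:
            raise ValueError("label values must be non-negative")
        self.affine = _check_affine(self.affine)
        present = set(np.unique(self.labels).tolist()) - {0}
        undeclared = present - set(self.scheme.ids)
        if undeclared:
            raise ValueError(f"labels {sorted(undeclared)} not declared in scheme")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def mask(self, label_ids: int | Iterable[int]) -> np.ndarray:
        if isinstance(label_ids, (int, np.integer)):
            return self.labels == int(label_ids)
        return np.isin(self.labels, list(label_ids))


#: An atlas is a label map whose scheme names disjoint spatial territories
#: (lobes per hemisphere, PLIC left/right).  Territory disjointness is
#: structural: a single integer image cannot overlap.
AtlasMap = LabelMap3D


def same_grid(a: Volume3D | LabelMap3D, b: Volume3D | LabelMap3D,
              atol: float = AFFINE_ATOL) -> bool:
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


def require_same_grid(*images: Volume3D | LabelMap3D) -> None:
    ref = images[0]
    for other in images[1:]:
        if not same_grid(ref, other):
            raise GridMismatchError(
                f"grid mismatch: {ref.shape} vs {other.shape} or affines differ"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality: Modality = Modality.OTHER) -> Volume3D:
    """Load a 3D NIfTI-1 file (optionally gzipped) as a :class:`Volume3D`.

    The modality is a caller hint; the header is not inspected for it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    return Volume3D(data=data, affine=np.asarray(img.affine), modality=modality)


def read_label_map(path: str | Path, scheme: LabelScheme) -> LabelMap3D:
    vol = read_volume(path)
    labels = np.asarray(vol.data)
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.round(labels)
        if not np.allclose(labels, rounded, atol=1e-6):
            raise ValueError(f"{path} does not hold integer labels")
        labels = rounded.astype(np.int16)
    return LabelMap3D(labels=labels, affine=vol.affine, scheme=scheme)


def write_volume(vol: Volume3D | LabelMap3D, path: str | Path) -> Path:
    """Write a volume or label map as NIfTI-1; labels stored as int16."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelMap3D):
        data = vol.labels
        if data.max(initial=0) > np.iinfo(np.int16).max:
            raise ValueError("label ids exceed int16 range")
        data = data.astype(np.int16)
    else:
        data = vol.data
    img = nib.Nifti1Image(data, vol.affine)
    img.set_data_dtype(data.dtype)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def voxel_volume_ml(vol: Volume3D | LabelMap3D) -> float:
    """Volume of one voxel in millilitres: ``|det(affine[:3,:3])| / 1000``."""
    det = np.linalg.det(vol.affine[:3, :3])
    if abs(det) < 1e-12:
        raise ValueError("singular affine")
    return abs(det) / 1000.0


def world_x_coordinates(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World x (left-right) coordinate of every voxel centre.

    Positive x is the anatomical right under the RAS convention.
    """
    i = np.arange(shape[0], dtype=float)
    j = np.arange(shape[1], dtype=float)
    k = np.arange(shape[2], dtype=float)
    x = (
        affine[0, 0] * i[:, None, None]
        + affine[0, 1] * j[None, :, None]
        + affine[0, 2] * k[None, None, :]
        + affine[0, 3]
    )
    return np.broadcast_to(x, shape).copy() if x.shape != shape else x


# ---------------------------------------------------------------------------
# Label remapping
# ---------------------------------------------------------------------------

def remap_labels(label_map: LabelMap3D,
                 grouping: Mapping[str, Iterable[int]]) -> LabelMap3D:
    """Collapse label ids into named groups.

    Output ids are consecutive group indices (1-based, in ``grouping``
    iteration order); voxels belonging to no group become background.
    Groups must be disjoint and reference declared ids.
    """
    seen: set[int] = set()
    declared = set(label_map.scheme.ids)
    for name, members in grouping.items():
        members = set(int(m) for m in members)
        unknown = members - declared
        if unknown:
            raise ValueError(f"group {name!r} references unknown ids {sorted(unknown)}")
        overlap = members & seen
        if overlap:
            raise ValueError(f"overlapping groups: ids {sorted(overlap)} appear twice")
        seen |= members

    max_id = int(label_map.labels.max(initial=0))
    lut = np.zeros(max(max_id, max(declared, default=0)) + 1, dtype=np.int16)
    entries = []
    for idx, (name, members) in enumerate(grouping.items(), start=1):
        member_entries = [label_map.scheme[m] for m in members]
        tissues = {e.tissue for e in member_entries}
        hemis = {e.hemisphere for e in member_entries}
        entries.append(LabelEntry(
            id=idx,
            name=name,
            tissue=tissues.pop() if len(tissues) == 1 else Tissue.GM,
            hemisphere=hemis.pop() if len(hemis) == 1 else Hemisphere.NA,
        ))
        for m in members:
            if m < lut.size:
                lut[m] = idx
    new_scheme = LabelScheme(entries=tuple(entries))
    return LabelMap3D(
        labels=lut[label_map.labels],
        affine=label_map.affine.copy(),
        scheme=new_scheme,
    )
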