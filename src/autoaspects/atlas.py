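"""ASPECTS region definitions and the template-space label atlas.

ASPECTS grades ten anterior-circulation territories per hemisphere —
caudate, putamen (lentiform), internal capsule, insula and the six MCA
cortical territories M1-M6 — so a complete atlas maps voxels to exactly
20 (name, hemisphere) regions.  The atlas is stored as a NIfTI integer
label volume plus a JSON sidecar table ``{label: {"name", "hemisphere"}}``;
hemisphere is carried in the table, never inferred from a midline, because
registered clinical atlases need not be symmetric.

Voxel indexing is 0-based and bounding boxes use the half-open convention
``[lo, hi)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["REGION_NAMES", "HEMISPHERES", "ASPECTSRegion", "all_regions",
           "RegionAtlas", "BoundingBox", "load_atlas", "save_atlas",
           "region_mask", "bounding_box", "AtlasFormatError"]

REGION_NAMES = ("caudate", "putamen", "internal_capsule", "insula",
                "M1", "M2", "M3", "M4", "M5", "M6")
HEMISPHERES = ("left", "right")


class AtlasFormatError(ValueError):
    """Raised when a label volume or its sidecar table is malformed."""


@dataclass(frozen=True, order=True)
class ASPECTSRegion:
    """One of the 20 scored territories: a name and a hemisphere."""

    name: str
    hemisphere: str

    def __post_init__(self):
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown ASPECTS region name {self.name!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")

    def __str__(self) -> str:
        return f"{self.hemisphere}_{self.name}"

    @classmethod
    def parse(cls, text: str) -> "ASPECTSRegion":
        hemi, _, name = text.partition("_")
        return cls(name, hemi)


def all_regions() -> list[ASPECTSRegion]:
    """The 20 distinct (name, hemisphere) pairs, hemisphere-major order."""
    return [ASPECTSRegion(n, h) for h in HEMISPHERES for n in REGION_NAMES]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open voxel-index box ``[lo, hi)`` per axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError(f"degenerate box {self.lo}..{self.hi}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass
class RegionAtlas:
    """Integer label volume in template space with its label table.

    ``labels`` uses 0 for background; every nonzero value present must have
    an entry in ``label_map``.  ``affine`` is the voxel-to-world matrix
    (right-handed axes); spacing is derived from it.
    """

    labels: np.ndarray
    label_map: dict[int, ASPECTSRegion]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise AtlasFormatError("label volume must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(self.labels == np.round(self.labels)):
                raise AtlasFormatError("label volume has non-integer voxel values")
            self.labels = self.labels.astype(np.int32)
        present = set(np.unique(self.labels)) - {0}
        unknown = present - set(self.label_map)
        if unknown:
            raise AtlasFormatError(f"labels {sorted(unknown)} present in volume "
                                   "but absent from the label table")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def regions(self) -> list[ASPECTSRegion]:
        return sorted(set(self.label_map.values()))

    def label_of(self, region: ASPECTSRegion) -> int:
        for lab, reg in self.label_map.items():
            if reg == region:
                return lab
        raise KeyError(f"region {region} not present in atlas")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def save_atlas(atlas: RegionAtlas, path) -> None:
    """Write the NIfTI label volume and its JSON sidecar label table."""
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    nib.save(img, path)
    table = {str(lab): {"name": reg.name, "hemisphere": reg.hemisphere}
             for lab, reg in atlas.label_map.items()}
    _sidecar_path(path).write_text(json.dumps(table, indent=1))


def load_atlas(path) -> RegionAtlas:
    """Read a label atlas written by :func:`save_atlas`.

    Raises :class:`AtlasFormatError` for non-integer voxel data or labels
    missing from the sidecar table.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise AtlasFormatError(f"missing label table {sidecar}")
    raw = json.loads(sidecar.read_text())
    try:
        label_map = {int(k): ASPECTSRegion(v["name"], v["hemisphere"]) for k, v in raw.items()}
    except (KeyError, ValueError, TypeError) as exc:
        raise AtlasFormatError(f"malformed label table {sidecar}: {exc}") from exc
    return RegionAtlas(labels=data, label_map=label_map, affine=img.affine)


def region_mask(atlas: RegionAtlas, region: ASPECTSRegion,
                labels: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask of the voxels carrying ``region``'s label.

    ``labels`` may override the atlas's own array (e.g. labels resampled
    into subject space) while reusing the atlas's label table.
    """
    lab = atlas.label_of(region)
    src = atlas.labels if labels is None else labels
    return src == lab


def bounding_box(mask: np.ndarray, margin_vox: int = 1) -> BoundingBox:
    """Minimal axis-aligned box containing all nonzero voxels, expanded by
    ``margin_vox`` and clipped to the volume bounds."""
    mask = np.asarray(mask)
    if margin_vox < 0:
        raise ValueError("margin_vox must be >= 0")
    nz = np.nonzero(mask)
    if nz[0].size == 0:
        raise ValueError("empty mask: region has no voxels")
    lo, hi = [], []
    for ax in range(mask.ndim):
        lo.append(max(int(nz[ax].min()) - margin_vox, 0))
        hi.append(min(int(nz[ax].max()) + 1 + margin_vox, mask.shape[ax]))
    return BoundingBox(tuple(lo), tuple(hi))
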