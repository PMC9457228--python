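"""Raw NCCT volume -> per-region normalized bounding subvolumes.

The pipeline is: (1) *soft intensity cropping*, a smooth monotone map of
Hounsfield units onto [0, 1] that suppresses bone and air while keeping
parenchymal contrast; (2) resampling the template-space ASPECTS label
atlas onto the subject grid through an externally supplied spatial
transform (identity for phantoms, an affine or precomputed dense
deformation for registered clinical data — registration itself is out of
scope); (3) cropping the normalized volume to each region's bounding box.

The soft crop is linear on the window ``[lo, hi]`` with half-cosine ramps
of width ``softness`` on either side, chosen so the full map is monotone,
continuous and C1: values <= lo - softness map to 0, >= hi + softness to
1, and the window midpoint to exactly 0.5.  With ``softness = 0`` it
degenerates to a hard linear window (identity on [0, 1] for the unit
window), which makes the map idempotent on already-normalized data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .atlas import ASPECTSRegion, BoundingBox, RegionAtlas, bounding_box, region_mask

__all__ = ["CTVolume", "RegionVolume", "soft_intensity_crop", "map_atlas_to_subject",
           "extract_region_volumes", "load_volume", "save_volume",
           "load_dicom_series", "MIN_INPLANE"]

#: smallest in-plane crop the classifier accepts (three stride-2 convolutions)
MIN_INPLANE = 8

# default soft-crop window: brain parenchyma sits around 0-80 HU
DEFAULT_LO_HU = 0.0
DEFAULT_HI_HU = 80.0
DEFAULT_SOFTNESS_HU = 20.0


@dataclass
class CTVolume:
    """A 3-D scalar field (Hounsfield units or normalized [0,1] intensity)
    with voxel-to-world affine and subject identity."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("CT volume must be a 3-D array with all dims >= 1")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive on all axes")

    @property
    def spacing(self) -> tuple[float, float, float]:
        return tuple(float(np.linalg.norm(self.affine[:3, i])) for i in range(3))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class RegionVolume:
    """Normalized bounding subvolume for one region of one subject — the
    classifier's input unit.  Values in [0, 1]; in-plane dims >= 8."""

    voxels: np.ndarray
    region: ASPECTSRegion
    subject_id: str
    source_box: BoundingBox

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.min() < 0.0 or self.voxels.max() > 1.0:
            raise ValueError("region volume values must lie in [0, 1]")
        if self.voxels.shape[0] < MIN_INPLANE or self.voxels.shape[1] < MIN_INPLANE:
            raise ValueError(f"in-plane dims must be >= {MIN_INPLANE}")


def soft_intensity_crop(volume: CTVolume, lo: float = DEFAULT_LO_HU,
                        hi: float = DEFAULT_HI_HU,
                        softness: float = DEFAULT_SOFTNESS_HU) -> CTVolume:
    """Smooth monotone HU -> [0, 1] windowing suppressing bone and air.

    Linear on ``[lo, hi]``; half-cosine ramps of width ``softness`` outside
    it.  The ramp amplitude ``a = 2*softness / (pi*(hi-lo) + 4*softness)``
    makes the map C1 at the window edges; the midpoint (lo+hi)/2 maps to
    0.5 by symmetry.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got lo={lo}, hi={hi}")
    if softness < 0:
        raise ValueError("softness must be >= 0")
    v = volume.voxels
    if softness == 0:
        out = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    else:
        a = 2.0 * softness / (np.pi * (hi - lo) + 4.0 * softness)
        slope = (1.0 - 2.0 * a) / (hi - lo)
        out = np.empty_like(v)
        below = v <= lo
        above = v >= hi
        mid = ~below & ~above
        out[mid] = a + slope * (v[mid] - lo)
        t = np.clip(v[below], lo - softness, lo)
        out[below] = a * (1.0 + np.sin(np.pi * (t - lo) / (2.0 * softness)))
        t = np.clip(v[above], hi, hi + softness)
        out[above] = 1.0 - a * (1.0 - np.sin(np.pi * (t - hi) / (2.0 * softness)))
    return CTVolume(voxels=out, affine=volume.affine.copy(), subject_id=volume.subject_id)


def map_atlas_to_subject(atlas: RegionAtlas, transform: np.ndarray | None,
                         target: CTVolume) -> np.ndarray:
    """Resample the atlas labels onto the subject grid (nearest neighbour).

    ``transform`` is either a 4x4 affine mapping template world
    coordinates to subject world coordinates (``None`` = identity), or a
    precomputed dense deformation: an array of shape ``target.shape +
    (3,)`` giving, for every subject voxel, the corresponding *template
    voxel* coordinate (the output of an external registration tool).
    Labels are pulled with order-0 interpolation, so the resampled label
    set is a subset of the atlas label set.
    """
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=np.float64)
    if transform.ndim == 4:
        if transform.shape != target.shape + (3,):
            raise ValueError(f"deformation field must have shape {target.shape + (3,)}, "
                             f"got {transform.shape}")
        coords = np.moveaxis(transform, -1, 0)
        return ndimage.map_coordinates(atlas.labels, coords, order=0,
                                       mode="constant", cval=0,
                                       output=atlas.labels.dtype)
    if transform.shape != (4, 4):
        raise ValueError(f"transform must be a 4x4 affine, got shape {transform.shape}")
    vox2vox = np.linalg.inv(atlas.affine) @ np.linalg.inv(transform) @ target.affine
    if np.allclose(vox2vox, np.eye(4)) and atlas.labels.shape == target.shape:
        return atlas.labels.copy()
    out = ndimage.affine_transform(
        atlas.labels, vox2vox[:3, :3], offset=vox2vox[:3, 3],
        output_shape=target.shape, order=0, mode="constant", cval=0,
        output=atlas.labels.dtype)
    return out


def _pad_box_to_min(box: BoundingBox, shape: tuple[int, int, int]) -> BoundingBox:
    """Grow the in-plane extent of ``box`` to at least MIN_INPLANE, staying
    inside the volume where possible."""
    lo, hi = list(box.lo), list(box.hi)
    for ax in (0, 1):
        while hi[ax] - lo[ax] < MIN_INPLANE:
            if lo[ax] > 0:
                lo[ax] -= 1
            elif hi[ax] < shape[ax]:
                hi[ax] += 1
            else:
                break
    return BoundingBox(tuple(lo), tuple(hi))


def extract_region_volumes(volume: CTVolume, subject_labels: np.ndarray,
                           atlas: RegionAtlas, margin_vox: int = 1
                           ) -> tuple[list[RegionVolume], list[ASPECTSRegion]]:
    """Crop one normalized bounding subvolume per region present in
    ``subject_labels``.

    Returns ``(region_volumes, missing)`` where ``missing`` lists atlas
    regions whose mask is empty in subject space (recorded, never silently
    skipped).  Crops touching the volume edge are clipped; in-plane dims
    are grown to >= 8 within the volume, with edge-replication padding as a
    last resort for volumes smaller than 8 in-plane.
    """
    subject_labels = np.asarray(subject_labels)
    if subject_labels.shape != volume.shape:
        raise ValueError(f"label grid {subject_labels.shape} does not match "
                         f"volume grid {volume.shape}")
    out: list[RegionVolume] = []
    missing: list[ASPECTSRegion] = []
    for region in atlas.regions:
        mask = region_mask(atlas, region, labels=subject_labels)
        if not mask.any():
            missing.append(region)
            continue
        box = _pad_box_to_min(bounding_box(mask, margin_vox), volume.shape)
        crop = volume.voxels[box.slices]
        if crop.shape[0] < MIN_INPLANE or crop.shape[1] < MIN_INPLANE:
            pad = [(0, max(0, MIN_INPLANE - crop.shape[0])),
                   (0, max(0, MIN_INPLANE - crop.shape[1])), (0, 0)]
            crop = np.pad(crop, pad, mode="edge")
        out.append(RegionVolume(voxels=crop, region=region,
                                subject_id=volume.subject_id, source_box=box))
    return out, missing


# -- I/O helpers -----------------------------------------------------------

def load_volume(path, subject_id: str | None = None) -> CTVolume:
    """Read a NIfTI volume."""
    path = Path(path)
    img = nib.load(path)
    sid = subject_id if subject_id is not None else path.name.split(".")[0]
    return CTVolume(voxels=np.asarray(img.dataobj, dtype=np.float64),
                    affine=img.affine, subject_id=sid)


def save_volume(volume: CTVolume, path) -> None:
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), volume.affine), Path(path))


def load_dicom_series(directory, subject_id: str = "") -> CTVolume:
    """Assemble an axial DICOM series into a CTVolume (slices sorted by
    ImagePositionPatient along the normal; rescale slope/intercept applied)."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    slices = [pydicom.dcmread(str(f)) for f in files if f.is_file()]
    if not slices:
        raise ValueError(f"no DICOM files found in {directory}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    data = np.stack([s.pixel_array.astype(np.float64) * float(getattr(s, "RescaleSlope", 1.0))
                     + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices], axis=-1)
    first = slices[0]
    dr, dc = (float(x) for x in first.PixelSpacing)
    if len(slices) > 1:
        dz = abs(float(slices[1].ImagePositionPatient[2]) - float(first.ImagePositionPatient[2]))
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    affine = np.diag([dr, dc, dz, 1.0])
    affine[:3, 3] = [float(x) for x in first.ImagePositionPatient]
    return CTVolume(voxels=data, affine=affine,
                    subject_id=subject_id or str(getattr(first, "PatientID", "")))
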