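"""Synthetic non-contrast head CT phantoms with an ASPECTS region atlas.

The generator builds an ellipsoidal "brain" in Hounsfield units — white
matter ~30 HU, a cortical gray-matter shell ~38 HU, a small central CSF
compartment ~8 HU, a skull shell ~700 HU, air at -1000 HU, independent
Gaussian voxel noise — and partitions it into the 10 mirrored ASPECTS
region pairs: deep structures (caudate, putamen, internal capsule,
insula) and cortical M1-M3 at the ganglionic slice level, M4-M6 at the
supraganglionic level.  Ischemic lesions are inserted as a uniform
*negative* HU shift over chosen region masks; the default shift of -8 HU
keeps the hypoattenuation subtle, as early infarcts are on real NCCT.

Annotations (region-level, slice-level, true ASPECTS) are derived from
the inserted masks, so they are consistent by construction: a region is
annotated infarcted iff a lesion was physically inserted there, and a
slice is annotated lesioned iff the inserted lesion intersects it in that
hemisphere.  A zero HU shift inserts nothing and therefore yields empty
annotations; the *assigned* regions of each cohort subject are kept
separately in the manifest so that label-randomization controls (signal-
free features vs. nominal labels) remain constructible.

The default grid is 64 x 64 x 16 voxels at 1 x 1 x 5 mm — thick axial
slices, matching routine acute-stroke NCCT.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ASPECTSRegion, REGION_NAMES, RegionAtlas, all_regions
from .preprocess import CTVolume
from .scoring import ASPECTSResult, compute_aspects
from .training import RegionAnnotation, SliceAnnotation

__all__ = ["PhantomSpec", "PhantomSubject", "PhantomCohort", "TISSUE_HU",
           "make_atlas", "tissue_template", "generate_subject", "generate_cohort",
           "midline_hemisphere_mask", "default_region_count_pmf"]

#: textbook CT attenuation per tissue class (HU)
TISSUE_HU = {"air": -1000.0, "white": 30.0, "gray": 38.0, "csf": 8.0, "skull": 700.0}

_TISSUE_CODE = {"air": 0, "white": 1, "gray": 2, "csf": 3, "skull": 4}

# fractional (x, y, z) centers and radii of the left-hemisphere regions;
# ganglionic level at z ~ 1/3, supraganglionic at z ~ 0.7
_REGION_GEOMETRY = {
    "caudate": ((0.40, 0.56, 0.33), (0.047, 0.047, 0.105)),
    "putamen": ((0.34, 0.53, 0.33), (0.047, 0.047, 0.105)),
    "internal_capsule": ((0.375, 0.45, 0.33), (0.040, 0.047, 0.105)),
    "insula": ((0.28, 0.50, 0.33), (0.040, 0.047, 0.105)),
    "M1": ((0.19, 0.63, 0.33), (0.047, 0.055, 0.105)),
    "M2": ((0.16, 0.47, 0.33), (0.047, 0.055, 0.105)),
    "M3": ((0.20, 0.31, 0.33), (0.047, 0.055, 0.105)),
    "M4": ((0.22, 0.63, 0.70), (0.047, 0.055, 0.105)),
    "M5": ((0.17, 0.47, 0.70), (0.047, 0.055, 0.105)),
    "M6": ((0.22, 0.31, 0.70), (0.047, 0.055, 0.105)),
}

_MIN_DIMS = (32, 32, 8)
_BRAIN_SEMI = (0.41, 0.44, 0.41)   # fractional semi-axes of the brain ellipsoid
_CORTEX_RHO = 0.85                 # normalized radius beyond which tissue is gray
_SKULL_RHO = (0.98, 1.12)
_CSF_GEOMETRY = ((0.50, 0.44, 0.33), (0.030, 0.080, 0.105))


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of one synthetic subject; defaults are the study
    conditions the rest of the package is exercised under."""

    dims: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    tissue_hu: dict = field(default_factory=lambda: dict(TISSUE_HU))
    noise_sd: float = 2.0
    lesion_delta_hu: float = -8.0
    lesion_regions: tuple[ASPECTSRegion, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.lesion_delta_hu > 0:
            raise ValueError("lesion_delta_hu must be <= 0: ischemia is hypodense on NCCT")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(d < m for d, m in zip(self.dims, _MIN_DIMS)):
            raise ValueError(f"dims must be at least {_MIN_DIMS} to host 20 disjoint regions")


def _ellipsoid(shape, center_frac, radii_frac) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    rho2 = np.zeros(shape)
    for ax in range(3):
        c = center_frac[ax] * (shape[ax] - 1)
        r = max(radii_frac[ax] * shape[ax], 1e-9)
        rho2 += ((idx[ax] - c) / r) ** 2
    return rho2


def midline_hemisphere_mask(shape, hemisphere: str) -> np.ndarray:
    """Midline-split helper for synthetic construction only (clinical
    atlases carry hemisphere in the label table instead)."""
    x = np.arange(shape[0])
    half = (x < shape[0] / 2.0) if hemisphere == "left" else (x >= shape[0] / 2.0)
    return np.broadcast_to(half[:, None, None], shape).copy()


def _brain_rho2(dims) -> np.ndarray:
    return _ellipsoid(dims, (0.5, 0.5, 0.5), _BRAIN_SEMI)


def tissue_template(dims=(64, 64, 16)) -> np.ndarray:
    """Integer tissue class map (0 air, 1 white, 2 gray, 3 csf, 4 skull)."""
    rho2 = _brain_rho2(dims)
    tissue = np.zeros(dims, dtype=np.int8)
    brain = rho2 <= 1.0
    tissue[brain] = _TISSUE_CODE["white"]
    tissue[brain & (rho2 > _CORTEX_RHO ** 2)] = _TISSUE_CODE["gray"]
    tissue[(rho2 > _SKULL_RHO[0] ** 2) & (rho2 <= _SKULL_RHO[1] ** 2)] = _TISSUE_CODE["skull"]
    csf = _ellipsoid(dims, *_CSF_GEOMETRY) <= 1.0
    tissue[csf & brain] = _TISSUE_CODE["csf"]
    return tissue


def make_atlas(dims=(64, 64, 16), spacing=(1.0, 1.0, 5.0)) -> RegionAtlas:
    """Build the mirrored 20-region synthetic atlas.

    Left-hemisphere regions are carved as ellipsoids (earlier regions take
    precedence where two ellipsoids touch, keeping the partition disjoint);
    the right hemisphere is the exact mirror image, so homologous voxel
    counts are equal by construction.
    """
    if any(d < m for d, m in zip(dims, _MIN_DIMS)):
        raise ValueError(f"dims must be at least {_MIN_DIMS}, got {dims}")
    brain = _brain_rho2(dims) <= 1.0
    left_half = midline_hemisphere_mask(dims, "left")
    labels_left = np.zeros(dims, dtype=np.int16)
    for li, name in enumerate(REGION_NAMES, start=1):
        center, radii = _REGION_GEOMETRY[name]
        mask = (_ellipsoid(dims, center, radii) <= 1.0) & brain & left_half
        mask &= labels_left == 0
        if not mask.any():
            raise ValueError(f"region {name} came out empty at dims {dims}")
        labels_left[mask] = li
    labels_right = labels_left[::-1].copy()
    labels_right[labels_right > 0] += len(REGION_NAMES)
    labels = labels_left + labels_right
    label_map = {}
    for li, name in enumerate(REGION_NAMES, start=1):
        label_map[li] = ASPECTSRegion(name, "left")
        label_map[li + len(REGION_NAMES)] = ASPECTSRegion(name, "right")
    affine = np.diag([*spacing, 1.0])
    return RegionAtlas(labels=labels, label_map=label_map, affine=affine)


@dataclass
class PhantomSubject:
    """One synthetic subject with its ground truth."""

    volume: CTVolume
    labels: np.ndarray                       # subject-space region labels
    lesion_regions: tuple[ASPECTSRegion, ...]    # physically inserted
    assigned_regions: tuple[ASPECTSRegion, ...]  # intended (== inserted unless delta 0)
    region_annotations: list[RegionAnnotation]
    slice_annotations: list[SliceAnnotation]
    true_aspects: ASPECTSResult

    @property
    def subject_id(self) -> str:
        return self.volume.subject_id


def _slice_annotations(atlas: RegionAtlas, lesioned: tuple[ASPECTSRegion, ...],
                       subject_id: str) -> list[SliceAnnotation]:
    dims = atlas.labels.shape
    brain = _brain_rho2(dims) <= 1.0
    lesion_mask = np.isin(atlas.labels, [atlas.label_of(r) for r in lesioned]) \
        if lesioned else np.zeros(dims, dtype=bool)
    out = []
    for z in range(dims[2]):
        if not brain[:, :, z].any():
            continue
        for hemi in ("left", "right"):
            half = midline_hemisphere_mask(dims, hemi)[:, :, z]
            label = "lesion" if (lesion_mask[:, :, z] & half).any() else "normal"
            out.append(SliceAnnotation(subject_id=subject_id, slice_index=z,
                                       hemisphere=hemi, label=label))
    return out


def generate_subject(spec: PhantomSpec, atlas: RegionAtlas | None = None,
                     subject_id: str = "phantom-000") -> PhantomSubject:
    """Draw one phantom: tissue means + Gaussian noise, then the lesion
    shift applied over the requested region masks.

    The noise field depends only on the seed, never on the lesion set, so
    a lesioned draw differs from the lesion-free draw at the same seed by
    exactly ``lesion_delta_hu`` inside the lesion mask.
    """
    if atlas is None:
        atlas = make_atlas(spec.dims, spec.spacing)
    if atlas.labels.shape != spec.dims:
        raise ValueError("atlas grid does not match spec dims")
    unknown = [r for r in spec.lesion_regions if r not in atlas.regions]
    if unknown:
        raise ValueError(f"lesion regions not in atlas: {unknown}")
    rng = np.random.default_rng(spec.seed)
    tissue = tissue_template(spec.dims)
    means = np.array([spec.tissue_hu[k] for k in
                      ("air", "white", "gray", "csf", "skull")])
    hu = means[tissue] + rng.normal(0.0, spec.noise_sd, size=spec.dims)
    inserted: tuple[ASPECTSRegion, ...] = ()
    if spec.lesion_delta_hu != 0.0 and spec.lesion_regions:
        inserted = tuple(spec.lesion_regions)
        mask = np.isin(atlas.labels, [atlas.label_of(r) for r in inserted])
        hu[mask] += spec.lesion_delta_hu
    volume = CTVolume(voxels=hu, affine=np.diag([*spec.spacing, 1.0]),
                      subject_id=subject_id)
    region_ann = [RegionAnnotation(subject_id=subject_id, region=r,
                                   label="infarcted" if r in inserted else "normal")
                  for r in all_regions()]
    slice_ann = _slice_annotations(atlas, inserted, subject_id)
    truth = compute_aspects({r: r in inserted for r in all_regions()})
    return PhantomSubject(volume=volume, labels=atlas.labels.copy(),
                          lesion_regions=inserted,
                          assigned_regions=tuple(spec.lesion_regions),
                          region_annotations=region_ann, slice_annotations=slice_ann,
                          true_aspects=truth)


def default_region_count_pmf() -> np.ndarray:
    """Probability of k affected regions (k = 1..10) for a stroke subject:
    a truncated geometric favoring small lesion loads while keeping
    enough mass at k >= 5 to exercise the dichotomy cutoff."""
    w = 0.75 ** np.arange(1, 11)
    return w / w.sum()


@dataclass
class PhantomCohort:
    atlas: RegionAtlas
    subjects: list[PhantomSubject]
    manifest: pd.DataFrame
    spec: PhantomSpec
    seed: int

    def __len__(self) -> int:
        return len(self.subjects)


def generate_cohort(n_subjects: int, stroke_prevalence: float = 0.622,
                    region_count_pmf: np.ndarray | None = None,
                    spec: PhantomSpec | None = None, seed: int = 0) -> PhantomCohort:
    """Generate a cohort: each subject is a stroke subject with probability
    ``stroke_prevalence``; stroke subjects receive k affected regions in
    one randomly chosen hemisphere, k drawn from ``region_count_pmf``.

    The default prevalence emulates an acute-stroke test cohort in which
    62.2% of suspected-stroke scans show infarction.
    """
    if not 0.0 <= stroke_prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    spec = spec or PhantomSpec()
    pmf = default_region_count_pmf() if region_count_pmf is None else np.asarray(region_count_pmf)
    if pmf.size != 10 or abs(pmf.sum() - 1.0) > 1e-9 or (pmf < 0).any():
        raise ValueError("region_count_pmf must be 10 nonnegative probabilities summing to 1")
    rng = np.random.default_rng(seed)
    atlas = make_atlas(spec.dims, spec.spacing)
    subjects, rows = [], []
    for i in range(n_subjects):
        sid = f"phantom-{i:03d}"
        is_stroke = bool(rng.random() < stroke_prevalence)
        regions: tuple[ASPECTSRegion, ...] = ()
        hemi = ""
        if is_stroke:
            hemi = "left" if rng.random() < 0.5 else "right"
            k = int(rng.choice(np.arange(1, 11), p=pmf))
            names = rng.choice(len(REGION_NAMES), size=k, replace=False)
            regions = tuple(ASPECTSRegion(REGION_NAMES[j], hemi) for j in sorted(names))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = generate_subject(replace(spec, lesion_regions=regions, seed=sub_seed),
                               atlas=atlas, subject_id=sid)
        subjects.append(sub)
        rows.append({"subject_id": sid, "is_stroke": is_stroke, "hemisphere": hemi,
                     "n_regions": len(regions),
                     "assigned_regions": ";".join(str(r) for r in regions),
                     "true_left": sub.true_aspects.left_score,
                     "true_right": sub.true_aspects.right_score,
                     "true_reported": sub.true_aspects.reported_score,
                     "true_category": sub.true_aspects.category,
                     "seed": sub_seed})
    return PhantomCohort(atlas=atlas, subjects=subjects,
                         manifest=pd.DataFrame(rows), spec=spec, seed=seed)
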