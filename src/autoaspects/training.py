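"""Two-step training of the region classifier.

Step 1 (*pre-training*) trains the slice encoder through a per-slice
classification head on slice-level labels; to avoid equivocal supervision,
every normal slice ipsilateral to any lesion slice of the same subject is
excluded.  Step 2 (*fine-tuning*) initializes the encoder from step 1 and
trains the entire region-level model on region annotations.

Both steps use Adam on binary cross-entropy, batch size 50, initial
learning rate 5e-4 decayed exponentially by 0.99 per epoch (applied at
epoch boundaries), for 200 epochs at full scale.  Data augmentation is
strictly in-plane — random rotation (+-15 deg), translation (+-2% of the
axis length) and scaling (+-10%), the same transform applied to every
slice of a volume; the through-plane axis is never transformed because of
the coarse slice spacing.  Per-epoch learning rate, loss and accuracy are
recorded so a training-curve plot can be produced from the log alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import Adam, bce_with_logits, sigmoid
from .atlas import ASPECTSRegion
from .model import AspectsNet, SliceHead

__all__ = ["TrainConfig", "SliceAnnotation", "RegionAnnotation",
           "build_pretrain_set", "lr_schedule", "augment",
           "sample_augmentation", "apply_inplane_transform",
           "pretrain", "finetune",
           "slice_annotations_from_csv", "region_annotations_from_csv"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and augmentation settings (defaults = full protocol)."""

    epochs: int = 200
    batch_size: int = 50
    lr0: float = 5e-4
    lr_decay_per_epoch: float = 0.99
    rot_deg_xy: float = 15.0
    trans_frac_xy: float = 0.02
    scale_frac_xy: float = 0.10
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if min(self.rot_deg_xy, self.trans_frac_xy, self.scale_frac_xy) < 0:
            raise ValueError("augmentation ranges are half-widths and must be >= 0")
        if not 0 < self.lr_decay_per_epoch <= 1:
            raise ValueError("lr decay must be in (0, 1]")


@dataclass(frozen=True)
class SliceAnnotation:
    """Slice-level label: slice_index is 0-based, inferior to superior."""

    subject_id: str
    slice_index: int
    hemisphere: str
    label: str  # "lesion" or "normal"

    def __post_init__(self):
        if self.label not in ("lesion", "normal"):
            raise ValueError(f"slice label must be 'lesion' or 'normal', got {self.label!r}")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"bad hemisphere {self.hemisphere!r}")


@dataclass(frozen=True)
class RegionAnnotation:
    subject_id: str
    region: ASPECTSRegion
    label: str  # "infarcted" or "normal"

    def __post_init__(self):
        if self.label not in ("infarcted", "normal"):
            raise ValueError(f"region label must be 'infarcted' or 'normal', got {self.label!r}")


def slice_annotations_from_csv(path) -> list[SliceAnnotation]:
    """Read slice annotations from a CSV with headers
    ``subject_id, slice_index, hemisphere, label``."""
    df = pd.read_csv(path)
    return [SliceAnnotation(subject_id=str(r.subject_id), slice_index=int(r.slice_index),
                            hemisphere=str(r.hemisphere), label=str(r.label))
            for r in df.itertuples()]


def region_annotations_from_csv(path) -> list[RegionAnnotation]:
    """Read region annotations from a CSV with headers
    ``subject_id, region, label`` (region as ``hemisphere_name``)."""
    df = pd.read_csv(path)
    return [RegionAnnotation(subject_id=str(r.subject_id),
                             region=ASPECTSRegion.parse(str(r.region)),
                             label=str(r.label))
            for r in df.itertuples()]


def build_pretrain_set(annotations: Sequence[SliceAnnotation],
                       known_subjects: Iterable[str] | None = None
                       ) -> list[SliceAnnotation]:
    """Apply the ipsilateral-exclusion rule to slice annotations.

    Keeps every lesion slice, and normal slices only from hemispheres in
    which the same subject has no lesion slice; normal slices sharing a
    hemisphere with a lesion are dropped as equivocal.
    """
    if known_subjects is not None:
        known = set(known_subjects)
        for a in annotations:
            if a.subject_id not in known:
                raise ValueError(f"annotation references unknown subject {a.subject_id!r}")
    lesioned: set[tuple[str, str]] = {(a.subject_id, a.hemisphere)
                                      for a in annotations if a.label == "lesion"}
    return [a for a in annotations
            if a.label == "lesion" or (a.subject_id, a.hemisphere) not in lesioned]


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Exponentially decayed learning rate: ``lr0 * decay**epoch``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.lr0 * cfg.lr_decay_per_epoch ** epoch


# -- in-plane augmentation -------------------------------------------------

def sample_augmentation(rng: np.random.Generator, cfg: TrainConfig) -> dict:
    """Draw one in-plane transform: scale, then rotation, then translation
    (all uniform over their symmetric ranges)."""
    return {
        "scale": (1.0 + rng.uniform(-cfg.scale_frac_xy, cfg.scale_frac_xy),
                  1.0 + rng.uniform(-cfg.scale_frac_xy, cfg.scale_frac_xy)),
        "rot_deg": rng.uniform(-cfg.rot_deg_xy, cfg.rot_deg_xy),
        "trans_frac": (rng.uniform(-cfg.trans_frac_xy, cfg.trans_frac_xy),
                       rng.uniform(-cfg.trans_frac_xy, cfg.trans_frac_xy)),
    }


def inplane_matrix(params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Forward 2x2 linear map (rotate @ scale) and its inverse."""
    sx, sy = params["scale"]
    th = np.deg2rad(params["rot_deg"])
    r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t2 = r @ np.diag([sx, sy])
    return t2, np.linalg.inv(t2)


def apply_inplane_transform(vol: np.ndarray, params: dict) -> np.ndarray:
    """Apply one in-plane affine to every slice of ``(H, W, Z)`` identically
    (bilinear, nearest-edge padding), clamping to [0, 1]."""
    vol = np.asarray(vol, dtype=np.float64)
    h, w = vol.shape[:2]
    if h <= 1 and w <= 1:
        return vol.copy()
    t2, t2inv = inplane_matrix(params)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    trans = np.array([params["trans_frac"][0] * h, params["trans_frac"][1] * w])
    matrix = np.eye(3)
    matrix[:2, :2] = t2inv
    offset = np.zeros(3)
    offset[:2] = center - t2inv @ (center + trans)
    out = ndimage.affine_transform(vol, matrix, offset=offset, order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0)


def augment(vol: np.ndarray, rng: np.random.Generator,
            cfg: TrainConfig | None = None) -> np.ndarray:
    """Randomly augment one ``(H, W, Z)`` volume in-plane; output dims equal
    input dims and the through-plane axis is untouched."""
    cfg = cfg or TrainConfig()
    return apply_inplane_transform(vol, sample_augmentation(rng, cfg))


# -- optimization loops ----------------------------------------------------

def _check_two_classes(labels: np.ndarray, what: str) -> None:
    if labels.all() or not labels.any():
        warnings.warn(f"{what} dataset contains a single class; refusing to train")
        raise ValueError(f"{what} dataset must contain both classes")


def _shape_groups(idx: np.ndarray, shapes: list[tuple]) -> list[np.ndarray]:
    by_shape: dict[tuple, list[int]] = {}
    for i in idx:
        by_shape.setdefault(shapes[i], []).append(i)
    return [np.array(v) for v in by_shape.values()]


def _epoch_log(history: list[dict], epoch: int, lr: float, losses: list[float],
               correct: int, total: int) -> None:
    history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)),
                    "accuracy": correct / total})


def pretrain(model: AspectsNet, slice_head: SliceHead,
             samples: Sequence[np.ndarray], labels: Sequence[int] | np.ndarray,
             cfg: TrainConfig) -> pd.DataFrame:
    """Train encoder + slice head on per-slice labels (binary
    cross-entropy); returns the per-epoch log (epoch, lr, loss, accuracy).

    ``samples`` are single-slice normalized arrays ``(H, W)`` or
    ``(H, W, 1)``; the encoder weights are updated in place, so the main
    model is initialized for fine-tuning when this returns.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if len(samples) == 0:
        raise ValueError("empty pre-training dataset")
    _check_two_classes(labels.astype(bool), "pre-training")
    vols = [np.asarray(s, dtype=np.float64)[..., None] if np.asarray(s).ndim == 2
            else np.asarray(s, dtype=np.float64) for s in samples]
    shapes = [v.shape for v in vols]
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(slice_head.params(), lr=cfg.lr0)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(len(vols))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for grp in _shape_groups(batch, shapes):
                xs = np.stack([augment(vols[i], rng, cfg) if cfg.augment else vols[i]
                               for i in grp])[:, None]
                ys = labels[grp]
                logits = slice_head.forward_logits(xs, training=True)[:, 0]
                loss, dl = bce_with_logits(logits, ys)
                # scale group gradient so the batch mean is optimized
                slice_head.backward((dl * len(grp) / len(batch))[:, None])
                batch_loss += loss * len(grp) / len(batch)
                correct += int(np.sum((sigmoid(logits) >= 0.5) == ys.astype(bool)))
            losses.append(batch_loss)
            opt.step()
        _epoch_log(history, epoch, opt.lr, losses or [np.nan], correct, len(vols))
    return pd.DataFrame(history)


def finetune(model: AspectsNet, samples: Sequence[np.ndarray],
             labels: Sequence[int] | np.ndarray, cfg: TrainConfig,
             *, cold_start: bool = False, pretrained: bool = True) -> pd.DataFrame:
    """Train the full region-level model on region labels.

    The encoder is expected to carry pre-trained weights (run
    :func:`pretrain` on the same model first); pass ``cold_start=True`` to
    deliberately train from random initialization.  Returns the per-epoch
    log.
    """
    if not pretrained and not cold_start:
        raise ValueError("encoder not pre-trained; pass cold_start=True to train from scratch")
    labels = np.asarray(labels, dtype=np.float64)
    if len(samples) == 0:
        raise ValueError("empty fine-tuning dataset")
    _check_two_classes(labels.astype(bool), "fine-tuning")
    vols = [np.asarray(s, dtype=np.float64) for s in samples]
    shapes = [v.shape for v in vols]
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params(), lr=cfg.lr0)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg)
        order = rng.permutation(len(vols))
        losses, correct = [], 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for grp in _shape_groups(batch, shapes):
                xs = np.stack([augment(vols[i], rng, cfg) if cfg.augment else vols[i]
                               for i in grp])[:, None]
                ys = labels[grp]
                logits = model.forward_logits(xs, training=True, rng=rng)
                loss, dl = bce_with_logits(logits, ys)
                model.backward(dl * len(grp) / len(batch))
                batch_loss += loss * len(grp) / len(batch)
                correct += int(np.sum((sigmoid(logits) >= 0.5) == ys.astype(bool)))
            losses.append(batch_loss)
            opt.step()
        _epoch_log(history, epoch, opt.lr, losses or [np.nan], correct, len(vols))
    return pd.DataFrame(history)
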