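"""End-to-end orchestration: cohort -> datasets -> trained model ->
per-subject ASPECTS -> evaluation report.

The evaluation report mirrors the layout of a clinical reader-study
summary: one row per ASPECTS region with sensitivity, specificity,
accuracy, precision, F1, kappa and AUC; a pooled row computed from the
summed per-region confusion matrices; and a dichotomized (>=6 vs <6)
block with sensitivity, specificity, accuracy, F1, ICC and AUC.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ASPECTSRegion, RegionAtlas, all_regions
from .model import AspectsNet, SliceHead, build_model, build_slice_head
from .phantom import PhantomCohort, PhantomSubject, midline_hemisphere_mask, _brain_rho2
from .preprocess import extract_region_volumes, soft_intensity_crop
from .scoring import compute_aspects, dichotomize
from .stats import (ConfusionMatrix, basic_metrics, cohens_kappa, confusion,
                    icc_absolute_agreement, roc_auc, UndefinedMetricError)
from .training import TrainConfig, build_pretrain_set, finetune, pretrain

__all__ = ["region_dataset", "slice_dataset", "train_two_step",
           "run_predict", "run_evaluate"]

REGION_TABLE_COLUMNS = ["Sensitivity", "Specificity", "Accuracy", "Precision",
                        "F1 Score", "Kappa", "AUC"]


def _normalized(subject: PhantomSubject):
    return soft_intensity_crop(subject.volume)


def region_dataset(cohort: PhantomCohort, margin_vox: int = 1,
                   use_assigned: bool = False):
    """Per-region crops and binary labels for the whole cohort.

    Returns ``(samples, labels, subject_ids, regions)`` with one entry per
    (subject, region).  ``use_assigned=True`` labels by the cohort's
    assigned lesion regions instead of the physically inserted ones (the
    label-randomization control for zero-contrast phantoms).
    """
    samples, labels, sids, regions = [], [], [], []
    for sub in cohort.subjects:
        norm = _normalized(sub)
        vols, missing = extract_region_volumes(norm, sub.labels, cohort.atlas,
                                               margin_vox=margin_vox)
        if missing:
            raise ValueError(f"subject {sub.subject_id} missing regions: {missing}")
        positive = set(sub.assigned_regions if use_assigned else sub.lesion_regions)
        for rv in vols:
            samples.append(rv.voxels)
            labels.append(int(rv.region in positive))
            sids.append(sub.subject_id)
            regions.append(rv.region)
    return samples, np.array(labels), np.array(sids), regions


def slice_dataset(cohort: PhantomCohort, use_assigned: bool = False,
                  apply_exclusion: bool = True):
    """Hemisphere half-slices and labels for pre-training.

    Each sample is one axial slice of one hemisphere, cropped to the brain
    bounding box of that hemisphere; the ipsilateral-exclusion rule is
    applied through :func:`autoaspects.training.build_pretrain_set`.
    """
    from .atlas import bounding_box
    from .phantom import _slice_annotations

    dims = cohort.atlas.labels.shape
    brain = _brain_rho2(dims) <= 1.0
    samples, labels = [], []
    for sub in cohort.subjects:
        anns = sub.slice_annotations if not use_assigned else _slice_annotations(
            cohort.atlas, tuple(sub.assigned_regions), sub.subject_id)
        kept = build_pretrain_set(anns) if apply_exclusion else list(anns)
        norm = _normalized(sub)
        for ann in kept:
            half = brain[:, :, ann.slice_index] & \
                midline_hemisphere_mask(dims, ann.hemisphere)[:, :, ann.slice_index]
            box = bounding_box(half[..., None], margin_vox=1)
            sl = norm.voxels[box.slices[0], box.slices[1], ann.slice_index]
            if sl.shape[0] < 8 or sl.shape[1] < 8:
                sl = np.pad(sl, [(0, max(0, 8 - sl.shape[0])),
                                 (0, max(0, 8 - sl.shape[1]))], mode="edge")
            samples.append(sl)
            labels.append(int(ann.label == "lesion"))
    return samples, np.array(labels)


def train_two_step(cohort: PhantomCohort, pretrain_cfg: TrainConfig,
                   finetune_cfg: TrainConfig, model: AspectsNet | None = None,
                   use_assigned: bool = False):
    """Run the full two-step protocol on a cohort.

    Returns ``(model, pretrain_log, finetune_log)``.
    """
    model = model or build_model()
    head = build_slice_head(model)
    s_samples, s_labels = slice_dataset(cohort, use_assigned=use_assigned)
    pre_log = pretrain(model, head, s_samples, s_labels, pretrain_cfg)
    r_samples, r_labels, _, _ = region_dataset(cohort, use_assigned=use_assigned)
    fin_log = finetune(model, r_samples, r_labels, finetune_cfg)
    return model, pre_log, fin_log


def run_predict(model: AspectsNet, cohort: PhantomCohort,
                threshold: float | None = None) -> pd.DataFrame:
    """Score every subject: per-region probabilities -> decisions ->
    hemisphere and reported ASPECTS.  One row per subject; per-subject
    wall-clock seconds are logged in the ``seconds`` column."""
    thr = model.config.threshold if threshold is None else threshold
    rows = []
    for sub in cohort.subjects:
        t0 = time.perf_counter()
        norm = _normalized(sub)
        vols, missing = extract_region_volumes(norm, sub.labels, cohort.atlas)
        if missing:
            raise ValueError(f"subject {sub.subject_id} missing region volumes: "
                             f"{[str(m) for m in missing]}")
        probs = {rv.region: float(model.forward(rv.voxels[None, None])[0]) for rv in vols}
        decisions = {r: probs[r] >= thr for r in all_regions()}
        result = compute_aspects(decisions)
        row = {"subject_id": sub.subject_id,
               "left_score": result.left_score, "right_score": result.right_score,
               "reported_score": result.reported_score, "category": result.category,
               "seconds": time.perf_counter() - t0}
        for r in all_regions():
            row[f"p_{r}"] = probs[r]
            row[f"d_{r}"] = bool(decisions[r])
        rows.append(row)
    return pd.DataFrame(rows)


def _truth_frame(cohort: PhantomCohort) -> pd.DataFrame:
    rows = []
    for sub in cohort.subjects:
        row = {"subject_id": sub.subject_id,
               "reported_score": sub.true_aspects.reported_score,
               "category": sub.true_aspects.category}
        for r in all_regions():
            row[f"d_{r}"] = r in sub.lesion_regions
        rows.append(row)
    return pd.DataFrame(rows)


def run_evaluate(results: pd.DataFrame, cohort: PhantomCohort) -> dict:
    """Compare predicted ASPECTS against cohort ground truth.

    Returns ``{"per_region": DataFrame, "pooled": Series, "dichotomized":
    Series}``; pooled metrics are computed from the summed per-region
    confusion matrices.  Metrics whose denominator is empty (e.g. AUC for
    a region never infarcted in the cohort) come back as NaN.
    """
    truth = _truth_frame(cohort)
    orphans = set(results["subject_id"]) ^ set(truth["subject_id"])
    if orphans:
        raise ValueError(f"subject ids do not match between results and truth: {sorted(orphans)}")
    merged = results.merge(truth, on="subject_id", suffixes=("", "_true"))

    def metric_row(cm: ConfusionMatrix, scores=None, labels=None) -> dict:
        m = basic_metrics(cm)
        row = {"Sensitivity": m["sensitivity"], "Specificity": m["specificity"],
               "Accuracy": m["accuracy"], "Precision": m["precision"], "F1 Score": m["f1"]}
        try:
            row["Kappa"] = cohens_kappa(cm)
        except UndefinedMetricError:
            row["Kappa"] = np.nan
        if scores is not None and labels is not None and 0 < np.sum(labels) < len(labels):
            row["AUC"] = roc_auc(scores, labels)["auc"]
        else:
            row["AUC"] = np.nan
        return {k: (np.nan if v is None else v) for k, v in row.items()}

    per_region_rows = {}
    pooled_cm = ConfusionMatrix(0, 0, 0, 0)
    region_names_seen = []
    for name in [r.name for r in all_regions()[:10]]:
        pred = np.concatenate([merged[f"d_{h}_{name}"].to_numpy(dtype=bool)
                               for h in ("left", "right")])
        tru = np.concatenate([merged[f"d_{h}_{name}_true"].to_numpy(dtype=bool)
                              for h in ("left", "right")])
        scores = np.concatenate([merged[f"p_{h}_{name}"].to_numpy(dtype=float)
                                 for h in ("left", "right")])
        cm = confusion(pred, tru)
        pooled_cm = pooled_cm + cm
        per_region_rows[name] = metric_row(cm, scores, tru)
        region_names_seen.append(name)
    per_region = pd.DataFrame(per_region_rows).T[REGION_TABLE_COLUMNS]

    all_pred = np.concatenate([merged[f"d_{r}"].to_numpy(dtype=bool) for r in all_regions()])
    all_true = np.concatenate([merged[f"d_{r}_true"].to_numpy(dtype=bool)
                               for r in all_regions()])
    all_scores = np.concatenate([merged[f"p_{r}"].to_numpy(dtype=float)
                                 for r in all_regions()])
    pooled = pd.Series(metric_row(pooled_cm, all_scores, all_true))

    # dichotomized block: positive class = severe stroke (score < 6)
    pred_pos = merged["category"] == "<6"
    true_pos = merged["category_true"] == "<6"
    cm = confusion(pred_pos.to_numpy(), true_pos.to_numpy())
    dich = metric_row(cm, -merged["reported_score"].to_numpy(dtype=float),
                      true_pos.to_numpy())
    del dich["Precision"], dich["Kappa"]
    ratings = np.column_stack([merged["reported_score"].to_numpy(dtype=float),
                               merged["reported_score_true"].to_numpy(dtype=float)])
    try:
        dich["ICC"] = icc_absolute_agreement(ratings)
    except (UndefinedMetricError, ValueError):
        dich["ICC"] = np.nan
    dichotomized = pd.Series(dich)[["Sensitivity", "Specificity", "Accuracy",
                                    "F1 Score", "ICC", "AUC"]]
    return {"per_region": per_region, "pooled": pooled, "dichotomized": dichotomized}
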