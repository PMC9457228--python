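# autoaspects

Automated ASPECTS scoring of non-contrast head CT (NCCT), with the full
reader-study evaluation toolbox and a synthetic phantom generator that
makes the whole pipeline testable without clinical data.

## The problem

The Alberta Stroke Program Early CT Score (ASPECTS) grades acute ischemic
stroke severity in the anterior circulation: each hemisphere starts at 10
and loses one point per affected territory (caudate, putamen, internal
capsule, insula, and the MCA cortical territories M1–M6). A score ≥ 6 is
a common eligibility cutoff for intra-arterial thrombectomy. Early
ischemia appears on NCCT only as subtle hypoattenuation, so manual
scoring is slow and reader-dependent — the motivation for an automated
reader that front-line physicians can consult.

## What the package does

1. **Atlas-based region extraction** (`autoaspects.atlas`,
   `autoaspects.preprocess`) — a template-space integer label atlas maps
   voxels to the 20 (region, hemisphere) territories; NCCT volumes are
   windowed onto [0, 1] by *soft intensity cropping* (linear on [0, 80] HU
   with C¹ half-cosine ramps) and cropped to per-region bounding
   subvolumes. Registration itself is external: the module consumes an
   affine (or identity, for phantoms).
2. **A 2.5-D CNN classifier** (`autoaspects.model`) — a 7-layer per-slice
   encoder (3×3×1 kernels, channels 8-8-16-16-32-32-32, three stride-2
   layers), adaptive max pooling to 4×4×20, a 16-channel 1×1×20 slice
   aggregator, and a fully connected classifier head with dropout 0.5 and
   a sigmoid output: P(region infarcted). 45,801 trainable parameters,
   implemented in NumPy with explicit backprop.
3. **Two-step training** (`autoaspects.training`) — slice-level
   pre-training of the encoder (normal slices ipsilateral to any lesion
   are excluded as equivocal), then region-level fine-tuning of the whole
   model; Adam, batch 50, lr 5e-4 decaying ×0.99/epoch, in-plane-only
   augmentation (±15° rotation, ±2% translation, ±10% scaling — never
   along Z).
4. **Scoring** (`autoaspects.scoring`) — 20 decisions → hemisphere scores
   → reported score (minimum of the two) → dichotomized ≥6 / <6 category.
5. **Evaluation statistics** (`autoaspects.stats`) — sensitivity/
   specificity/accuracy/precision/F1, Cohen's kappa, ICC(2,1), ROC/AUC,
   a paired one-tailed permutation test for assisted-vs-unassisted reader
   performance, and `reconstruct_confusion`, which recovers the exact
   integer confusion matrix behind a printed metrics row by exhaustive
   search.
6. **Phantoms** (`autoaspects.phantom`) — seeded synthetic head CTs
   (gray/white/CSF/skull/air in HU, Gaussian noise, hypodense lesions
   inserted into chosen territories) with fully consistent ground-truth
   annotations.

## Worked example

```python
import numpy as np
from autoaspects import (PhantomSpec, generate_cohort, TrainConfig,
                         train_two_step, run_predict, run_evaluate)

cohort = generate_cohort(20, stroke_prevalence=0.7,
                         spec=PhantomSpec(lesion_delta_hu=-30.0), seed=7)
model, pre_log, fin_log = train_two_step(
    cohort, TrainConfig(epochs=3, seed=0), TrainConfig(epochs=12, seed=0))
results = run_predict(model, cohort)
print(results[["subject_id", "left_score", "right_score",
               "reported_score", "category"]].head(3))
report = run_evaluate(results, cohort)
print(report["pooled"].round(3))
```

prints (a short training run, evaluated on the training cohort itself):

```
    subject_id  left_score  right_score  reported_score category
0  phantom-000          10            5               5       <6
1  phantom-001          10           10              10      >=6
2  phantom-002           9           10               9      >=6
Sensitivity    0.978
Specificity    1.000
Accuracy       0.998
Precision      1.000
F1 Score       0.989
Kappa          0.988
AUC            1.000
```

One row per subject with both hemisphere scores, the reported (minimum)
score and its dichotomized category; the pooled block is computed from
the summed per-region confusion matrices over all 20 territories, and
the near-perfect values reflect the deliberately strong −30 HU lesion
contrast of this toy cohort and the optimistic train-set evaluation.

The same flow is available from the shell:

```sh
autoaspects generate --n-subjects 20 --seed 7 --out scratch/cohort.pkl
autoaspects train --cohort scratch/cohort.pkl --out scratch/model.ckpt
autoaspects predict --checkpoint scratch/model.ckpt --cohort scratch/cohort.pkl --out scratch/results.csv
autoaspects evaluate --results scratch/results.csv --cohort scratch/cohort.pkl --out scratch/report.json
```

See `examples/` for short narrative scripts, one per capability.

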