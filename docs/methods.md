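# Methods

## Overview

`autoaspects` scores the 10 ASPECTS territories per hemisphere on
non-contrast CT by classifying each region's bounding subvolume with a
2.5-dimensional CNN, then totals the 20 binary decisions into hemisphere
scores, a reported score and the dichotomized ≥6 / <6 category. Around
that core sit the preprocessing chain, the two-step training protocol,
the reader-study statistics, and a synthetic phantom generator that
stands in for clinical data everywhere in the tests.

## Preprocessing

**Soft intensity cropping.** Brain parenchyma spans roughly 0–80 HU while
bone (~700 HU) and air (−1000 HU) dominate the raw dynamic range. The
window map is linear on `[lo, hi] = [0, 80]` HU with half-cosine ramps of
width `softness = 20` HU on both sides; the ramp amplitude
`a = 2s / (π(hi−lo) + 4s)` makes the map C¹, monotone, and exactly 0.5 at
the window midpoint. Values ≤ lo−s map to 0 and ≥ hi+s to 1. The exact
ramp shape is a declared implementation choice — any smooth monotone
window with these properties would serve; all three constants are
arguments. With `softness = 0` the map degenerates to a hard linear
window, which is the identity on already-normalized data and makes the
operation idempotent there.

**Atlas resampling.** Region labels live in template space; a 4×4 affine
(template world → subject world) composed with the two voxel-to-world
matrices pulls labels onto the subject grid with nearest-neighbour
interpolation (label integrity; intensities, when resampled, use
trilinear). Nonlinear registration is deliberately external — the package
accepts its output, it does not compute it. Phantoms use the identity.

**Region crops.** Each region's bounding box (minimal, half-open,
0-based) is expanded by `margin_vox = 1` (minimal context without overlap
explosion) and clipped to the volume; in-plane dims are grown to ≥ 8 —
the minimum the three stride-2 encoder layers require — preferentially by
expanding within the volume, with edge-replication padding as a last
resort. Z is never resampled: thick-slice CT is handled by the
architecture, not the preprocessing.

## The classifier

Input: one region crop, `(H ≥ 8, W ≥ 8, Z ≥ 1)`, values in [0, 1].

- **Slice encoder** — seven 3-D convolutions with 3×3×1 kernels (in-plane
  padding 1, through-plane 0), channels 8, 8, 16, 16, 32, 32, 32,
  in-plane strides 1, 2, 1, 2, 1, 1, 2, ReLU after each. The ×1
  through-plane extent makes every layer an independent 2-D convolution
  per slice.
- **Aggregator** — adaptive max pooling to a fixed 4×4×20 grid (inputs
  with fewer than 20 slices are handled by the overlapping-bin semantics
  of adaptive pooling, so any Z ≥ 1 is legal), then a 16-channel 1×1×20
  convolution collapsing the slice axis.
- **Classifier** — a 32-channel 4×4×1 convolution (a fully connected map
  over the pooled grid), ReLU, dropout 0.5, a 1-channel 1×1×1 convolution
  and a sigmoid.

Total: 45,801 trainable parameters (encoder 80 + 584 + 1,168 + 2,320 +
4,640 + 9,248 + 9,248; aggregator 10,256; classifier 8,224 + 33). The
decision threshold defaults to 0.5 and is configurable.

A **slice-level head** for pre-training shares the encoder: global
in-plane max pooling of the 32-channel slice features, then 32→32 ReLU →
32→1 sigmoid per slice. Its two-layer shape is a declared choice; only
the encoder's weights carry over to fine-tuning (by object identity, so
"initialization from pre-training" is automatic).

The network, backpropagation and Adam are implemented directly in NumPy
(float64): strided im2col convolutions with explicit col2im backward,
argmax-routed pooling gradients, inverted dropout. The backward pass is
verified against central finite differences in the test suite.
Initialization is Kaiming-uniform for weights, zeros for biases, seeded
per construction.

## Training protocol

Binary cross-entropy for both steps (canonical for sigmoid outputs; the
protocol names only the optimizer). Adam with conventional β/ε; batch
size 50; initial lr 5e-4 with exponential decay ×0.99 applied at epoch
boundaries; 200 epochs at full scale. Per-epoch lr, loss and accuracy are
logged as a DataFrame/CSV, sufficient to reproduce a training-curve plot.

**Ipsilateral exclusion.** Pre-training labels are per slice per
hemisphere. Every normal slice sharing a hemisphere with any lesion slice
of the same subject is excluded (equivocal supervision); lesion slices
are always kept. The rule is verified by exhaustive enumeration of label
patterns.

**Augmentation.** Strictly in-plane: per sample one transform —
scale ~ U(0.9, 1.1) per axis, rotation ~ U(−15°, 15°), translation
~ U(−2%, 2%) of the axis length — composed scale → rotate → translate
about the in-plane center, bilinear resampling, nearest-edge padding,
output clamped to [0, 1]. Every slice of a volume receives the identical
transform; there are no through-plane parameters at all, reflecting the
poor inter-slice resolution of 5 mm acquisitions.

Determinism: all randomness flows through one seeded
`numpy.random.Generator` per run; with a fixed seed and a fixed BLAS the
loss curves are bit-identical across runs on one platform.

## Scoring conventions

`hemisphere_score = 10 − #affected`; the reported score is
`min(left, right)` — the clinically conservative collapse for bilateral
predictions, since no single standard exists; both hemisphere scores are
always exposed. Dichotomization at ≥ 6 follows the thrombectomy
eligibility cutoff.

## Evaluation statistics

- Confusion metrics with explicit undefined-handling (zero denominators
  flagged, never silent NaN).
- Cohen's kappa from the 2×2 marginals; kappa = 1 returned for perfect
  agreement with degenerate marginals, undefined flagged otherwise.
- ICC: two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) by default (standard for interchangeable raters), ICC(3,1)
  as an option; computed from the ANOVA mean squares and cross-checked
  against `pingouin` in the tests.
- ROC/AUC via scikit-learn (AUC equals the Mann–Whitney statistic with
  ties counted ½), cross-checked against an O(n²) pairwise oracle.
- **Paired permutation test**: observed statistic =
  metric(assisted) − metric(unassisted); the null swaps the two condition
  labels independently within each case with probability ½ (the paired
  sign-flip design); one-tailed p with add-one smoothing,
  `(1 + #{perm ≥ obs}) / (1 + n_perm)`, 10,000 permutations by default.
  Permutations with undefined metrics are redrawn and counted. The test
  is metric-generic (sensitivity and accuracy provided).
- **`reconstruct_confusion`**: exhaustive search over all integer
  (tp, fp, fn, tn) summing to n for matrices whose recomputed metrics
  round — half away from zero, the convention of printed clinical
  tables — to a reported (sens, spec, acc, prec) row. At n = 180
  (2 hemispheres × 90 patients, an inference supported by the exact
  integer consistency of all 10 published rows and their pooled line)
  every published region row reconstructs uniquely, which is what lets
  the derived F1/kappa cells and the pooled line be recomputed exactly.

## The phantom generator

What it emulates: head-CT geometry (64×64×16 voxels at 1×1×5 mm — thick
axial slices), textbook tissue attenuation (white 30, gray 38, CSF 8,
skull 700, air −1000 HU), independent Gaussian voxel noise (SD 2 HU), and
ischemic lesions as a uniform negative HU shift over whole region masks.
The default shift of −8 HU keeps hypoattenuation subtle, as in real early
infarcts; verification experiments that need strong signal use −30 HU
explicitly. The 20 regions are mirrored ellipsoids placed at anatomically
ordered heights (deep structures and M1–M3 ganglionic, M4–M6
supraganglionic); homologous voxel counts are equal by construction.

Cohorts draw stroke subjects at prevalence 0.622 by default (the AIS rate
of the emulated test cohort; the emulated training cohort's 0.81 is a
parameter away), with k affected regions in one hemisphere, k from a
truncated-geometric pmf ∝ 0.75^k over 1..10 — small lesion loads are most
common but enough mass sits at k ≥ 5 to exercise the dichotomy cutoff.
The noise field depends only on the seed, never on the lesion set, so a
lesioned and a clean draw at the same seed differ by exactly ΔHU inside
the lesion mask.

What it does **not** emulate: CT physics (beam hardening, streaks,
partial volume), anatomical variability, registration error, lesions
partially covering a region, or gray/white differential involvement.
Passing phantom tests therefore demonstrates that the pipeline's
machinery — extraction, training, scoring, statistics — is correct, not
that the classifier reaches clinical accuracy on real NCCT; the published
clinical table is instead verified through the reconstruction bridge.

A zero ΔHU inserts nothing and yields empty annotations; each cohort
subject additionally records its *assigned* regions so the zero-contrast
null experiment (train against signal-free labels, expect AUC 0.5) is
constructible.

## Scaled experiment sizes

The standing verification experiment trains on a 200-phantom cohort
(160 train / 40 held out, split by subject to prevent leakage) with 6
pre-training and 12 fine-tuning epochs — enough for the loss to plateau
on this separable task while keeping a full run to a few minutes on one
CPU. Against it run: held-out region-level AUC ≥ 0.90 under strong
contrast, no more than 0.05 behind a mean-intensity logistic baseline,
and chance AUC (0.5 ± 0.1) under zero contrast. Permutation calibration
uses a 5-case study against exact enumeration over all 2⁵ swap patterns
and a 500 × 200 super-uniformity check.

## Known limitations

- The NumPy implementation is single-threaded-CPU oriented; full-scale
  200-epoch training on large clinical cohorts would be slow.
- ICC on the dichotomized block is computed between predicted and true
  total scores (2 raters); with a single model there is no multi-rater
  ICC to report.
- The permutation test's within-case swap assumes exchangeability of the
  two conditions under the null; crossover designs with order effects
  would need an explicit order term.
- `reconstruct_confusion` is exact but O(n³); fine for n in the hundreds.
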