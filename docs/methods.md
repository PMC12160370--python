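# Methods

`tonguedx` implements a tongue-image pipeline for Traditional Chinese
Medicine (TCM) constitution recognition over five classes: Gentleness
(balanced), Qi-deficiency, Yang-deficiency, Wetness-heat, and Qi-depression.
This note records the models, the defaults that matter, and the design
choices made where the design was genuinely open.

## Questionnaire scoring (CCMQ)

Each of the nine subscales of the Constitution in Chinese Medicine
Questionnaire is a set of 5-point Likert items. The raw score (sum of item
responses) is rescaled to

    transformation = (raw − n_entries) / (4 · n_entries) · 100  ∈ [0, 100].

Determination rules: Gentleness iff the balanced subscale scores ≥ 60 *and*
all eight imbalanced subscales score < 30; an imbalanced subscale scoring
≥ 40 flags its type. Exactly one flagged *studied* type yields that call;
only non-studied flags yield `OTHER_IMBALANCED`; everything else —
no rule firing, several studied flags, or a studied/non-studied mix — is
`INDETERMINATE`. Two open points were resolved conservatively: ties between
flagged types are not broken by the larger score (ambiguous subjects are the
ones a study would exclude), and the 30 ≤ s < 40 band carries no call of its
own. Subscale entry counts default to the published instrument
(8/8/7/8/8/6/7/7/7) and are configurable.

## Synthetic cohort

No labelled tongue-image dataset is publicly deposited, so the package ships
a seeded generator that every downstream stage is tested against. A sample
is a superellipse tongue (smoothly perturbed boundary, randomized exponent
2.2–2.8 and axes) on a skin-toned gradient background with a darker oval rim
imitating a capture-chamber opening. Class-conditional appearance follows
classical tongue diagnosis:

| class | body | lesion |
|---|---|---|
| Gentleness | pink | none (thin whitish coating) |
| Qi-deficiency | pink | central cracks |
| Yang-deficiency | pale (lower a*), larger | marginal tooth indentations |
| Wetness-heat | pink | yellow (high b*), opaque "greasy" coating |
| Qi-depression | pink | reddened tip |

Only Yang-deficiency alters the body itself; the other imbalanced classes
share the Gentleness body so that the class-defining lesion carries the
signal. This matters for explanation tests: if each class also had its own
incidental body tint, a classifier could (and in practice does) key on
arbitrary body regions, and heatmap-localization of lesions would measure
nothing. Lesion sub-masks (crack, toothmark, coating, red tip) are recorded
per sample as ground truth for Grad-CAM scoring; every sub-mask is a subset
of the tongue mask. Effect sizes are package choices — the source cohort is
private and described only qualitatively — and all are overridable per
`PhenotypeSpec`.

Determinism: generators are pure functions of (spec, seed); cohorts derive
per-sample seeds with a counter-based `SeedSequence` scheme
(`spawn_key = (class_index, within_index)`), so cohorts are
order-independent and bit-reproducible.

What the generator does *not* emulate: photo-realistic texture, lighting and
camera variation, occlusions (lips, teeth), inter-subject anatomy beyond the
superellipse family, or label noise between the questionnaire and the image.
Passing tests therefore show that the pipeline recovers a signal with the
assumed structure — not that it reaches any particular accuracy on clinical
photographs.

## Segmentation networks

Three variants share one training/inference surface:

* **unet** — plain encoder–decoder, double-conv blocks, skip connections.
* **unetpp** — nested-skip lattice X[i][j]; node X[i][j] consumes all
  same-row predecessors plus the upsampled X[i+1][j−1]. Deep supervision
  attaches one sigmoid head per row-0 nested node; the loss is the uniform
  mean of per-head losses.
* **ise_unetpp** — the nested lattice with every interior node's dense
  double convolution replaced by: 1×1 mixing convolution → two tandem
  Inception depthwise layers → squeeze-and-excitation (SE) gate. The
  Inception layer splits channels 1/8 : 1/8 : 1/8 : 5/8 into a 3×3 square
  depthwise branch, 1×11 and 11×1 band depthwise branches, and an identity
  passthrough (kernel sizes follow the InceptionNeXt design; all
  configurable). This cuts interior-node parameters several-fold relative
  to dense blocks (asserted in tests), while the band kernels give cheap
  long-range context along each axis.

SE reduction defaults to 16 (clamped to the channel count at tiny widths)
and sits after the tandem extraction layer in every interior node; the exact
placement is not fixed by any published description and is a declared choice.

Training: SGD with momentum 0.9, BCE + soft-Dice loss (no published loss to
follow; this pair is the standard choice for binary medical segmentation),
batch size 10, learning rate 0.1 for the tiny preset. The per-epoch MIoU in
the training history is accumulated from the training minibatches (the same
quantity a training-curve figure shows) rather than a second full-dataset
pass. Masks threshold the sigmoid at 0.5; mask semantics: 1 = tongue,
0-based pixel coordinates.

The networks run on an in-repo numpy autograd engine (`tonguedx.nn`):
reverse-mode tape over NCHW float32 arrays, convolution lowered to
im2col + BLAS matmul, fused batch-norm with gradients through the batch
statistics. Every op is verified against central-difference gradients in the
test suite. The **tiny preset** (depth 2, base 8 channels, and a stride-2
average-pool stem that runs the lattice at half resolution, upsampling the
head output) trains 20 epochs on fifty 128×128 images in well under a
minute per variant on one CPU; full-resolution operation (`stem_pool=1`) is
the default outside the preset.

Metrics: MIoU = TP/(TP+FP+FN) for the tongue class, MPA = (TP+TN)/N, and
pixel accuracy, from pixel-level confusion counts. `improvement_report`
computes metric deltas between models at 2-decimal precision.

## Features

**Traditional.** CIELAB (D65) mean and standard deviation of L*, a*, b*
over masked pixels (via scikit-image's reference conversion), plus masked
GLCM statistics: gray conversion, quantization to 32 levels over the masked
range, symmetric normalized co-occurrence at distance 1 and angles
0°/45°/90°/135°, pairs straddling the mask excluded, and ASM, contrast,
correlation, homogeneity and entropy averaged over the four offsets. The
defaults (distance, angles, levels, the five statistics) are package
choices; no published parameterization exists to follow. Degenerate
single-valued regions return ASM = 1, contrast = 0 by convention.
Preprocessing: full-vocabulary one-hot encoding (no reference category
dropped), leakage-safe standardization (parameters fitted on a declared id
subset only), binary-column validation with mode imputation and audit, and
Fleiss' kappa (statsmodels) for inter-rater agreement, NaN when expected
agreement is 1.

**Deep.** A bottleneck residual classifier trained on segmented images
(background zeroed outside the mask — embeddings are provably independent of
background pixels, which the tests assert). Default layout is the 50-layer
bottleneck network: stages (3,4,6,3), final stage width 2048, so the
penultimate (post-global-average-pool) activations give the 2048-dimensional
embedding exported as `DL_0 … DL_2047`. The test preset uses 2 stages, width
16, embedding 64, 64×64 inputs. Loss is class-weighted categorical
cross-entropy with inverse-frequency weights normalized so the
count-weighted mean weight is 1 (so a 380-vs-152 imbalance gives the
minority 2.5× the majority weight). Optimizer: SGD, momentum 0.9, default
learning rate 1e-3; the tiny preset uses 0.05 with a single ×0.3 step decay
after two-thirds of the epochs, which stabilizes end-of-training accuracy at
desk scale. Random initialization is the default; pretrained weights are
out of scope for the tests (no downloads). Embeddings are by default
extracted from a model fitted once on the full cohort; a maintainer wanting
strict fold hygiene can refit per training fold — both modes are reachable
through the API, and the leakage implication of fit-once is the caller's to
weigh.

## Screening and balancing

LASSO: one-vs-rest per class, λ by 10-fold cross-validated MSE
(`LassoCV`), selected set = union over classes of nonzero supports. The
union rule is a declared choice (per-class panels exist in the literature
but no combination rule). Random forest: 500 trees, depth ≤ 15, Gini;
importance = mean decrease in impurity, cutoff = above-mean importance; an
out-of-bag error curve (overall and per class) is recorded as the forest
grows via warm-started refits. The screened set is the intersection of the
two, ordered by name. SMOTE is hand-implemented (k = 5 neighbours, convex
combinations, originals preserved verbatim) and is applied to training folds
only — balancing before the split would leak synthetic copies of test
points into training.

## Classifiers and evaluation

Eight benchmark algorithms behind one interface: decision tree, random
forest, KNN, multinomial logistic, elastic-net logistic (saga,
l1_ratio 0.5), MLP, LightGBM, XGBoost (the boosters are the installed
upstream libraries). The fusion MLP follows the 37 → 8 → 8 → 5 layout
(421 trainable parameters, asserted against the fitted model).

Binary confusion-count formulas (accuracy, precision = PPV,
sensitivity = recall, specificity, F1, NPV, MCC, Cohen's kappa) extend to
five classes one-vs-rest with unweighted macro averaging; zero-denominator
cells yield NaN with a warning and are excluded from the macro mean. AUC is
the tie-corrected trapezoidal one-vs-rest ROC area (rank formulation),
macro-averaged — it matches scikit-learn's `roc_auc_score(multi_class="ovr")`
to 1e-10 in tests but is computed independently. Validation: stratified 8:2
split plus stratified 5-fold cross-validation; the fold-AUC summary is the
mean and the standard error (sample sd / √k), which reproduces the published
worked example (folds 0.906, 0.846, 0.890, 0.938, 0.852 → 0.886 ± 0.0171).
When k exceeds the smallest class the splitter falls back to unstratified
folds with a warning (this is what makes leave-one-out expressible).

Fusion concatenates selected traditional columns, optional demographic
controls (age; sex coded 0 = male, 1 = female), then selected deep columns,
rejecting duplicate names. Whether age/sex sit inside the traditional set or
are appended is explicit at the call site rather than implied.

## Explanation

Grad-CAM on the residual backbone (the only differentiable image path):
activations of the last convolutional stage weighted by spatially pooled
logit gradients, rectified, bilinearly upsampled, min-max normalized per map
(all-zero maps stay zero; positive rescaling of the logits leaves the map
unchanged). The localization score of a heatmap against a lesion sub-mask is
(mean heat inside) / (mean heat outside), 1.0 for flat maps, capped at 1e6
when all heat is inside. At tiny scale the region a trained network uses is
somewhat run-dependent, so the localization acceptance check pools scores
over three training replicates before taking the median; single replicates
pass for most but not all seeds.

## Problem sizes used by the test suite

Segmentation benchmark: 50 images at 128×128, 20 epochs per variant, tiny
preset. Backbone: 100 balanced 64×64 images, 30 epochs. Fusion ordering:
300-subject cohort (60 per class) at 64×64, held-out fifth. Screening
recovery: n = 300, 60 features, 5 informative, 10 seeds. These sizes keep
the full suite in the single-digit minutes on one CPU while leaving each
property comfortably away from its threshold.

## Known limitations

* Published headline performance (98–99% segmentation overlap, fused-model
  accuracy ≈ 0.84) was measured on a private 1374-subject cohort and is
  intentionally not asserted anywhere; the suite checks orderings,
  identities, and worked computations instead.
* The numpy engine is CPU-only and single-threaded beyond BLAS; it is meant
  for desk-scale experiments, not production training.
* GLCM features quantize over the masked range, so they are
  contrast-normalized per image; absolute gray-level information is carried
  by the Lab statistics only.
* The synthetic generator's phenotype effect sizes are not calibrated to any
  measured distribution; conclusions about real tongue images require real
  data.
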