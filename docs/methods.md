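# Methods

## Problem and approach

CNN graders of diabetic retinopathy (DR) reach expert-level accuracy, but
accuracy alone does not show *which* image content drives the grade. This
package quantifies that: it trains small CNN grade classifiers, extracts
Grad-CAM attention maps, binarizes them with Otsu's method, and scores the
binarized maps against per-component ground-truth masks with
intersection-over-union (IoU),

    IoU(X, f, c) = |D_f(X) ∩ M_c(X)| / |D_f(X) ∪ M_c(X)|,

where `D_f(X)` is the binarized saliency map of model `f` on image `X` and
`M_c(X)` the binary mask of ocular component
`c ∈ {microaneurysm, hemorrhage, exudate, optic_disc, vessels, other}`.
Derived summaries: mean IoU per (model, component), pairwise inter-model
agreement (mean-over-images IoU between binarized maps, optionally
stratified by a component), and the fraction of ground-truth lesions the
binarized map misses.

Because the analysis runs on synthetic images whose masks are exact by
construction, saliency claims can be tested causally: the generator
controls what the label depends on.

## Synthetic scene model

Each image is a circular field of view (FOV, radius 0.95 of the half-width)
on black: a shaded red-orange background with Gaussian sensor noise
(sd 0.02), a bright optic disc (radius 0.07–0.10 of the image side, offset
0.45 of the FOV radius from center), a branching dark-red vessel tree grown
from the disc by a seeded random walk (6 main branches, depth 3, widths
1–2 px), and lesions: microaneurysms (dark dots, radius 1–2 px),
hemorrhages (dark ellipses, 3–6 px), exudates (bright yellow disks,
2–5 px), and neovascular tufts (tangles of fine vessels, 6–10 px). Tuft
pixels are recorded in the vessel mask — they are vessels — so the six
component masks stay fixed; grade-4 scenes additionally carry a heavy
hemorrhage/exudate burden so the three pathology masks remain informative
for proliferative disease. `other` is the FOV minus the union of the named
masks; later-drawn elements overwrite earlier pixels in the *image*, while
masks record each component independently.

The grade is a deterministic function of lesion counts (K = 5 by default):
0 — no lesions; 1 — microaneurysms only; 2 — between 1 and K
hemorrhages-plus-exudates; 3 — more than K hemorrhages; 4 — neovascular
tufts present. Real screening labels come from expert readers; the
deterministic rule replaces them so that the lesion burden is the *only*
label signal, which is what makes the recovery experiment below
interpretable. The rule is monotone: adding lesions never lowers the grade.

A watermark mode severs that link: lesion counts are drawn from a fixed,
grade-independent distribution and the label is stamped as `grade + 1`
bright blocks near the top of the FOV (returned as an extra mask).

What the generator does *not* emulate: photorealistic texture, camera
optics, image-quality defects, macular edema, laser scars, inter-grader
label noise. Tests passing on this data show the pipeline measures what it
claims to measure on images with known ground truth — not that any
conclusion transfers to real fundus photographs.

## Dataset protocol

- **Rebalancing** to a fixed cap (default 500) per grade: classes above the
  cap are undersampled without replacement, classes below it are
  oversampled by repeating manifest rows; repeated rows are de-duplicated
  in effect by random augmentation at training time.
- **Splitting** 80/10/10 train/val/test, stratified by grade, with all
  duplicates of one source image forced into a single split so
  oversampling can never leak evaluation images into training.
- **Augmentation**: rotation up to ±360°, height/width shift up to 0.15 of
  the side, zoom 0.9–1.1, horizontal and vertical flips. One sampled
  transform is applied identically to the image (bilinear) and every mask
  (nearest-neighbour, so masks stay binary); pixels leaving the frame
  become black and drop out of `other`.

## Models and training

No deep-learning framework is part of the dependency set; the classifiers
are a compact, fully-tested numpy CNN stack (im2col convolutions, manual
backward passes verified against finite differences at 1e-6). Four
variants carry the motifs that distinguish the large published
architectures: `plain` (straight conv stack), `residual` (additive skip),
`multibranch` (parallel conv branches, channels concatenated), `separable`
(depth-wise + point-wise convolution). All end in a tagged last
convolutional layer, global average pooling and a 5-way softmax.

Training follows a two-phase schedule: the classifier head alone for
`head_epochs` (default 5), then the full model for up to `full_epochs`
(default 100) with Adam (default learning rate 0.001, batch 32),
cross-entropy loss, early stopping on validation loss with 20-epoch
patience, and restoration of the best-validation weights. Weight
initialization is a seeded uniform fan-in scheme; runs are bit-reproducible
for a fixed seed on one thread.

Default input side is 512 px for real data, 128 px for synthetic work;
both are configurable and must be divisible by 4 (two pooling stages).

## Saliency

Grad-CAM uses the last convolutional layer and, by default, the predicted
label: channel weights are the spatial mean of d(class logit)/d(activation),
the weighted activation sum is rectified, bilinearly upsampled to image
resolution, and min–max normalized to [0, 1] (a constant map becomes all
zeros — "no attention"). The normalization makes the downstream Otsu
threshold well defined; it is recorded in each heatmap's JSON sidecar so
alternative conventions can be compared. Occlusion sensitivity (average
per-pixel drop in the target-class probability under a sliding black
patch, negatives clamped, normalized) is kept as an independent,
gradient-free probe of the same question and as a cross-check in tests.

## Scoring choices

- **Otsu binarization** on a 256-bin histogram over [0, 1] (8-bit
  convention); candidate thresholds are interior bin edges, first argmax
  wins, pixels strictly above the threshold are foreground, ties go to
  background. A constant map yields an empty detection.
- **Both-empty IoU is undefined**, not 0 or 1, and is excluded from means
  (1 would reward components absent from an image, 0 would penalize
  correct silence). Group means report defined and total counts.
- **Agreement** between two models is the mean over images of the IoU of
  their binarized maps (component-stratified variant intersects both maps
  with that component's mask first). The matrix is symmetric with unit
  diagonal. The choice of IoU here is isolated behind one function so
  Dice or pixel accuracy could be swapped in.
- **Missed pathology** counts lesions as 4-connected components of the
  union of the three pathology masks; a lesion is detected when its
  overlap with the detection map is at least τ of its area (default: any
  overlap). The pixel-level missed fraction is reported alongside the
  lesion-level one.

## Recovery experiment and falsification control

`experiments.lesion_signal_recovery` trains one variant on 250 images
(50 per grade, 64×64, 15 epochs total: 2 head + 13 full) and scores
Grad-CAM maps of the held-out test images against the pathology-mask
union. Significance comes from a permutation null: each test image's mask
is independently rotated (uniform angle) and translated to a uniform
position inside the FOV, 99 times; p = (1 + #{null ≥ observed}) / 100.
The watermark control runs the same procedure on watermark-labelled data
and tests both the pathology masks (expected: consistent with the null)
and the watermark region (expected: above the null).

At this desk scale the paper-default optimizer setting leaves the small
CNN at chance within the epoch budget, so the experiment's own training
configuration uses learning rate 0.003 and 16 base channels; these are
model-side choices, fixed once — the generator's scene statistics are
identical across grades by construction and were not adjusted.

## Metrics

From the 5×5 confusion matrix: accuracy; Cohen's kappa from the marginal
chance agreement; the multi-class Matthews correlation
(c·s − Σ t_k p_k) / √((s² − Σ p_k²)(s² − Σ t_k²)); and macro one-vs-rest
SE/SP/PPV/NPV. AUC is the macro mean of one-vs-rest ROC areas computed
from the per-image probability vectors. One-vs-rest entries with zero
denominators are undefined and excluded from macro means with a warning.
Macro one-vs-rest aggregation is a stated choice (consistent with the
per-grade SE/SP table the suite also emits); it is printed in every
report header.

## Numerical and degenerate-input conventions

Images are float64 in [0, 1], stored as 8-bit PNG (masks 0/255, heatmaps
16-bit grayscale). Coordinates are row-major, origin top-left. Empty
heatmap directories score to empty reports with a warning, not an error.
Early stopping treats "no improvement" as `loss ≥ best − 1e-12`.
Manifest CSVs store paths relative to their own location so reruns of the
same configuration are byte-identical.

## Problem sizes

The test suite trains only miniature models (16–32 px inputs, ≤60 epochs
on ≤120 images) except for the two recovery experiments (64 px, 250
images, 15 epochs each); a full default suite run takes about a minute on
one CPU core, and `scripts/acceptance.py` about the same.

## Known limitations

- The numpy CNN stack is desk-scale by design; it has no GPU path, no
  batch normalization, and two pooling stages, so the Grad-CAM grid is
  1/4 of the input side — coarse relative to microaneurysms, which
  depresses pathology IoU for the smallest lesions.
- Mean IoU values on synthetic data are not comparable in magnitude to
  values obtained on real fundus datasets; only their ordering and the
  permutation tests are designed to be meaningful here.
- The agreement statistic is computed on binarized maps; computing it on
  continuous maps is a defensible alternative the API does not currently
  expose.
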