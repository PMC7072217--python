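# Methods

`npcscreen` implements a two-stage classifier for nasopharyngeal biopsy
slides, exercised end to end on synthetic annotated slides.  This note
records the model, the generator it is trained against, and the numerical
and design choices a maintainer would want to know.

## The two-stage model

**Stage 1 — patch level.**  256×256 px RGB patches are cropped dynamically
from free-hand polygon annotations of three kinds of area: tumor (NPC),
benign tissue, and background.  The cropping rules are asymmetric: benign
and background patches must lie 100 % inside the union of their class's
annotated regions, while a tumor patch needs at least 50 % of its area
inside the union of tumor annotations (tumor margins are informative; clean
benign examples must be unambiguous).  Membership is decided by the pixel
*center* (even-odd rule, strict interior, 0-based coordinates, half-open
windows) — the unambiguous, reproducible convention.  Overlap is
always measured against the union of same-class regions so duplicated or
abutting annotations never double count.

Batches are balanced: 48 patches, 16 per class, slides drawn uniformly
among those that admit at least one rule-compliant window, then a region
with probability proportional to its area, then rejection sampling of the
window position (top-left uniform in the region's bounding box dilated by
128 px, capped at 10,000 attempts).

The classifier is a small residual convolutional network (≈48k parameters)
with a 3-way softmax head:

    input (uint8 or [0,1] float) → 4×4 average pool → 3×3 conv stride 4 (16 ch)
    → BN → ReLU → 3×3 conv stride 2 (24 ch) → BN → ReLU
    → 3×3 conv (32 ch) → BN → ReLU → 2 residual blocks (32 ch)
    → global average pooling → linear 3-way head

Training is SGD with Nesterov momentum — initial learning rate 0.0017,
momentum 0.95, balanced batch of 48 — with validation every
`eval_interval` steps and a reduce-on-plateau schedule (factor 0.1,
patience 5 evaluations, min 1e-6).  The best-validation
checkpoint is retained.  Batch normalization is what keeps this recipe
stable at that learning rate from random initialization; without it the
loss collapses to the uniform-prediction plateau.  Pixels are normalized
to [0,1]; there is no stain normalization and no augmentation beyond the
random crop position.

The network engine is written in NumPy (NHWC, float32, im2col convolutions
through BLAS), sized so a full training run takes CPU minutes.  Gradients
are verified against float64 central differences in the test suite.  The
backbone is a configuration dict, so deeper variants are drop-in.

**Stage 2 — slide level.**  A slide is tiled into non-overlapping 256×256
windows (row-major, `ceil(H/256) × ceil(W/256)`, edge tiles padded with
white so the background class absorbs the padding).  Each tile's 3-vector
of class probabilities becomes one pixel of the probability map.  The map
is stacked with a tile-aligned RGB thumbnail (area mean per tile — the one
downscale that needs no registration) into a 6-channel slide input.

The slide classifier is the same residual design with a 2-way head and
global average pooling, hence free input sizes.  Each training batch
(8 inputs, 4 per label) is resized — bilinear, aspect ratio not preserved —
to one of six fixed target shapes {256×256, 256×512, 256×768, 512×768,
400×600, 500×500} drawn uniformly; the resize acts as augmentation.  At
test time a slide is scored under all six targets and the mean NPC
probability is the slide score — averaging over aspect ratios is the
natural use of the free-size property.  Bilinear resizing
is implemented in separable matrix form and matches `skimage.transform.
resize(order=1, mode="edge")` to float32 precision.

**Interpretability.**  Grad-CAM on the final convolutional block: the
gradient of the target class's pre-softmax score w.r.t. the last
pre-pooling activations is averaged spatially into per-channel weights;
the rectified weighted sum is upsampled bilinearly to patch size and
min-max normalized per patch (normalization after upsampling, so the
maximum is exactly 1 whenever any activation survives the rectifier, and
re-normalization is a no-op).

**Evaluation.**  AUC is pairwise concordance (ties half) — identical to
the trapezoidal area under the empirical ROC — computed via scikit-learn
and cross-checked in the tests against exhaustive pair enumeration.  Two
patch models are compared by repeating the testing inference (30 runs by
default; each run draws one balanced tumor/benign patch sample scored by
both models) and applying a two-tailed t-test to the per-run AUCs.  The
test is Welch's (unequal variance, Welch–Satterthwaite df) — the
conservative unpaired default; a paired variant is available since both
models score the same patches in every run.  Degenerate convention: both samples constant →
p = 1 for equal means, 0 otherwise.

## The synthetic slide generator

The generator stands in for scanned H&E biopsies at desk scale (default
2048×1536 px; all geometry is 64-bit so the same code paths hold at
gigapixel sizes).  A slide is a near-white background with 1–2 star-shaped
tissue fragments, which carry:

- **lymphoid tissue** — lavender-pink base densely seeded with small dark
  nuclei (r ≈ 2–3.4 px, ~0.008/px²);
- **tumor nests** — sheets with large pale vesicular nuclei (r ≈ 6.5–9.5 px)
  carrying a thin dark rim, plus sparse admixed lymphocytes;
- **germinal centers** — pale cores with nuclei deliberately identical to
  tumor nuclei *except* for the missing rim and absent admixed
  lymphocytes; each is annotated together with a 1.55× collar of
  surrounding lymphoid tissue, the way a pathologist circles the area, so
  full benign windows exist over confuser content;
- **surface epithelium** — a palisaded ribbon of elongated nuclei along a
  boundary arc of the fragment;
- **stroma** — pink rim with sparse spindle nuclei;
- **background** — two tissue-free corner boxes, fixed before the tissue
  fragments are placed so they always exist.

Structures are placed by clearance: a Euclidean distance transform of the
free zone yields every pixel whose clearance covers the candidate blob's
maximal radial extent; a blob that fits nowhere shrinks to the largest
feasible radius (bounded below per structure kind).  Clean benign-tissue
annotations are *reserved first* (radius 210 px, enough to inscribe a full
256-px window with slack), then tumor nests, then germinal centers
(which shrink most gracefully), then epithelium.  The tumor share of the
tissue area tracks the requested `tumor_fraction` within ±20 % relative;
the first nest is forced above the ~102 px radius below which no window
can reach 50 % tumor coverage (slides under ~6 % tumor on small canvases
may therefore not support tumor patch sampling — mirroring how very-low-
burden slides are the hard case).  Datasets are written as PNG (or tiled
TIFF) plus GeoJSON annotations and a CSV manifest; per-slide seeds derive
deterministically from the template seed, and a slide whose geometry
cannot be placed is retried under a derived seed so manifests stay
reproducible.

Canvas-size guidance: ≥1280×1024 supports all three patch classes;
1024×768 supports tumor/benign sampling but its background boxes are too
small for full windows, so such slides serve the slide stage (maps only);
512-px slides are generation-only.

**What the generator does and does not emulate.**  It reproduces the
*task structure*: three annotatable classes, benign mimics of tumor
(germinal centers, epithelium), tumor-area fractions down to <5 %, complete
polygon ground truth, and recorded nucleus centers for localization
audits.  It does not attempt photorealism: no stain variation, no blur or
scanner artifacts, no nuclear chromatin texture, no overlapping-cell
occlusion.  Textures are separable by construction (a linear classifier on
64-px block channel statistics exceeds 0.8 accuracy — this is asserted in
the tests).  Passing the synthetic benchmark therefore demonstrates that
the pipeline's machinery — rule-compliant sampling, training loop,
stitching, free-size slide model, attribution — is correct and that the
training targets are attainable; it does not certify performance on real
histology.

## Study conditions (problem sizes)

Chosen once, as the desk-scale analogue of the clinical design:

- patch benchmark: 20 training slides (1280×1024, tumor fraction
  0.18–0.22, 4 confusers), 4 validation, 16 held-out; 3,000 steps;
- slide benchmark: 60 training inputs (the 20 patch-training slides plus
  40 extras at 1024×768), 400 steps, 20 held-out slides;
- expansion experiment: 8 training slides with vs without confuser
  annotations (250-step runs across 5 seeds in the tests; 400-step runs
  with a 30-run repeated comparison in the acceptance script), tested on a
  confuser-rich cohort;
- low-fraction stress: 1600×1200 slides at 4 % tumor fraction (the size
  at which the anchor-nest guarantee is active).

`scripts/acceptance.py` runs a proportionally scaled version of all of the
above (12 training slides, 1,500 patch steps, 300 slide steps) so a full
from-scratch reproduction finishes in minutes on one CPU.

## Numerical choices and edge cases

- Pixel-in-polygon: shapely strict interior at pixel centers; a center
  exactly on an edge counts as outside.
- Window overlap = mean of the rasterized union mask over the window; the
  summed-area-table fast path used during training is asserted equal to
  fresh rasterization.
- uint8 network inputs are pooled in integer-exact float32 accumulation
  and scaled by 1/255 after pooling; this matches the float path to ~1e-7.
- BatchNorm: batch statistics during training, running statistics
  (momentum 0.1) at inference, so evaluation is batch-composition
  independent and deterministic.
- Reduce-on-plateau counts an evaluation as "no improvement" if the
  validation loss fails to drop by >1e-8; the rate is reduced after
  `patience` consecutive such evaluations.
- Welch p-values fall back to the degenerate convention above instead of
  propagating NaNs.
- All randomness flows from explicit `numpy` Generators; slides are
  byte-identical across regenerations, training is deterministic given a
  seed and thread count.

## Known limitations

- The synthetic appearance model is minimal (see above); hyperparameters
  tuned here may not transfer to real H&E data.
- The patch backbone sees the image through a 4×4 average pool; cues
  smaller than ~4 px (e.g. chromatin detail) are invisible by design,
  which is acceptable for the synthetic textures but a real deployment
  would widen the stem.
- Epithelium ribbons are too thin to host full 256-px benign windows, so
  the expansion experiment's effect is carried almost entirely by germinal
  centers.
- Slide-level training uses probability maps from a single patch
  checkpoint; co-training or ensembling across checkpoints is out of
  scope.
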